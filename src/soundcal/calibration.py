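"""Device-specific logarithmic calibration of smartphone amplitude values.

Android's ``MediaRecorder.getMaxAmplitude()`` returns a unitless amplitude on
a device-dependent scale (modelled here as integers in [0, 32767]).  A device
model's calibration is the log-linear curve

    level_dBC = a * log10(amplitude) + b

fitted against a reference sound level meter at 1000 Hz (where dB(C), dB(A)
and dB_SPL coincide).  The slope ``a`` is in dB per decade of amplitude and is
near 20 for real devices (amplitude roughly proportional to sound pressure);
the intercept ``b`` absorbs the device-specific gain offset.

A packaged registry maps the device IDs observed in crowdsensed user-agent
strings to canonical model names and, for lab-calibrated models, to their
fitted curves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .acoustics import SoundLevel, Weighting

__all__ = [
    "InvalidAmplitudeError",
    "DegenerateDesignError",
    "DeviceCalibration",
    "CalibrationSession",
    "RegistryRecord",
    "DeviceRegistry",
    "amplitude_to_db",
    "db_to_amplitude",
    "fit_log_calibration",
    "offset_calibration",
    "resolve_device",
    "default_registry",
    "FITTED_RANGE_DB",
    "MAX_AMPLITUDE",
]

#: Level range (dB(C)) covered by the calibration experiments; conversions
#: outside it are extrapolations of the fitted curve.
FITTED_RANGE_DB: tuple[float, float] = (50.0, 80.0)

#: Ceiling of the platform recorder's absolute amplitude scale (16-bit).
MAX_AMPLITUDE: int = 32767


class InvalidAmplitudeError(ValueError):
    """Raised for amplitude values on which the log-calibration is undefined."""


class DegenerateDesignError(ValueError):
    """Raised when a calibration fit has fewer than two distinct amplitudes."""


@dataclass(frozen=True)
class DeviceCalibration:
    """Fitted log-calibration curve of one device model.

    Parameters
    ----------
    model_name:
        Canonical device model name.
    slope_a:
        Slope in dB per decade of amplitude; must be positive.
    intercept_b:
        Intercept in dB(C) (the level mapped to amplitude 1).
    r_squared:
        Coefficient of determination of the fit, in [0, 1]; ``None`` for
        hand-entered (e.g. single-point offset) profiles.
    """

    model_name: str
    slope_a: float
    intercept_b: float
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.slope_a > 0):
            raise ValueError(f"slope must be > 0, got {self.slope_a}")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"R^2 must be in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class CalibrationSession:
    """Reference-level / amplitude pairs from one calibration run.

    A standard session holds seven points at 50..80 dB(C) in 5 dB steps,
    measured with a pure 1000 Hz tone against a reference sound level meter.
    """

    points: tuple[tuple[float, float], ...]
    frequency_hz: float = 1000.0
    weighting: Weighting = Weighting.C

    def __post_init__(self) -> None:
        pts = tuple((float(lv), float(x)) for lv, x in self.points)
        if any(x <= 0 for _, x in pts):
            raise InvalidAmplitudeError("session amplitudes must be > 0")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weighting", Weighting(self.weighting))

    @property
    def levels(self) -> np.ndarray:
        return np.array([lv for lv, _ in self.points])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([x for _, x in self.points])


def amplitude_to_db(x: float, cal: DeviceCalibration) -> SoundLevel:
    """Convert a recorder amplitude to dB(C) via the device's fitted curve.

    Returns ``a * log10(x) + b`` as a C-weighted level.  Amplitudes below 1
    digital unit are mathematically valid (they map below the intercept) but
    callers that model the integer recorder scale reject them upstream.

    Raises
    ------
    InvalidAmplitudeError
        If ``x <= 0`` (the logarithm is undefined).
    """
    x = float(x)
    if not (x > 0):
        raise InvalidAmplitudeError(f"amplitude must be > 0 for dB conversion, got {x}")
    return SoundLevel(cal.slope_a * math.log10(x) + cal.intercept_b, Weighting.C)


def db_to_amplitude(level: SoundLevel | float, cal: DeviceCalibration) -> float:
    """Invert the calibration curve: amplitude ``10**((L - b) / a)``."""
    return 10.0 ** ((float(level) - cal.intercept_b) / cal.slope_a)


def is_extrapolated(level: SoundLevel | float) -> bool:
    """True if a converted level lies outside the 50-80 dB(C) fitted range."""
    lo, hi = FITTED_RANGE_DB
    return not (lo <= float(level) <= hi)


def fit_log_calibration(
    session: CalibrationSession, model_name: str = "fitted"
) -> DeviceCalibration:
    """Ordinary least squares of reference level on log10(amplitude).

    Minimizes squared error in the dB (response) direction, which matches a
    calibration experiment where the reference level is set and the amplitude
    is the device's reading.  ``R^2 = 1 - SS_res / SS_tot`` is the coefficient
    of determination of that regression.

    Raises
    ------
    DegenerateDesignError
        With fewer than two points or fewer than two distinct amplitudes.
    """
    x = session.amplitudes
    y = session.levels
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise DegenerateDesignError(
            "calibration fit needs >= 2 points with distinct amplitudes"
        )
    result = stats.linregress(np.log10(x), y)
    # two points define an exact line; linregress reports rvalue=0 when y
    # variance is 0, so recompute R^2 from residuals for the general case
    pred = result.slope * np.log10(x) + result.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DeviceCalibration(
        model_name=model_name,
        slope_a=float(result.slope),
        intercept_b=float(result.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
    )


def offset_calibration(
    point: tuple[SoundLevel | float, float],
    reference_slope: float,
    model_name: str = "offset-calibrated",
) -> DeviceCalibration:
    """Single-point calibration assuming a known (shared) slope.

    Device curves differ mainly by an offset, so one (level, amplitude) pair
    plus a reference slope pins down a usable profile:
    ``b = L - reference_slope * log10(x)``.  No R^2 is attached.
    """
    level, x = point
    x = float(x)
    if not (x > 0):
        raise InvalidAmplitudeError(f"amplitude must be > 0, got {x}")
    b = float(level) - reference_slope * math.log10(x)
    return DeviceCalibration(
        model_name=model_name, slope_a=float(reference_slope), intercept_b=b
    )


# ---------------------------------------------------------------------------
# Device registry


@dataclass(frozen=True)
class RegistryRecord:
    """One device-ID record: canonical name, alias IDs, optional calibration."""

    device_id: str
    model_name: str
    aliases: tuple[str, ...] = ()
    calibration: Optional[DeviceCalibration] = None
    source: str = ""


@dataclass(frozen=True)
class DeviceRegistry:
    """Mapping from observed device IDs to canonical models and calibrations.

    Matching is case-sensitive exact-string on the primary ``device_id`` first
    and on alias IDs second; device IDs are verbatim platform constants, so no
    normalization is applied.  Unknown IDs resolve to model ``"unknown"`` with
    no calibration — a normal outcome for a crowdsensed database.
    """

    records: tuple[RegistryRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.device_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate device IDs in registry: {dupes}")

    def resolve(self, device_id: str) -> tuple[str, Optional[DeviceCalibration]]:
        """Resolve one device ID; see :func:`resolve_device`."""
        for rec in self.records:
            if rec.device_id == device_id:
                return rec.model_name, rec.calibration
        for rec in self.records:
            if device_id in rec.aliases:
                return rec.model_name, rec.calibration
        return "unknown", None

    def calibrated_records(self) -> tuple[RegistryRecord, ...]:
        return tuple(r for r in self.records if r.calibration is not None)

    def calibration_for_model(self, model_name: str) -> Optional[DeviceCalibration]:
        for rec in self.records:
            if rec.model_name == model_name and rec.calibration is not None:
                return rec.calibration
        return None

    # -- JSON round trip ----------------------------------------------------

    @classmethod
    def from_json(cls, path) -> "DeviceRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_dict(cls, data: dict) -> "DeviceRegistry":
        records = []
        for rec in data["devices"]:
            cal = None
            if rec.get("slope") is not None:
                cal = DeviceCalibration(
                    model_name=rec["model_name"],
                    slope_a=rec["slope"],
                    intercept_b=rec["intercept"],
                    r_squared=rec.get("r_squared"),
                )
            records.append(
                RegistryRecord(
                    device_id=rec["device_id"],
                    model_name=rec["model_name"],
                    aliases=tuple(rec.get("aliases", ())),
                    calibration=cal,
                    source=rec.get("source", ""),
                )
            )
        return cls(records=tuple(records))

    def to_dict(self) -> dict:
        devices = []
        for rec in self.records:
            cal = rec.calibration
            devices.append(
                {
                    "device_id": rec.device_id,
                    "model_name": rec.model_name,
                    "aliases": list(rec.aliases),
                    "slope": None if cal is None else cal.slope_a,
                    "intercept": None if cal is None else cal.intercept_b,
                    "r_squared": None if cal is None else cal.r_squared,
                    "source": rec.source,
                }
            )
        return {"devices": devices}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def resolve_device(
    device_id: str, registry: DeviceRegistry
) -> tuple[str, Optional[DeviceCalibration]]:
    """Look up a device ID: exact match first, then alias groups.

    Returns ``(canonical_model_name, calibration_or_None)``; unknown IDs yield
    ``("unknown", None)``.
    """
    return registry.resolve(device_id)


def default_registry() -> DeviceRegistry:
    """The packaged registry: five lab-calibrated profiles plus the device-ID
    to model-name mappings observed in the crowdsensed dataset."""
    path = resources.files("soundcal.data").joinpath("default_registry.json")
    with path.open("r", encoding="utf-8") as fh:
        return DeviceRegistry.from_dict(json.load(fh))
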
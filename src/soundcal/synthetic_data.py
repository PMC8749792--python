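"""Seeded generators emulating the calibration experiment and a crowdsensed
sound-level database.

The real crowdsensed database and the lab's raw amplitude readings are not
redistributable, so every pipeline stage is exercised against synthetic
equivalents instead:

* :func:`simulate_series` — one 15 s measurement (30 amplitude samples) of a
  device held at a true level, with multiplicative microphone gain error
  (additive Gaussian noise in dB, i.e. log-normal in amplitude) and the
  recorder's startup artifact (first sample 0, second sample depressed).
* :func:`generate_calibration_session` — the seven-point 50..80 dB(C)
  calibration procedure run in silico against a known device curve.
* :func:`generate_synthetic_database` — a full entries table with prescribed
  per-platform and per-model composition whose Android amplitudes carry the
  deployed app's documented bias, because they are produced by the *legacy*
  arithmetic averaging of simulated series.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationSession,
    DeviceCalibration,
    DeviceRegistry,
    db_to_amplitude,
    default_registry,
)
from .measurement import DEFAULT_DISCARD, STANDARD_LENGTH, AmplitudeSeries

__all__ = [
    "DeviceNoiseModel",
    "ModelCount",
    "DatabaseSpec",
    "simulate_series",
    "generate_calibration_session",
    "generate_synthetic_database",
    "DEFAULT_SESSION_LEVELS",
    "FALLBACK_PROFILE",
]

#: Seven reference levels of a standard calibration session: 50..80 dB(C) in
#: 5 dB steps.
DEFAULT_SESSION_LEVELS: tuple[float, ...] = tuple(float(v) for v in range(50, 85, 5))

#: Generic curve used to synthesize amplitudes for device models that have no
#: lab calibration (slope near the cluster of fitted devices; synthetic).
FALLBACK_PROFILE = DeviceCalibration(
    model_name="synthetic-generic", slope_a=21.0, intercept_b=8.0
)


@dataclass(frozen=True)
class DeviceNoiseModel:
    """Measurement-noise model of a simulated device.

    ``sigma_db`` is the standard deviation of additive Gaussian noise on the
    per-sample level in dB (default 0.5 dB, the accuracy class of the
    reference meter); ``startup_artifact`` injects the recorder warm-up
    pattern; amplitudes are clipped to the 16-bit recorder ceiling.
    """

    sigma_db: float = 0.5
    startup_artifact: bool = True
    clip_max: int = 32767

    def __post_init__(self) -> None:
        if self.sigma_db < 0:
            raise ValueError("sigma_db must be >= 0")
        if self.clip_max <= 0:
            raise ValueError("clip_max must be > 0")


def _simulate_sample_matrix(
    rng: np.random.Generator,
    true_levels: np.ndarray,
    cal: DeviceCalibration,
    noise: DeviceNoiseModel,
    n_samples: int = STANDARD_LENGTH,
) -> np.ndarray:
    """(n_series, n_samples) integer amplitude matrix; shared kernel for the
    single-series and bulk-database paths."""
    true_levels = np.atleast_1d(np.asarray(true_levels, dtype=float))
    eps = rng.normal(0.0, noise.sigma_db, size=(true_levels.size, n_samples))
    amps = np.rint(
        10.0 ** ((true_levels[:, None] + eps - cal.intercept_b) / cal.slope_a)
    )
    amps = np.clip(amps, 0, noise.clip_max)
    if noise.startup_artifact and n_samples >= 3:
        amps[:, 0] = 0
        frac = rng.uniform(0.0, 1.0, size=true_levels.size)
        amps[:, 1] = np.floor(frac * amps[:, 2])
    return amps


def simulate_series(
    true_level: float,
    cal: DeviceCalibration,
    noise: DeviceNoiseModel = DeviceNoiseModel(),
    seed: int | np.random.Generator = 0,
    n_samples: int = STANDARD_LENGTH,
    device_id: str = "",
) -> AmplitudeSeries:
    """Simulate one measurement series of a device at a true level.

    Each retained sample is ``round(db_to_amplitude(true_level + eps))`` with
    ``eps ~ N(0, sigma_db^2)``, clipped to ``[0, clip_max]``.  With the
    startup artifact on, sample 1 is 0 and sample 2 a uniform fraction in
    [0, 1) of sample 3.  Identical (arguments, seed) give identical series.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amps = _simulate_sample_matrix(rng, np.array([true_level]), cal, noise, n_samples)
    return AmplitudeSeries(samples=amps[0], device_id=device_id)


def generate_calibration_session(
    cal: DeviceCalibration,
    levels: Sequence[float] = DEFAULT_SESSION_LEVELS,
    noise: DeviceNoiseModel = DeviceNoiseModel(),
    seed: int | np.random.Generator = 0,
):
    """Run the calibration procedure in silico: one point per reference level.

    For each level, per-sample noisy levels ``true + eps_i`` are drawn for a
    full series, the startup samples discarded, the corrected (Leq) average
    taken, and the result inverted to an equivalent steady amplitude — the
    averaged reading the experiment app reports per step.  The averaged
    amplitude is kept continuous (an average of many samples resolves below
    one digital unit), so with ``sigma_db = 0`` the points lie *exactly* on
    the device curve and a refit recovers (a, b) to machine precision.
    """
    if not levels:
        raise ValueError("need at least one reference level")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    points = []
    n_retained = STANDARD_LENGTH - DEFAULT_DISCARD
    for level in levels:
        eps = rng.normal(0.0, noise.sigma_db, size=n_retained)
        measured = 10.0 * np.log10(np.mean(10.0 ** ((level + eps) / 10.0)))
        points.append((float(level), db_to_amplitude(measured, cal)))
    return CalibrationSession(points=tuple(points))


# ---------------------------------------------------------------------------
# Database generator


@dataclass(frozen=True)
class ModelCount:
    """Prescribed usage of one device model: users and measurement count."""

    model_name: str
    n_users: int
    n_measurements: int

    def __post_init__(self) -> None:
        if self.n_users < 0 or self.n_measurements < 0:
            raise ValueError("counts must be >= 0")
        if self.n_users > self.n_measurements:
            raise ValueError(
                f"{self.model_name}: {self.n_users} users cannot exceed "
                f"{self.n_measurements} measurements"
            )


@dataclass(frozen=True)
class DatabaseSpec:
    """Prescription for a synthetic crowdsensed database.

    Per-model rows fix the Android composition; ``n_ios`` and
    ``n_no_user_agent`` fill in the other platforms.  True environmental
    levels are Gaussian in dB(C), clipped to [30, 100] (the range observed in
    converted field data); per-user loudness is a Gaussian base in [0, 1]
    with per-entry fluctuation.  ``seed`` is mandatory: the generator is a
    pure function of (spec, seed).
    """

    models: tuple[ModelCount, ...]
    n_ios: int = 0
    n_no_user_agent: int = 0
    loudness_mean: float = 0.4
    loudness_sd: float = 0.15
    level_mean_db: float = 65.0
    level_sd_db: float = 12.0
    noise: DeviceNoiseModel = DeviceNoiseModel()
    seed: int = 0

    @property
    def n_android(self) -> int:
        return sum(m.n_measurements for m in self.models)

    @classmethod
    def from_json(cls, path) -> "DatabaseSpec":
        """Load a spec from a JSON config (documented in the README)."""
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        noise = DeviceNoiseModel(**data.get("noise", {}))
        models = tuple(ModelCount(**m) for m in data["models"])
        keys = (
            "n_ios",
            "n_no_user_agent",
            "loudness_mean",
            "loudness_sd",
            "level_mean_db",
            "level_sd_db",
            "seed",
        )
        kwargs = {k: data[k] for k in keys if k in data}
        return cls(models=models, noise=noise, **kwargs)


def _device_id_for(model_name: str, registry: DeviceRegistry) -> str:
    for rec in registry.records:
        if rec.model_name == model_name:
            return rec.device_id
    return model_name  # unmapped models use their name as raw device ID


def generate_synthetic_database(
    spec: DatabaseSpec, registry: Optional[DeviceRegistry] = None
) -> pd.DataFrame:
    """Generate an entries table with exactly the prescribed composition.

    Android ``stored_amplitude`` values are the *legacy* arithmetic mean of a
    simulated 30-sample series (startup artifact included), so the synthetic
    database reproduces the deployed app's documented downward bias.  Users
    are assigned measurements round-robin so every prescribed user appears at
    least once; loudness traces fluctuate per entry (never constant unless
    ``loudness_sd`` and the fluctuation are forced to zero).
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(spec.seed)
    frames: list[pd.DataFrame] = []
    entry_counter = 0
    user_counter = 0

    def _user_block(n_entries: int, n_users: int, prefix: str) -> np.ndarray:
        nonlocal user_counter
        ids = np.array([f"u{user_counter + i:05d}" for i in range(n_users)])
        user_counter += n_users
        # round-robin keeps every user present; order then shuffled
        assignment = ids[np.arange(n_entries) % n_users]
        rng.shuffle(assignment)
        return assignment

    def _timestamps(n: int) -> np.ndarray:
        base = np.datetime64("2014-04-01T00:00:00")
        offsets = np.sort(rng.integers(0, 6 * 365 * 24 * 3600, size=n))
        return np.datetime_as_string(base + offsets.astype("timedelta64[s]"))

    def _loudness(users: np.ndarray) -> np.ndarray:
        base = {
            u: float(np.clip(rng.normal(spec.loudness_mean, spec.loudness_sd), 0, 1))
            for u in np.unique(users)
        }
        vals = np.array([base[u] for u in users])
        vals = np.clip(vals + rng.normal(0.0, 0.08, size=vals.size), 0.0, 1.0)
        return np.round(vals, 3)

    for model in spec.models:
        if model.n_measurements == 0:
            continue
        n = model.n_measurements
        cal = registry.calibration_for_model(model.model_name) or FALLBACK_PROFILE
        device_id = _device_id_for(model.model_name, registry)
        users = _user_block(n, model.n_users, model.model_name)
        user_shift = {
            u: float(rng.normal(0.0, spec.level_sd_db / 2)) for u in np.unique(users)
        }
        levels = np.clip(
            spec.level_mean_db
            + np.array([user_shift[u] for u in users])
            + rng.normal(0.0, spec.level_sd_db / 2, size=n),
            30.0,
            100.0,
        )
        samples = _simulate_sample_matrix(rng, levels, cal, spec.noise)
        stored = samples.mean(axis=1)  # legacy arithmetic mean, all 30 samples
        frames.append(
            pd.DataFrame(
                {
                    "entry_id": [f"e{entry_counter + i:06d}" for i in range(n)],
                    "user_id": users,
                    "device_id": device_id,
                    "platform": "android",
                    "timestamp": _timestamps(n),
                    "stored_amplitude": np.round(stored, 2),
                    "tinnitus_loudness": _loudness(users),
                }
            )
        )
        entry_counter += n

    for n, platform, device in (
        (spec.n_ios, "ios", None),
        (spec.n_no_user_agent, "unknown", None),
    ):
        if n == 0:
            continue
        n_users = max(1, n // 400)  # a few hundred entries per user, as observed
        users = _user_block(n, n_users, platform)
        frames.append(
            pd.DataFrame(
                {
                    "entry_id": [f"e{entry_counter + i:06d}" for i in range(n)],
                    "user_id": users,
                    "device_id": device,
                    "platform": platform,
                    "timestamp": _timestamps(n),
                    "stored_amplitude": np.nan,
                    "tinnitus_loudness": _loudness(users),
                }
            )
        )
        entry_counter += n

    if not frames:
        from .transform import ENTRY_COLUMNS

        return pd.DataFrame(columns=ENTRY_COLUMNS)
    return pd.concat(frames, ignore_index=True)
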
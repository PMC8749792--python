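"""Bulk transformation of stored crowdsensed amplitudes into dB(C), plus
dataset summaries and per-user plausibility screening.

The crowdsensed database stores, per questionnaire entry, a single averaged
amplitude value (Android), a relative dB value (iOS, not convertible here),
and the user-agent-derived device ID.  This module converts the Android
amplitudes to dB(C) through the device registry, labels every entry with an
explicit status (nothing is silently dropped), and reproduces the standard
dataset views: platform composition, per-model user/measurement counts, and
per-model level summaries.

Entries are handled as pandas DataFrames with the columns of
:class:`SoundEntry`; :func:`read_entries_csv` / :func:`write_entries_csv`
define the CSV interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .acoustics import energetic_mean_db
from .calibration import DeviceRegistry, amplitude_to_db, default_registry, is_extrapolated

__all__ = [
    "SoundEntry",
    "ENTRY_COLUMNS",
    "STATUSES",
    "CompositionReport",
    "transform_entries",
    "summarize_levels",
    "dataset_composition",
    "plausibility_screen",
    "read_entries_csv",
    "write_entries_csv",
]

ENTRY_COLUMNS = [
    "entry_id",
    "user_id",
    "device_id",
    "platform",
    "timestamp",
    "stored_amplitude",
    "tinnitus_loudness",
]

#: Mutually exclusive outcomes of the conversion; they partition the output.
STATUSES = ("converted", "non_android", "no_calibration", "invalid_amplitude")


@dataclass(frozen=True)
class SoundEntry:
    """One database record: who measured what, on which device, when.

    ``stored_amplitude`` is the legacy arithmetic-mean amplitude the app
    stored (Android only); ``tinnitus_loudness`` is the questionnaire's
    loudness slider in [0, 1].  Timestamps are carried as ISO-8601 text and
    never interpreted.
    """

    entry_id: str
    user_id: str
    platform: str = "android"
    device_id: Optional[str] = None
    timestamp: str = ""
    stored_amplitude: Optional[float] = None
    tinnitus_loudness: Optional[float] = None


def entries_to_frame(entries) -> pd.DataFrame:
    """Build the canonical entries DataFrame from SoundEntry records."""
    df = pd.DataFrame([e.__dict__ for e in entries], columns=ENTRY_COLUMNS)
    return df


def _as_frame(entries) -> pd.DataFrame:
    if isinstance(entries, pd.DataFrame):
        df = entries.copy()
        for col in ENTRY_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        return df
    return entries_to_frame(list(entries))


def transform_entries(
    entries, registry: Optional[DeviceRegistry] = None
) -> pd.DataFrame:
    """Convert stored amplitudes to dB(C); label every entry with a status.

    Every input entry appears exactly once in the output with columns
    ``model_name``, ``db_c``, ``status`` and ``extrapolated`` added:

    * ``converted`` — Android, device calibration known, amplitude >= 1;
      ``db_c`` holds the converted level and ``extrapolated`` marks levels
      outside the 50-80 dB(C) fitted range.
    * ``non_android`` — iOS or unknown platform (relative-dB values are not
      convertible by amplitude calibration).
    * ``no_calibration`` — Android, but the device ID is unknown or has no
      calibrated profile (checked before the amplitude: without a curve no
      amplitude could be converted anyway).
    * ``invalid_amplitude`` — Android with calibration, but the stored
      amplitude is missing or below 1 digital unit.
    """
    registry = registry if registry is not None else default_registry()
    df = _as_frame(entries)

    models: list[str] = []
    statuses: list[str] = []
    db_c: list[float] = []
    extrapolated: list[bool] = []
    cache: dict[str, tuple] = {}
    for platform, device_id, amplitude in zip(
        df["platform"], df["device_id"], df["stored_amplitude"]
    ):
        device_key = "" if pd.isna(device_id) else str(device_id)
        if device_key not in cache:
            cache[device_key] = registry.resolve(device_key)
        model, cal = cache[device_key]
        models.append(model)
        if pd.isna(platform) or platform != "android":
            statuses.append("non_android")
            db_c.append(np.nan)
            extrapolated.append(False)
        elif cal is None:
            statuses.append("no_calibration")
            db_c.append(np.nan)
            extrapolated.append(False)
        elif pd.isna(amplitude) or amplitude < 1:
            statuses.append("invalid_amplitude")
            db_c.append(np.nan)
            extrapolated.append(False)
        else:
            level = float(amplitude_to_db(float(amplitude), cal))
            statuses.append("converted")
            db_c.append(level)
            extrapolated.append(is_extrapolated(level))

    out = df
    out["model_name"] = models
    out["db_c"] = db_c
    out["status"] = statuses
    out["extrapolated"] = extrapolated
    return out


def summarize_levels(transformed: pd.DataFrame) -> pd.DataFrame:
    """Per-model min / max / average dB(C) over converted entries.

    Reports both the arithmetic mean of the per-entry levels and their
    energetic (Leq) mean; the two coincide only for constant levels, and the
    arithmetic mean is always the lower of the two.
    """
    conv = transformed[transformed["status"] == "converted"]
    rows = []
    for model, grp in conv.groupby("model_name", sort=False):
        levels = grp["db_c"].to_numpy(dtype=float)
        rows.append(
            {
                "model_name": model,
                "n_entries": len(levels),
                "db_c_min": float(np.min(levels)),
                "db_c_max": float(np.max(levels)),
                "db_c_avg": float(np.mean(levels)),
                "db_c_leq": float(energetic_mean_db(levels)),
            }
        )
    cols = ["model_name", "n_entries", "db_c_min", "db_c_max", "db_c_avg", "db_c_leq"]
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values("n_entries", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def _percent(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    share = Decimal(count) * 100 / Decimal(total)
    return float(share.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _round_half_up_int(x: float) -> int:
    return int(Decimal(repr(float(x))).quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionReport:
    """Dataset composition: platform shares and per-model usage counts."""

    platforms: pd.DataFrame
    models: pd.DataFrame
    n_total: int


def dataset_composition(
    entries, registry: Optional[DeviceRegistry] = None
) -> CompositionReport:
    """Platform counts/shares and per-model user & measurement counts.

    Platform percentages are rounded half-up to two decimals.  Device IDs are
    grouped under canonical model names through the registry (IDs the
    registry does not know keep the raw ID as their model name, matching how
    crowdsensing reports list unmapped user-agent strings); models are sorted
    descending by measurement count and the mean measurements per user is
    rounded half-up to the nearest integer.
    """
    registry = registry if registry is not None else default_registry()
    df = _as_frame(entries)
    n_total = len(df)

    platform = df["platform"].fillna("unknown")
    counts = {p: int((platform == p).sum()) for p in ("android", "ios", "unknown")}
    platforms = pd.DataFrame(
        [
            {"platform": p, "entries": c, "percent": _percent(c, n_total)}
            for p, c in counts.items()
        ]
    )

    android = df[(platform == "android") & df["device_id"].notna()].copy()
    cache: dict[str, str] = {}

    def canonical(device_id: str) -> str:
        if device_id not in cache:
            model, _ = registry.resolve(device_id)
            cache[device_id] = device_id if model == "unknown" else model
        return cache[device_id]

    android["model_name"] = [canonical(str(d)) for d in android["device_id"]]
    rows = []
    for model, grp in android.groupby("model_name", sort=False):
        n_users = int(grp["user_id"].nunique())
        n_meas = int(len(grp))
        rows.append(
            {
                "model_name": model,
                "n_users": n_users,
                "n_measurements": n_meas,
                "measurements_per_user": _round_half_up_int(n_meas / n_users)
                if n_users
                else 0,
            }
        )
    models = (
        pd.DataFrame(
            rows,
            columns=["model_name", "n_users", "n_measurements", "measurements_per_user"],
        )
        .sort_values("n_measurements", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return CompositionReport(platforms=platforms, models=models, n_total=n_total)


def plausibility_screen(entries, min_entries: int = 500) -> pd.DataFrame:
    """Per-user eligibility for longitudinal analysis.

    A user is eligible when they contributed more than ``min_entries``
    entries carrying a sound measurement AND both their tinnitus-loudness and
    stored-amplitude traces fluctuate plausibly (not all zero, not constant).
    Traces with fewer than two distinct observed values count as constant.
    """
    df = _as_frame(entries)
    rows = []
    for user, grp in df.groupby("user_id", sort=False):
        amp = grp["stored_amplitude"].dropna()
        loud = grp["tinnitus_loudness"].dropna()
        n_sound = int(len(amp))
        amp_zero = bool(len(amp) > 0 and (amp == 0).all())
        amp_const = bool(amp.nunique() <= 1)
        loud_zero = bool(len(loud) > 0 and (loud == 0).all())
        loud_const = bool(loud.nunique() <= 1)
        eligible = (
            n_sound > min_entries
            and not (amp_zero or amp_const or loud_zero or loud_const)
        )
        rows.append(
            {
                "user_id": user,
                "n_sound_entries": n_sound,
                "amplitude_all_zero": amp_zero,
                "amplitude_constant": amp_const,
                "loudness_all_zero": loud_zero,
                "loudness_constant": loud_const,
                "eligible": eligible,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "user_id",
            "n_sound_entries",
            "amplitude_all_zero",
            "amplitude_constant",
            "loudness_all_zero",
            "loudness_constant",
            "eligible",
        ],
    )


# ---------------------------------------------------------------------------
# CSV interchange


def read_entries_csv(path) -> pd.DataFrame:
    """Read an entries CSV (comma, header, UTF-8) into the canonical frame.

    Raises a ValueError naming the offending line on malformed input.
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"entry_id": str, "user_id": str, "device_id": str, "platform": str},
        )
    except pd.errors.ParserError as exc:  # surface the line number
        raise ValueError(f"unreadable entries file {path}: {exc}") from exc
    missing = [c for c in ("entry_id", "user_id", "platform") if c not in df.columns]
    if missing:
        raise ValueError(f"entries file {path} lacks required columns {missing}")
    return _as_frame(df)


def write_entries_csv(entries: pd.DataFrame, path) -> None:
    """Write entries (or transformed entries) as CSV."""
    entries.to_csv(path, index=False)
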
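"""Model of the app's 15 s sound measurement and its two averaging pathways.

The mobile app polls the recorder's maximum absolute amplitude every 500 ms
for a total of 30 values.  Two pathways turn a series into one number:

* ``legacy_average`` — the arithmetic mean of all 30 raw amplitudes, exactly
  as the deployed app stored it.  Averaging in the amplitude domain and then
  taking the logarithm understates the level whenever the series fluctuates.
* ``corrected_average`` — discard the first two samples (a consistent
  recorder warm-up artifact: the first poll returns 0 and the second is
  depressed), convert each retained sample to dB(C) with the device's
  calibration, and take the energetic (Leq) mean of those levels.

Both are exposed so audits can quantify their gap on identical input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acoustics import SoundLevel, energetic_mean_db
from .calibration import DeviceCalibration, InvalidAmplitudeError, amplitude_to_db

__all__ = [
    "AmplitudeSeries",
    "StartupArtifactReport",
    "legacy_average",
    "corrected_average",
    "detect_startup_artifact",
    "read_series_csv",
    "write_series_csv",
    "STANDARD_LENGTH",
    "DEFAULT_DISCARD",
]

#: Samples per measurement: one per 500 ms over 15 s.
STANDARD_LENGTH: int = 30
#: Number of startup samples excluded by the corrected pathway.
DEFAULT_DISCARD: int = 2


@dataclass(frozen=True)
class AmplitudeSeries:
    """One measurement: an ordered series of non-negative integer amplitudes.

    ``n_discard`` records how many leading startup samples the corrected
    pathway drops for this series (0 or 2).  Series of nonstandard length are
    accepted with a warning, since experiment builds and the deployed app
    differ in effective sample count.
    """

    samples: np.ndarray
    device_id: str = ""
    n_discard: int = DEFAULT_DISCARD

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if np.any(samples < 0):
            raise ValueError("amplitudes must be >= 0")
        if self.n_discard not in (0, 2):
            raise ValueError(f"n_discard must be 0 or 2, got {self.n_discard}")
        if samples.size != STANDARD_LENGTH:
            warnings.warn(
                f"series has {samples.size} samples, expected {STANDARD_LENGTH}",
                stacklevel=3,
            )
        object.__setattr__(self, "samples", samples.astype(float))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def retained(self) -> np.ndarray:
        """Samples kept by the corrected pathway (startup samples dropped)."""
        return self.samples[self.n_discard :]


def legacy_average(series: AmplitudeSeries) -> float:
    """Arithmetic mean of all samples — the value the deployed app stored.

    Includes the startup-artifact samples and averages in the amplitude
    domain; both behaviors are faithful to the original code and are what
    the error audit quantifies.
    """
    return float(np.mean(series.samples))


def corrected_average(series: AmplitudeSeries, cal: DeviceCalibration) -> SoundLevel:
    """Leq of the per-sample dB(C) levels after discarding startup samples.

    Raises
    ------
    ValueError
        If no samples remain after the discard.
    InvalidAmplitudeError
        If any retained sample is below 1 digital unit (dB conversion is not
        meaningful on the integer recorder scale there); the message lists
        the offending sample indices.
    """
    retained = series.retained
    if retained.size == 0:
        raise ValueError("no samples remain after discarding startup samples")
    bad = np.nonzero(retained < 1)[0] + series.n_discard
    if bad.size:
        raise InvalidAmplitudeError(
            f"retained samples < 1 at indices {bad.tolist()}; "
            "cannot convert to dB"
        )
    levels = [amplitude_to_db(x, cal) for x in retained]
    return energetic_mean_db(levels)


@dataclass(frozen=True)
class StartupArtifactReport:
    """Flags for the recorder warm-up pattern in a series' first second."""

    first_sample_zero: bool
    second_sample_low: bool
    flagged_indices: tuple[int, ...]
    reference_median: float

    @property
    def any(self) -> bool:
        return self.first_sample_zero or self.second_sample_low


def detect_startup_artifact(series: AmplitudeSeries) -> StartupArtifactReport:
    """Detect the warm-up artifact: first sample 0, second sample depressed.

    The second sample is flagged when it falls below half the median of the
    steady-state samples (index 2 onward) — a concrete threshold for the
    empirically observed "often too low" pattern.  Detection only flags; it
    never repairs the series.
    """
    s = series.samples
    ref = float(np.median(s[2:])) if s.size > 2 else float("nan")
    first = bool(s[0] == 0)
    second = bool(s.size > 2 and ref == ref and s[1] < 0.5 * ref)
    flagged = tuple(i for i, f in ((0, first), (1, second)) if f)
    return StartupArtifactReport(
        first_sample_zero=first,
        second_sample_low=second,
        flagged_indices=flagged,
        reference_median=ref,
    )


# ---------------------------------------------------------------------------
# Raw-series CSV interchange (entry_id, device_id, sample_index, amplitude)


def read_series_csv(path) -> dict[str, AmplitudeSeries]:
    """Read raw series from CSV into a dict keyed by entry_id.

    Expects columns ``entry_id, device_id, sample_index, amplitude`` with a
    0-based sample index; samples are sorted by index per entry.
    """
    df = pd.read_csv(path, dtype={"entry_id": str, "device_id": str})
    out: dict[str, AmplitudeSeries] = {}
    for entry_id, grp in df.groupby("entry_id", sort=False):
        grp = grp.sort_values("sample_index")
        device = grp["device_id"].iloc[0] if "device_id" in grp else ""
        out[str(entry_id)] = AmplitudeSeries(
            samples=grp["amplitude"].to_numpy(), device_id=str(device)
        )
    return out


def write_series_csv(series_map: dict[str, AmplitudeSeries], path) -> None:
    """Inverse of :func:`read_series_csv`."""
    rows = []
    for entry_id, series in series_map.items():
        for i, amp in enumerate(series.samples):
            rows.append((entry_id, series.device_id, i, int(amp)))
    pd.DataFrame(
        rows, columns=["entry_id", "device_id", "sample_index", "amplitude"]
    ).to_csv(path, index=False)
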
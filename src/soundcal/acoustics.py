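"""Core decibel mathematics: sound pressure level and energetic (Leq) averaging.

Sound levels are logarithmic: a level ``L`` in dB relates to a root-mean-square
pressure ``p`` via ``L = 20 * log10(p / p0)`` with the standard reference
pressure ``p0 = 20 uPa``.  Because of this, levels cannot be averaged
arithmetically; the equivalent continuous level over equal-duration samples is
the *energetic* mean, ``10 * log10(mean(10**(L_i / 10)))``, which always lies
at or above the arithmetic mean of the levels.

Frequency weightings (A, C) are carried as metadata tags only: at 1000 Hz the
A- and C-weighting curves both apply a 0 dB offset, so dB_SPL, dB(A) and dB(C)
coincide there and a pure-tone experiment at 1000 Hz fixes all three at once.
No filter curves are implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "P0",
    "Weighting",
    "SoundPressure",
    "SoundLevel",
    "MixedWeightingError",
    "spl_from_pressure",
    "pressure_from_spl",
    "energetic_mean_db",
    "round_db",
]

#: Reference sound pressure, 20 micropascal (2e-5 Pa).
P0: float = 2e-5


class Weighting(str, Enum):
    """Frequency-weighting tag of a sound level.

    ``SPL`` denotes the unweighted sound pressure level.  At 1000 Hz the three
    tags are interchangeable (both A- and C-weighting are 0 dB there).
    """

    SPL = "SPL"
    A = "A"
    C = "C"


class MixedWeightingError(ValueError):
    """Raised when levels with different weighting tags are averaged."""


@dataclass(frozen=True)
class SoundPressure:
    """Root-mean-square sound pressure in pascal; strictly positive."""

    p: float

    def __post_init__(self) -> None:
        if not (self.p > 0) or not math.isfinite(self.p):
            raise ValueError(f"sound pressure must be finite and > 0, got {self.p}")


@dataclass(frozen=True)
class SoundLevel:
    """A sound level in decibel with its frequency-weighting tag.

    Parameters
    ----------
    value:
        Level in dB; must be finite.
    weighting:
        Frequency-weighting tag (default C, the weighting used throughout the
        calibration experiments).
    """

    value: float
    weighting: Weighting = Weighting.C

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"sound level must be finite, got {self.value}")
        # accept bare strings like "C" for convenience
        object.__setattr__(self, "weighting", Weighting(self.weighting))

    def __float__(self) -> float:
        return float(self.value)


def _as_value(level: SoundLevel | float) -> float:
    return float(level)


def spl_from_pressure(p: SoundPressure | float) -> SoundLevel:
    """Sound pressure level ``20 * log10(p / p0)`` in dB re 20 uPa.

    Parameters
    ----------
    p:
        RMS sound pressure in Pa (``SoundPressure`` or a bare positive float).

    Returns
    -------
    SoundLevel
        The unweighted level (tag ``SPL``).
    """
    value = p.p if isinstance(p, SoundPressure) else float(p)
    if not (value > 0):
        raise ValueError(f"sound pressure must be > 0, got {value}")
    return SoundLevel(20.0 * math.log10(value / P0), Weighting.SPL)


def pressure_from_spl(level: SoundLevel | float) -> SoundPressure:
    """Inverse of :func:`spl_from_pressure`: ``p = p0 * 10**(L / 20)``."""
    return SoundPressure(P0 * 10.0 ** (_as_value(level) / 20.0))


def energetic_mean_db(
    levels: Sequence[SoundLevel | float] | Iterable[SoundLevel | float],
) -> SoundLevel:
    """Equivalent continuous level (Leq) of equal-duration level samples.

    Computes ``10 * log10(mean(10**(L_i / 10)))``, i.e. the levels are taken
    back to their energetic source values (relative power), averaged, and
    re-expressed in dB.  This is the correct way to average sound levels; the
    arithmetic mean of dB values systematically understates loudness.

    Parameters
    ----------
    levels:
        Non-empty sequence of levels.  ``SoundLevel`` items must share one
        weighting tag; bare floats are accepted and inherit that tag (or dB(C)
        if all inputs are floats).

    Raises
    ------
    ValueError
        If the sequence is empty.
    MixedWeightingError
        If ``SoundLevel`` items carry different weighting tags.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("cannot average an empty list of levels")
    tags = {lv.weighting for lv in levels if isinstance(lv, SoundLevel)}
    if len(tags) > 1:
        raise MixedWeightingError(f"mixed weighting tags: {sorted(t.value for t in tags)}")
    weighting = tags.pop() if tags else Weighting.C
    values = np.asarray([_as_value(lv) for lv in levels], dtype=float)
    mean_power = float(np.mean(10.0 ** (values / 10.0)))
    return SoundLevel(10.0 * math.log10(mean_power), weighting)


def round_db(value: SoundLevel | float, decimals: int = 1) -> float:
    """Round a level for display, half-up, to `decimals` places (default 0.1 dB).

    Internal computations keep full precision; rounding to the 0.1 dB
    resolution of a class-2 sound level meter happens only at presentation.
    Python's built-in banker's rounding would round e.g. 55.85 to 55.8, which
    does not match how instrument readouts are reported.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(_as_value(value))).quantize(quantum, rounding=ROUND_HALF_UP))
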
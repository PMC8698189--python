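"""Five-sieve particle-size model for total mixed rations.

The modified Penn State Particle Separator used here stacks five sieves with
square holes of diagonal 38.1, 19.1, 7.9, 3.8 and 1.8 mm over a bottom pan.
Each stratum is summarised by a geometric midpoint length (mm); the geometric
mean particle length (GMPL) of a sample is the exponential of the
fraction-weighted mean log midpoint.  The physical-effectiveness factor (pef)
is the mass proportion with particle length >= 4 mm, i.e. everything retained
on the fourth sieve or above, and physically effective NDF is
``peNDF = aNDF * pef``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InputValidationError, ParameterError

#: Sieve names in coarse-to-fine stacking order.
SIEVE_NAMES = ("s1", "s2", "s3", "s4", "s5", "bottom")

#: Square-hole diagonals of the five sieves, mm (pan has none).
SIEVE_DIAGONALS_MM = (38.1, 19.1, 7.9, 3.8, 1.8)

#: Geometric midpoint length of each stratum, mm, pan included.
STRATUM_MIDPOINTS_MM = (48.0, 38.04, 17.32, 7.73, 3.69, 0.90)

_LOG_MIDPOINTS = np.log(STRATUM_MIDPOINTS_MM)

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class SieveFractions:
    """Percent of wet sample mass retained per stratum (S1..S5 + pan).

    Values are percentages; a normalised instance sums to 100 within 1e-6.
    """

    s1: float
    s2: float
    s3: float
    s4: float
    s5: float
    bottom: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4, self.s5, self.bottom], dtype=float)

    @classmethod
    def from_array(cls, values) -> "SieveFractions":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ParameterError("sieve fractions need exactly six values (S1..S5, bottom)")
        return cls(*values)

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.as_array().sum()) - 100.0) <= _SUM_TOL


@dataclass(frozen=True)
class ParticleSummary:
    """Derived particle-size quantities for one sample.

    gmpl      geometric mean particle length, mm
    s4_cum    mass retained on the 3.8 mm sieve, % (S4)
    c5        S4 + S5 cumulative mass, %
    cb        S4 + S5 + bottom cumulative mass, %
    pef       physical-effectiveness factor, proportion of mass >= 4 mm
    pendf     physically effective NDF, % of DM (None until aNDF is supplied)
    """

    gmpl: float
    s4_cum: float
    c5: float
    cb: float
    pef: float
    pendf: float | None = field(default=None)


def _check_raw(raw: np.ndarray) -> None:
    if raw.shape != (6,):
        raise ParameterError("expected six sieve fractions (S1..S5, bottom)")
    if not np.all(np.isfinite(raw)):
        raise InputValidationError("sieve fractions must be finite")
    if np.any(raw < 0):
        raise InputValidationError("sieve fractions must be nonnegative")
    if raw.sum() <= 0:
        raise DegenerateInputError("all-zero sieve fractions cannot be normalised")


def average_sievings(*replicates) -> np.ndarray:
    """Mean of duplicate sievings, taken before normalisation.

    Replicate sieving of the same (undried) sample is routine; replicates are
    averaged stratum-wise first and the average is then rescaled to 100%.
    """
    if not replicates:
        raise ParameterError("at least one sieving replicate required")
    stack = np.vstack([np.asarray(r, dtype=float) for r in replicates])
    for row in stack:
        _check_raw(row)
    return stack.mean(axis=0)


def normalize_fractions(raw) -> SieveFractions:
    """Proportionally rescale six nonnegative strata so they sum to 100.

    Order is preserved; already-normalised input is returned unchanged
    (the operation is idempotent).
    """
    raw = np.asarray(raw, dtype=float)
    _check_raw(raw)
    return SieveFractions.from_array(raw * (100.0 / raw.sum()))


def _require_normalized(f: SieveFractions) -> np.ndarray:
    arr = f.as_array()
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise InputValidationError("sieve fractions must be finite and nonnegative")
    if abs(arr.sum() - 100.0) > _SUM_TOL:
        raise InputValidationError(
            f"fractions must be normalised to 100% (got sum {arr.sum():.6f}); "
            "call normalize_fractions first"
        )
    return arr


def gmpl(f: SieveFractions) -> float:
    """Geometric mean particle length, mm.

    ``exp( sum_j p_j * ln(m_j) )`` with ``p_j`` the stratum proportions
    (percent / 100) and ``m_j`` the stratum midpoints
    (48, 38.04, 17.32, 7.73, 3.69, 0.90 mm).  Bounded by the extreme
    midpoints, 0.90 and 48 mm.
    """
    arr = _require_normalized(f)
    return float(math.exp(float((arr / 100.0) @ _LOG_MIDPOINTS)))


def cumulative_and_pef(f: SieveFractions) -> ParticleSummary:
    """Cumulative lower-strata fractions and the physical-effectiveness factor.

    s4_cum = S4; c5 = S4 + S5; cb = S4 + S5 + bottom.  pef is the proportion
    of mass with length >= 4 mm: the 3.8 mm sieve is the separator's "4 mm"
    screen, so S1..S4 count as physically effective.
    """
    arr = _require_normalized(f)
    s4_cum = float(arr[3])
    c5 = float(arr[3] + arr[4])
    cb = float(arr[3] + arr[4] + arr[5])
    pef = float(arr[:4].sum() / 100.0)
    return ParticleSummary(gmpl=gmpl(f), s4_cum=s4_cum, c5=c5, cb=cb, pef=pef)


def pendf(andf_pct_dm: float, pef: float) -> float:
    """Physically effective NDF, % of DM: ``aNDF * pef``."""
    if not (0.0 <= pef <= 1.0):
        raise ParameterError(f"pef must lie in [0, 1], got {pef}")
    if not np.isfinite(andf_pct_dm) or andf_pct_dm < 0:
        raise ParameterError(f"aNDF must be finite and nonnegative, got {andf_pct_dm}")
    return float(andf_pct_dm * pef)


def particle_summary(raw_fractions, andf_pct_dm: float | None = None) -> ParticleSummary:
    """Convenience wrapper: normalise -> GMPL + cumulatives + pef (+ peNDF)."""
    f = normalize_fractions(raw_fractions)
    summary = cumulative_and_pef(f)
    if andf_pct_dm is not None:
        summary = ParticleSummary(
            gmpl=summary.gmpl,
            s4_cum=summary.s4_cum,
            c5=summary.c5,
            cb=summary.cb,
            pef=summary.pef,
            pendf=pendf(andf_pct_dm, summary.pef),
        )
    return summary
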
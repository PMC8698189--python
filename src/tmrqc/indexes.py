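"""Homogeneity and Sorting indexes for distributed TMR batches.

A distribution event is sampled at 16 points along the feeding alley,
immediately after unloading (``fresh``) and optionally again 2 h later at the
same points (``later``).  Seven index traits are tracked per point: the S4,
S5 and bottom sieve fractions (% w/w wet), GMPL (mm), and CP, aNDF and starch
(% of DM).

Homogeneity index (Hi, 0-100%, 100 = perfect homogeneity): per trait, points
outside mean +/- 2 SD are discarded, the coefficient of variation
``CV = 100 * sd / mean`` is compared with a maximal acceptable CV, and the
trait scores ``s = min(1, acceptable_cv / CV)``.  Hi is the weighted sum of
the trait scores with integer weights summing to 100.

Sorting index (Si, 0-1, 1 = total sorting): per trait, a two-sided two-sample
Student t-test compares fresh vs +2 h points; the p-value is mapped through a
fixed piecewise-constant grid (1.0 for p <= 0.01 down to 0.0 for p > 0.5),
the grid scores are weighted exactly as for Hi and the weighted sum is
divided by 100.

Batches classify as homogeneous (Hbhi) when Hi > 79% and as showing evident
selection (ESbsi) when Si > 0.30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InputValidationError,
    NotComputableError,
    ParameterError,
)

#: Trait order, weights and maximal acceptable CVs (%) for the index traits.
DEFAULT_TRAIT_SPECS: tuple["IndexTraitSpec", ...]

HI_THRESHOLD = 79.0      # Hi <= 79 %  -> inhomogeneous (Ibhi)
SI_THRESHOLD = 0.30      # Si <= 0.30  -> negligible selection (NSbsi)

#: p-value grid: (upper bound, score); intervals are left-open/right-closed.
P_GRID = ((0.01, 1.0), (0.05, 0.5), (0.10, 0.4), (0.20, 0.2), (0.50, 0.1), (1.0, 0.0))


@dataclass(frozen=True)
class IndexTraitSpec:
    """Weight and maximal acceptable CV (%) for one index trait."""

    trait: str
    weight: int
    acceptable_cv: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ParameterError("trait weight must be positive")
        if self.acceptable_cv <= 0:
            raise ParameterError("acceptable CV must be positive")


DEFAULT_TRAIT_SPECS = (
    IndexTraitSpec("S4", 8, 3.0),
    IndexTraitSpec("S5", 22, 3.0),
    IndexTraitSpec("bottom", 22, 5.0),
    IndexTraitSpec("GMPL", 20, 10.0),
    IndexTraitSpec("CP", 10, 3.0),
    IndexTraitSpec("aNDF", 9, 3.0),
    IndexTraitSpec("starch", 9, 3.0),
)

TRAIT_NAMES = tuple(s.trait for s in DEFAULT_TRAIT_SPECS)


def _check_specs(specs: Sequence[IndexTraitSpec]) -> None:
    total = sum(s.weight for s in specs)
    if total != 100:
        raise ParameterError(f"trait weights must sum to 100, got {total}")


@dataclass
class AlleyBatch:
    """Point measurements of the index traits for one distribution event.

    ``fresh`` (and optionally ``later``) are DataFrames with one row per
    sampling point and one column per index trait.
    """

    fresh: pd.DataFrame
    later: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fresh = self._check_frame(self.fresh, "fresh")
        if self.later is not None:
            self.later = self._check_frame(self.later, "later")

    @staticmethod
    def _check_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
        df = pd.DataFrame(df)
        missing = [t for t in TRAIT_NAMES if t not in df.columns]
        if missing:
            raise InputValidationError(f"{name} table lacks trait columns {missing}")
        if len(df) < 3:
            raise InputValidationError(f"{name} table needs at least 3 points")
        values = df[list(TRAIT_NAMES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise InputValidationError(f"{name} table contains non-finite values")
        return df


@dataclass
class IndexResult:
    """Hi/Si values, binary classes, and per-trait diagnostics for one batch."""

    hi: float
    si: float | None
    hi_class: str
    si_class: str | None
    hi_diagnostics: pd.DataFrame | None = None
    si_diagnostics: pd.DataFrame | None = None


def trim_outlier_points(values) -> np.ndarray:
    """Single-pass +/- 2 SD trim of point values.

    Mean and SD are computed on the full vector; values strictly outside
    mean +/- 2 SD are removed (boundary values are retained).  No
    re-iteration.  Raises if fewer than 3 values survive.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise DegenerateInputError("need at least 3 finite point values")
    if not np.all(np.isfinite(values)):
        raise InputValidationError("point values must be finite")
    mu, sd = values.mean(), values.std(ddof=1)
    kept = values[np.abs(values - mu) <= 2.0 * sd]
    if len(kept) < 3:
        raise DegenerateInputError("fewer than 3 points survive the +/-2 SD trim")
    return kept


def default_trait_score(cv: float, acceptable_cv: float) -> float:
    """Trait homogeneity score: 1 when CV is within the acceptable ratio,
    otherwise the acceptable ratio over the observed CV."""
    if cv <= acceptable_cv:
        return 1.0
    return acceptable_cv / cv


def homogeneity_index(
    batch: AlleyBatch,
    specs: Sequence[IndexTraitSpec] = DEFAULT_TRAIT_SPECS,
    score_fn: Callable[[float, float], float] = default_trait_score,
) -> tuple[float, pd.DataFrame]:
    """Homogeneity index over the fresh point samples.

    Returns ``(hi, diagnostics)``; diagnostics carry per-trait CV, points
    removed, and score.  The trait score function is pluggable (default
    ``min(1, acceptable_cv / CV)``).
    """
    _check_specs(specs)
    rows = []
    hi = 0.0
    for spec in specs:
        points = batch.fresh[spec.trait].to_numpy(dtype=float)
        kept = trim_outlier_points(points)
        mean = kept.mean()
        if mean <= 0:
            raise DegenerateInputError(f"trait {spec.trait!r} has nonpositive mean")
        cv = 100.0 * kept.std(ddof=1) / mean
        score = float(score_fn(cv, spec.acceptable_cv))
        hi += spec.weight * score
        rows.append({
            "trait": spec.trait,
            "n_used": len(kept),
            "n_removed": len(points) - len(kept),
            "cv_pct": cv,
            "acceptable_cv_pct": spec.acceptable_cv,
            "score": score,
            "weight": spec.weight,
        })
    return float(hi), pd.DataFrame(rows).set_index("trait")


def p_to_grid(p: float) -> float:
    """Map a t-test p-value to the discrete sorting grid.

    Left-open/right-closed bins: (0,0.01] -> 1.0, (0.01,0.05] -> 0.5,
    (0.05,0.10] -> 0.4, (0.10,0.20] -> 0.2, (0.20,0.50] -> 0.1, (0.50,1] -> 0.
    """
    if not np.isfinite(p) or p < 0.0 or p > 1.0:
        raise ParameterError(f"p-value must lie in [0, 1], got {p}")
    for upper, score in P_GRID:
        if p <= upper:
            return score
    return 0.0


def sorting_index_from_pvalues(
    pvalues: dict[str, float], specs: Sequence[IndexTraitSpec] = DEFAULT_TRAIT_SPECS
) -> tuple[float, pd.DataFrame]:
    """Sorting index from per-trait fresh-vs-2 h p-values.

    ``Si = sum(weight * grid(p)) / 100``; always in [0, 1].
    """
    _check_specs(specs)
    rows = []
    total = 0.0
    for spec in specs:
        if spec.trait not in pvalues:
            raise ParameterError(f"missing p-value for trait {spec.trait!r}")
        p = float(pvalues[spec.trait])
        g = p_to_grid(p)
        total += spec.weight * g
        rows.append({"trait": spec.trait, "p_value": p, "grid": g, "weight": spec.weight})
    return float(total / 100.0), pd.DataFrame(rows).set_index("trait")


def sorting_index(
    batch: AlleyBatch,
    specs: Sequence[IndexTraitSpec] = DEFAULT_TRAIT_SPECS,
    paired: bool = False,
    trim_later: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Sorting index from fresh vs +2 h point samples.

    Per trait: each time set is trimmed (+/- 2 SD, independently; disable the
    +2 h trim with ``trim_later=False``), a two-sided equal-variance
    two-sample Student t-test compares the sets (``paired=True`` switches to
    a paired test over positionally matched points), and the p-value goes
    through :func:`p_to_grid`.  Identical sets (zero pooled variance) carry
    no evidence of sorting and score 0.
    """
    if batch.later is None:
        raise NotComputableError("sorting index requires the +2 h resampling")
    _check_specs(specs)
    pvals = {}
    for spec in specs:
        fresh = batch.fresh[spec.trait].to_numpy(dtype=float)
        later = batch.later[spec.trait].to_numpy(dtype=float)
        with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
            # near-identical sets trip scipy's precision-loss warning; their
            # p is NaN and scored as no evidence of sorting below
            warnings.simplefilter("ignore", RuntimeWarning)
            if paired:
                if len(fresh) != len(later):
                    raise InputValidationError("paired test needs matched point counts")
                p = stats.ttest_rel(fresh, later).pvalue
            else:
                f_t = trim_outlier_points(fresh)
                l_t = trim_outlier_points(later) if trim_later else later
                p = stats.ttest_ind(f_t, l_t, equal_var=True).pvalue
        pvals[spec.trait] = 1.0 if not np.isfinite(p) else float(p)
    return sorting_index_from_pvalues(pvals, specs)


def classify(hi: float, si: float | None) -> tuple[str, str | None]:
    """Binary classes: Hbhi iff Hi > 79 %; ESbsi iff Si > 0.30."""
    hi_class = "Hbhi" if hi > HI_THRESHOLD else "Ibhi"
    si_class = None if si is None else ("ESbsi" if si > SI_THRESHOLD else "NSbsi")
    return hi_class, si_class


def evaluate_batch(
    batch: AlleyBatch,
    specs: Sequence[IndexTraitSpec] = DEFAULT_TRAIT_SPECS,
    **sorting_kwargs,
) -> IndexResult:
    """Hi, Si (when the +2 h set exists) and their binary classes for a batch."""
    hi, hi_diag = homogeneity_index(batch, specs)
    if batch.later is not None:
        si, si_diag = sorting_index(batch, specs, **sorting_kwargs)
    else:
        si, si_diag = None, None
    hi_class, si_class = classify(hi, si)
    return IndexResult(
        hi=hi, si=si, hi_class=hi_class, si_class=si_class,
        hi_diagnostics=hi_diag, si_diagnostics=si_diag,
    )
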
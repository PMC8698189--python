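"""NIRS chemometrics: pretreatment, PLS calibration and validation metrics.

The calibration workflow mirrors common portable-NIRS practice on fresh,
unground TMR: spectra on a 902-1660 nm grid are pretreated (SNV, detrend,
Savitzky-Golay smoothing / first derivative), the sample set is split 55/45
into calibration and validation per trait, and a PLS model with at most 10
factors is fitted on the calibration set with two cross-validation passes
separated by outlier elimination (score-space Mahalanobis distance and
Cook's D).  The factor count minimises the cross-validated RMSE.

Validation reports the usual chemometric metric suite: R2 and RMSE in both
cross-validation and validation, an F-value (explained over residual
variance), the skew (slope of the predicted-vs-actual line, ideal 1), and GH
(mean squared Mahalanobis distance of validation scores in the calibration
score space, per factor).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .errors import DegenerateInputError, InputValidationError, ParameterError

WAVELENGTH_MIN_NM = 902.0
WAVELENGTH_MAX_NM = 1660.0


# ---------------------------------------------------------------------------
# Spectrum container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """One scan: shared wavelength grid (nm) plus an absorbance vector."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or ab.shape != wl.shape:
            raise InputValidationError("wavelengths and absorbance must be equal-length 1-D vectors")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise InputValidationError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise InputValidationError("wavelength grid must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN_NM - 1e-9 or wl[-1] > WAVELENGTH_MAX_NM + 1e-9:
            raise InputValidationError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def with_absorbance(self, ab: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavelengths, ab, self.sample_id)


# ---------------------------------------------------------------------------
# Pretreatments (pure: never mutate their input)
# ---------------------------------------------------------------------------

def _snv_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        raise DegenerateInputError("SNV undefined for a constant spectrum")
    return (X - X.mean(axis=-1, keepdims=True)) / sd


def snv(s: Spectrum) -> Spectrum:
    """Standard Normal Variate: centre each spectrum and scale to unit SD.

    Removes additive and multiplicative scatter offsets; output has mean 0
    and sample standard deviation 1.
    """
    return s.with_absorbance(_snv_matrix(s.absorbance[None, :])[0])


def _detrend_matrix(X: np.ndarray, wavelengths: np.ndarray, degree: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if degree < 0:
        raise ParameterError("detrend degree must be >= 0")
    if X.shape[-1] <= degree + 1:
        raise DegenerateInputError(
            f"detrend of degree {degree} needs more than {degree + 1} points"
        )
    # orthonormal polynomial basis in the wavelength coordinate
    u = (wavelengths - wavelengths.mean()) / (np.ptp(wavelengths) / 2.0)
    basis = np.polynomial.polynomial.polyvander(u, degree)
    q, _ = np.linalg.qr(basis)
    return X - (X @ q) @ q.T


def detrend(s: Spectrum, degree: int = 2) -> Spectrum:
    """Residual after a least-squares polynomial fit of absorbance on wavelength."""
    return s.with_absorbance(_detrend_matrix(s.absorbance[None, :], s.wavelengths, degree)[0])


def _savgol_matrix(
    X: np.ndarray, wavelengths: np.ndarray, window: int, poly: int, deriv_order: int
) -> np.ndarray:
    if window % 2 == 0 or window < 3:
        raise ParameterError("Savitzky-Golay window must be an odd integer >= 3")
    if not (window > poly >= deriv_order >= 0):
        raise ParameterError("require window > poly >= deriv_order >= 0")
    if deriv_order > 1:
        raise ParameterError("only smoothing (0) and first derivative (1) are supported")
    X = np.asarray(X, dtype=float)
    if X.shape[-1] < window:
        raise DegenerateInputError("spectrum shorter than the filter window")
    delta = float(np.mean(np.diff(wavelengths)))
    # mode="interp" refits the polynomial on truncated edge windows, preserving length
    return savgol_filter(X, window, poly, deriv=deriv_order, delta=delta, axis=-1, mode="interp")


def smooth_and_derivative(
    s: Spectrum, window: int = 7, poly: int = 2, deriv_order: int = 0
) -> Spectrum:
    """Savitzky-Golay smoothing (deriv_order=0) or first derivative (1).

    The derivative is taken with respect to wavelength (units: absorbance/nm).
    Edges are handled by refitting the local polynomial on truncated windows
    so the vector length is preserved.
    """
    return s.with_absorbance(
        _savgol_matrix(s.absorbance[None, :], s.wavelengths, window, poly, deriv_order)[0]
    )


class PretreatmentChain:
    """Ordered, serialisable chain of pretreatment steps.

    Steps are ("snv", {}), ("detrend", {"degree": d}) or
    ("savgol", {"window": w, "poly": p, "deriv_order": o}); application order
    matters and every step is pure.
    """

    _STEPS = ("snv", "detrend", "savgol")

    def __init__(self, steps: Sequence[tuple[str, dict]] = ()):
        for name, params in steps:
            if name not in self._STEPS:
                raise ParameterError(f"unknown pretreatment step {name!r}")
            dict(params)  # must be mapping-like
        self.steps = [(name, dict(params)) for name, params in steps]

    @classmethod
    def default(cls) -> "PretreatmentChain":
        """SNV -> quadratic detrend -> Savitzky-Golay first derivative (w=7, p=2)."""
        return cls([
            ("snv", {}),
            ("detrend", {"degree": 2}),
            ("savgol", {"window": 7, "poly": 2, "deriv_order": 1}),
        ])

    def apply_matrix(self, X: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        wavelengths = np.asarray(wavelengths, dtype=float)
        for name, params in self.steps:
            if name == "snv":
                X = _snv_matrix(X)
            elif name == "detrend":
                X = _detrend_matrix(X, wavelengths, params.get("degree", 2))
            elif name == "savgol":
                X = _savgol_matrix(
                    X,
                    wavelengths,
                    params.get("window", 7),
                    params.get("poly", 2),
                    params.get("deriv_order", 0),
                )
        return X

    def apply(self, s: Spectrum) -> Spectrum:
        return s.with_absorbance(self.apply_matrix(s.absorbance[None, :], s.wavelengths)[0])

    def to_list(self) -> list:
        return [[name, dict(params)] for name, params in self.steps]

    @classmethod
    def from_list(cls, data) -> "PretreatmentChain":
        return cls([(name, dict(params)) for name, params in data])


# ---------------------------------------------------------------------------
# Calibration / validation split
# ---------------------------------------------------------------------------

def split_calibration_validation(
    n_samples: int, fraction_cal: float = 0.55, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive split into calibration and validation indices.

    ``|c| = floor(fraction_cal * n + 0.5)`` (round half up).  Deterministic
    under ``seed``; call once per trait to emulate trait-specific validation
    sets.
    """
    if n_samples < 10:
        raise ParameterError("need at least 10 samples to split")
    if not (0.0 < fraction_cal < 1.0):
        raise ParameterError("fraction_cal must lie in (0, 1)")
    ncal = int(np.floor(fraction_cal * n_samples + 0.5))
    perm = np.random.default_rng(seed).permutation(n_samples)
    return np.sort(perm[:ncal]), np.sort(perm[ncal:])


# ---------------------------------------------------------------------------
# Outlier diagnostics
# ---------------------------------------------------------------------------

def cooks_d(t, h, k: int):
    """Cook's distance from studentized residual(s) t, leverage(s) h and k model variables.

    ``D = t^2 * h / ((k + 1) * (1 - h))``.
    """
    t = np.asarray(t, dtype=float)
    h = np.asarray(h, dtype=float)
    if k < 1:
        raise ParameterError("k must be >= 1")
    if np.any(h < 0) or np.any(h >= 1):
        raise ParameterError("leverage must satisfy 0 <= h < 1")
    out = (t**2) * h / ((k + 1) * (1.0 - h))
    return float(out) if out.ndim == 0 else out


def _score_geometry(scores: np.ndarray):
    """Centered scores, their covariance inverse, and score-space leverage."""
    T = np.asarray(scores, dtype=float)
    n = T.shape[0]
    Tc = T - T.mean(axis=0, keepdims=True)
    cov = (Tc.T @ Tc) / (n - 1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "singular score covariance; reduce the factor count or remove "
            "duplicate samples"
        ) from exc
    d2 = np.einsum("ij,jk,ik->i", Tc, cov_inv, Tc)
    leverage = 1.0 / n + d2 / (n - 1)
    return Tc, cov_inv, d2, leverage


def mahalanobis_distance(scores: np.ndarray) -> np.ndarray:
    """Per-factor-normalised Mahalanobis distance of each score vector.

    ``sqrt(D^2 / k)`` with D the Mahalanobis distance to the score centroid;
    expectation ~1 for a well-behaved sample, conventional outlier cut-off 3.
    """
    T = np.asarray(scores, dtype=float)
    _, _, d2, _ = _score_geometry(T)
    return np.sqrt(d2 / T.shape[1])


def detect_outliers(
    scores: np.ndarray,
    residuals: np.ndarray,
    n_factors: int,
    mahalanobis_threshold: float = 3.0,
    cooks_threshold: float = 3.0,
):
    """Union of score-space Mahalanobis and Cook's D outliers.

    ``residuals`` are cross-validated prediction residuals; they are
    internally studentized using the score-space leverage.  Returns
    ``(indices, diagnostics)`` with per-sample M-distance, leverage,
    studentized residual and Cook's D.
    """
    T = np.asarray(scores, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n = T.shape[0]
    _, _, d2, leverage = _score_geometry(T)
    md = np.sqrt(d2 / n_factors)
    dof = max(n - n_factors - 1, 1)
    s = np.sqrt(np.sum(e**2) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stud = np.where(s > 0, e / (s * np.sqrt(np.clip(1.0 - leverage, 1e-12, None))), 0.0)
    leverage_c = np.clip(leverage, 0.0, 1.0 - 1e-12)
    cd = cooks_d(t_stud, leverage_c, n_factors)
    flagged = np.flatnonzero((md > mahalanobis_threshold) | (cd > cooks_threshold))
    diagnostics = {
        "mahalanobis": md,
        "leverage": leverage,
        "studentized_residual": t_stud,
        "cooks_d": cd,
    }
    return flagged, diagnostics


# ---------------------------------------------------------------------------
# PLS calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Fitted PLS calibration for one trait.

    Prediction is linear after pretreatment:
    ``y = (x_pretreated - x_mean) @ coef + y_mean``.
    """

    trait: str
    chain: PretreatmentChain
    wavelengths: np.ndarray
    n_factors: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    rotations: np.ndarray            # projection to score space, (p, k)
    score_mean: np.ndarray
    score_cov_inv: np.ndarray
    removed_outliers: list = field(default_factory=list)
    ncal: int = 0
    rmse_cv: float = float("nan")
    r2_cv: float = float("nan")
    seed: int | None = None

    @property
    def n_outliers_removed(self) -> int:
        return len(self.removed_outliers)

    def pretreat(self, X_raw: np.ndarray) -> np.ndarray:
        return self.chain.apply_matrix(np.atleast_2d(X_raw), self.wavelengths)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        Xp = self.pretreat(X_raw)
        return (Xp - self.x_mean) @ self.coef + self.y_mean

    def scores(self, X_raw: np.ndarray) -> np.ndarray:
        Xp = self.pretreat(X_raw)
        return (Xp - self.x_mean) @ self.rotations

    def gh(self, X_raw: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance to the calibration score centroid, per factor."""
        t = self.scores(X_raw) - self.score_mean
        d2 = np.einsum("ij,jk,ik->i", t, self.score_cov_inv, t)
        return d2 / self.n_factors

    def to_json_dict(self) -> dict:
        return {
            "trait": self.trait,
            "chain": self.chain.to_list(),
            "wavelengths": self.wavelengths.tolist(),
            "n_factors": self.n_factors,
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "rotations": self.rotations.tolist(),
            "score_mean": self.score_mean.tolist(),
            "score_cov_inv": self.score_cov_inv.tolist(),
            "removed_outliers": list(self.removed_outliers),
            "ncal": self.ncal,
            "rmse_cv": self.rmse_cv,
            "r2_cv": self.r2_cv,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            trait=d["trait"],
            chain=PretreatmentChain.from_list(d["chain"]),
            wavelengths=np.asarray(d["wavelengths"], dtype=float),
            n_factors=int(d["n_factors"]),
            coef=np.asarray(d["coef"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            rotations=np.asarray(d["rotations"], dtype=float),
            score_mean=np.asarray(d["score_mean"], dtype=float),
            score_cov_inv=np.asarray(d["score_cov_inv"], dtype=float),
            removed_outliers=list(d["removed_outliers"]),
            ncal=int(d["ncal"]),
            rmse_cv=float(d["rmse_cv"]),
            r2_cv=float(d["r2_cv"]),
            seed=d.get("seed"),
        )

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _cv_rmse_per_factor(Xp, y, max_factors, n_folds, seed):
    """Cross-validated predictions for each factor count 1..max_factors."""
    n = len(y)
    if n < n_folds:
        raise ParameterError(f"{n} samples cannot be split into {n_folds} folds")
    kmax = int(min(max_factors, n - int(np.ceil(n / n_folds)) - 1, Xp.shape[1]))
    kmax = max(kmax, 1)
    preds = np.empty((n, kmax))
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # over-specified factor counts on (near-)noiseless data are expected
        warnings.filterwarnings("ignore", message="y residual is constant")
        for k in range(1, kmax + 1):
            for train, test in folds.split(Xp):
                pls = PLSRegression(n_components=k, scale=False)
                pls.fit(Xp[train], y[train])
                preds[test, k - 1] = pls.predict(Xp[test]).ravel()
    rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return preds, rmse


def _select_factors(rmse_per_k: np.ndarray) -> int:
    """Smallest factor count within numerical ties of the minimum RMSE."""
    best = rmse_per_k.min()
    for k, r in enumerate(rmse_per_k, start=1):
        if r <= best * (1.0 + 1e-6) + 1e-12:
            return k
    return int(np.argmin(rmse_per_k)) + 1


def fit_pls(
    X_raw: np.ndarray,
    y: np.ndarray,
    trait: str = "trait",
    wavelengths: np.ndarray | None = None,
    chain: PretreatmentChain | None = None,
    max_factors: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    mahalanobis_threshold: float = 3.0,
    cooks_threshold: float = 3.0,
    sample_ids: Sequence | None = None,
) -> CalibrationModel:
    """Fit a PLS calibration with two cross-validation passes and outlier removal.

    Pass 1 cross-validates factor counts 1..max_factors on the full
    calibration set; score-space Mahalanobis distance (> threshold) and
    Cook's D on the cross-validated residuals (> threshold) flag outliers,
    which are removed.  Pass 2 re-runs the cross-validation on the cleaned
    set; the final factor count minimises the pass-2 RMSEcv (ties broken
    toward fewer factors) and the final model is refitted on the cleaned set.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X_raw.shape[0] != len(y):
        raise ParameterError("X and y disagree on sample count")
    if len(y) < 20:
        raise ParameterError("calibration needs at least 20 samples")
    if not (1 <= max_factors <= 10):
        raise ParameterError("max_factors must lie in [1, 10]")
    if wavelengths is None:
        wavelengths = np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, X_raw.shape[1])
    if chain is None:
        chain = PretreatmentChain()
    ids = list(sample_ids) if sample_ids is not None else list(range(len(y)))

    Xp = chain.apply_matrix(X_raw, wavelengths)

    # pass 1: cross-validation on the full set, then outlier elimination
    preds1, rmse1 = _cv_rmse_per_factor(Xp, y, max_factors, n_folds, seed)
    k1 = _select_factors(rmse1)
    pls1 = PLSRegression(n_components=k1, scale=False)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls1.fit(Xp, y)
    cv_resid = y - preds1[:, k1 - 1]
    flagged, _ = detect_outliers(
        pls1.x_scores_, cv_resid, k1, mahalanobis_threshold, cooks_threshold
    )
    keep = np.setdiff1d(np.arange(len(y)), flagged)
    removed = [ids[i] for i in flagged]

    # pass 2: cross-validation on the cleaned set, final factor choice and fit
    X2, y2 = Xp[keep], y[keep]
    _, rmse2 = _cv_rmse_per_factor(X2, y2, max_factors, n_folds, seed)
    k2 = _select_factors(rmse2)
    pls2 = PLSRegression(n_components=k2, scale=False)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls2.fit(X2, y2)

    scores = pls2.x_scores_
    _, cov_inv, _, _ = _score_geometry(scores)
    var_y2 = float(np.var(y2))
    rmse_cv = float(rmse2[k2 - 1])
    r2_cv = 1.0 - rmse_cv**2 / var_y2 if var_y2 > 0 else float("nan")

    return CalibrationModel(
        trait=trait,
        chain=chain,
        wavelengths=np.asarray(wavelengths, dtype=float),
        n_factors=k2,
        coef=np.asarray(pls2.coef_).reshape(-1),
        x_mean=pls2._x_mean if hasattr(pls2, "_x_mean") else X2.mean(axis=0),
        y_mean=float(y2.mean()),
        rotations=pls2.x_rotations_,
        score_mean=scores.mean(axis=0),
        score_cov_inv=cov_inv,
        removed_outliers=removed,
        ncal=len(keep),
        rmse_cv=rmse_cv,
        r2_cv=r2_cv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Validation metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Calibration/validation metric suite for one trait."""

    trait: str
    n_cal: int
    n_val: int
    n_factors: int
    n_outliers_removed: int
    r2_cv: float
    rmse_cv: float
    r2_v: float
    rmse_v: float
    f_value: float
    skew: float            # slope of predicted-vs-actual, ideal 1; NaN if undefined
    gh: float              # mean squared Mahalanobis of validation scores / PC
    pred_line: dict = field(default_factory=dict)
    isv: float | None = None
    irv: float | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["pred_line"] = dict(self.pred_line)
        return d


def predicted_vs_actual_line(actual: np.ndarray, predicted: np.ndarray) -> dict:
    """Least-squares line ``predicted = a + b * actual`` with adj. R2 and RSE."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = len(actual)
    sxx = np.sum((actual - actual.mean()) ** 2)
    if sxx <= 0:
        raise DegenerateInputError("actual values are constant; regression undefined")
    b = float(np.sum((actual - actual.mean()) * (predicted - predicted.mean())) / sxx)
    a = float(predicted.mean() - b * actual.mean())
    resid = predicted - (a + b * actual)
    sst = np.sum((predicted - predicted.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 and np.isfinite(r2) else float("nan")
    rse = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else float("nan")
    return {"intercept": a, "slope": b, "adj_r2": adj_r2, "rse": rse}


def evaluate(
    model: CalibrationModel,
    X_val_raw: np.ndarray,
    y_val: np.ndarray,
    extra_metrics: dict[str, Callable] | None = None,
) -> MetricReport:
    """Score a fitted calibration on a disjoint validation set.

    ``extra_metrics`` is a hook for proprietary-style indices (e.g. ISV/IRV
    implementations): mapping name -> f(actual, predicted); results are
    attached to the report if the name matches a report field.
    """
    y_val = np.asarray(y_val, dtype=float).ravel()
    if len(y_val) == 0:
        raise InputValidationError("empty validation set")
    yhat = model.predict(X_val_raw)
    resid = y_val - yhat
    rmse_v = float(np.sqrt(np.mean(resid**2)))
    sst = np.sum((y_val - y_val.mean()) ** 2)
    r2_v = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else float("nan")
    var_resid = float(np.var(resid, ddof=1)) if len(y_val) > 1 else float("nan")
    var_fit = float(np.var(yhat, ddof=1)) if len(y_val) > 1 else float("nan")
    f_value = var_fit / var_resid if var_resid > 0 else float("inf")

    # skew: slope of predicted on actual; undefined for constant predictions
    if np.var(yhat) <= 1e-24 or sst <= 0:
        skew = float("nan")
        line = {}
    else:
        line = predicted_vs_actual_line(y_val, yhat)
        skew = line["slope"]

    gh = float(np.mean(model.gh(X_val_raw)))

    report = MetricReport(
        trait=model.trait,
        n_cal=model.ncal,
        n_val=len(y_val),
        n_factors=model.n_factors,
        n_outliers_removed=model.n_outliers_removed,
        r2_cv=model.r2_cv,
        rmse_cv=model.rmse_cv,
        r2_v=r2_v,
        rmse_v=rmse_v,
        f_value=f_value,
        skew=skew,
        gh=gh,
        pred_line=line,
    )
    for name, fn in (extra_metrics or {}).items():
        if hasattr(report, name):
            setattr(report, name, float(fn(y_val, yhat)))
    return report
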
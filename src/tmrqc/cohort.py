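"""Farm-cohort statistics for Hi/Si monitoring.

Applies the observational-cohort analysis layer to farm records: repeated
visits are averaged per farm, continuous variables are screened for
normality, Hi and Si are modelled against mixer-wagon (MW) settings and TMR
traits with linear and logistic regressions (odds ratios, ROC/AUC),
correlations are screened at |r| >= 0.6, a scaled PCA summarises the
predictor space, and a VIF-pruned bidirectional AIC search selects
multiparametric models.

Farm records travel as a pandas DataFrame (one row per farm-visit); the
column schema in :data:`FARM_NUMERIC_COLUMNS` / :data:`FARM_CATEGORICAL_COLUMNS`
is the record contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import DataIntegrityError, DegenerateInputError, ParameterError

#: Numeric farm-record fields (units in docs/methods.md).
FARM_NUMERIC_COLUMNS = (
    "fullness", "hi", "si", "cows", "dmi", "total_intake", "milking_days",
    "milk_yield", "gmpl", "dm", "cp", "starch", "andf", "pendf",
    "mw_volume", "augers", "loading_time", "operating_time", "mixing_time",
)

#: Categorical farm-record fields.
FARM_CATEGORICAL_COLUMNS = ("mw_type",)


@dataclass
class ModelReport:
    """Fitted-model summary shared by the linear and logistic layers."""

    kind: str                      # "linear" | "logistic"
    n: int
    params: pd.Series = field(default_factory=pd.Series)
    bse: pd.Series = field(default_factory=pd.Series)
    pvalues: pd.Series = field(default_factory=pd.Series)
    adj_r2: float | None = None
    rse: float | None = None
    odds_ratios: pd.Series | None = None
    auc: float | None = None
    vif: pd.Series | None = None
    aic: float | None = None
    separation: bool = False
    selected: list[str] | None = None


def mw_fullness(
    load_weight_t: float,
    specific_weight_t_per_m3: float,
    declared_volume_m3: float,
    literal: bool = False,
) -> float:
    """Mixer-wagon load fullness, %: 100 * loaded volume / declared volume.

    Loaded volume is ``weight / specific weight`` (t over t/m3 gives m3).
    ``literal=True`` reproduces the historically printed product
    ``weight * specific weight`` for compatibility; it is dimensionally a
    mass-squared-per-volume and not recommended.
    """
    for name, v in (
        ("load_weight_t", load_weight_t),
        ("specific_weight_t_per_m3", specific_weight_t_per_m3),
        ("declared_volume_m3", declared_volume_m3),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ParameterError(f"{name} must be positive and finite, got {v}")
    volume = (
        load_weight_t * specific_weight_t_per_m3
        if literal
        else load_weight_t / specific_weight_t_per_m3
    )
    return 100.0 * volume / declared_volume_m3


def average_repeated_visits(records: pd.DataFrame, farm_col: str = "farm") -> pd.DataFrame:
    """Collapse repeated visits to one row per farm (arithmetic mean).

    Numeric fields are averaged; categorical fields must be constant within a
    farm, otherwise a :class:`DataIntegrityError` is raised.
    """
    if farm_col not in records.columns:
        raise ParameterError(f"missing farm identifier column {farm_col!r}")
    numeric = records.select_dtypes(include=[np.number]).columns.tolist()
    categorical = [c for c in records.columns if c not in numeric and c != farm_col]
    for farm, group in records.groupby(farm_col):
        for col in categorical:
            if group[col].dropna().nunique() > 1:
                raise DataIntegrityError(
                    f"farm {farm!r} has conflicting values in categorical column {col!r}"
                )
    agg = {c: "mean" for c in numeric}
    agg.update({c: "first" for c in categorical})
    out = records.groupby(farm_col, sort=True).agg(agg).reset_index()
    return out


def screen_normality(values, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk screen deciding the summary form for a variable.

    Returns the test statistic and p-value plus the chosen summary:
    mean +/- SD when normality is not rejected, median and quartiles
    otherwise.  Constant vectors are reported as degenerate (non-normal).
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 3:
        raise ParameterError("normality screening needs n >= 3")
    if np.ptp(x) == 0:
        return {
            "statistic": float("nan"), "p_value": 0.0, "normal": False,
            "summary": {"median": float(x[0]), "q1": float(x[0]), "q3": float(x[0])},
        }
    stat, p = stats.shapiro(x)
    normal = p > alpha
    if normal:
        summary = {"mean": float(x.mean()), "sd": float(x.std(ddof=1))}
    else:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        summary = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return {"statistic": float(stat), "p_value": float(p), "normal": normal, "summary": summary}


def _design(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    X = pd.DataFrame(X)
    X = pd.get_dummies(X, drop_first=True, dtype=float)
    return sm.add_constant(X.astype(float), has_constant="add")


def linear_model(y, X) -> ModelReport:
    """OLS fit with adjusted R2, residual standard error and coefficient table."""
    y = np.asarray(y, dtype=float)
    Xd = _design(X)
    if len(y) <= Xd.shape[1]:
        raise ParameterError("need n > number of parameters")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise DegenerateInputError("design matrix is rank deficient")
    fit = sm.OLS(y, Xd).fit()
    rse = float(np.sqrt(fit.mse_resid))
    return ModelReport(
        kind="linear", n=int(fit.nobs), params=fit.params, bse=fit.bse,
        pvalues=fit.pvalues, adj_r2=float(fit.rsquared_adj), rse=rse,
        aic=float(fit.aic),
    )


def mann_whitney_auc(scores, classes) -> float:
    """AUC as the rank (Mann-Whitney) probability that a random positive
    outscores a random negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes).astype(bool)
    n_pos, n_neg = classes.sum(), (~classes).sum()
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[classes].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def logistic_model(classes, X) -> ModelReport:
    """Maximum-likelihood logistic regression with odds ratios and ROC AUC.

    Odds ratios are ``exp(coefficient)`` per predictor; AUC uses the
    Mann-Whitney rank construction over the fitted probabilities.  Perfect
    separation is flagged (``separation=True``) and the odds ratios reported
    as non-estimable (NaN).
    """
    y = np.asarray(classes).astype(float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("both classes must be present")
    Xd = _design(X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, Xd).fit(disp=False, maxiter=200)
            # absurd coefficient scale also indicates quasi-separation
            if not fit.mle_retvals.get("converged", True) or np.any(np.abs(fit.params[1:]) > 50):
                separation = True
        except (PerfectSeparationWarning, Exception):
            separation = True
            fit = sm.Logit(y, Xd).fit(disp=False, maxiter=35, method="bfgs", start_params=None)
    fitted = np.asarray(fit.predict(Xd))
    auc = mann_whitney_auc(fitted, y.astype(bool))
    slope_names = [c for c in Xd.columns if c != "const"]
    if separation:
        ors = pd.Series(np.nan, index=slope_names)
    else:
        ors = np.exp(fit.params[slope_names])
    return ModelReport(
        kind="logistic", n=int(len(y)), params=fit.params, bse=fit.bse,
        pvalues=fit.pvalues, odds_ratios=ors, auc=auc,
        aic=float(fit.aic), separation=separation,
    )


def correlation_screen(
    table: pd.DataFrame,
    threshold: float = 0.6,
    ordinal: tuple[str, ...] = (),
    exceptions: tuple[tuple[str, str], ...] = (),
) -> pd.DataFrame:
    """Pairwise correlations filtered at |r| >= threshold.

    Pearson for quantitative pairs; Spearman whenever either variable is
    named in ``ordinal`` (ordered categories coded numerically).  Pairs named
    in ``exceptions`` are retained regardless of the threshold.
    """
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    exc = {frozenset(p) for p in exceptions}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                continue
            method = "spearman" if (a in ordinal or b in ordinal) else "pearson"
            if method == "pearson":
                r, p = stats.pearsonr(pair[a], pair[b])
            else:
                r, p = stats.spearmanr(pair[a], pair[b])
            if abs(r) >= threshold or frozenset((a, b)) in exc:
                rows.append({"var_a": a, "var_b": b, "method": method,
                             "r": float(r), "p_value": float(p), "n": len(pair)})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "method", "r", "p_value", "n"])


def pca_summary(table: pd.DataFrame, n_components: int = 10) -> dict:
    """PCA on unit-variance-scaled numeric columns.

    Zero-variance columns are dropped with a warning.  Returns scores,
    loadings (columns x components) and explained-variance percentages,
    components ordered by explained variance.
    """
    num = table.select_dtypes(include=[np.number]).dropna()
    keep = [c for c in num.columns if num[c].std(ddof=0) > 0]
    dropped = [c for c in num.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    if not keep:
        raise DegenerateInputError("no varying numeric columns for PCA")
    Z = (num[keep] - num[keep].mean()) / num[keep].std(ddof=1)
    k = int(min(n_components, len(keep), len(Z) - 1))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return {
        "scores": pd.DataFrame(scores, index=Z.index, columns=comp_names),
        "loadings": pd.DataFrame(pca.components_.T, index=keep, columns=comp_names),
        "explained_variance_pct": pd.Series(
            100.0 * pca.explained_variance_ratio_, index=comp_names
        ),
        "dropped": dropped,
    }


def _vif_prune(X: pd.DataFrame, cap: float) -> pd.DataFrame:
    """Iteratively drop the predictor with the largest VIF until all < cap."""
    X = X.copy()
    while X.shape[1] > 1:
        design = sm.add_constant(X.astype(float), has_constant="add").to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([
                variance_inflation_factor(design, j + 1) for j in range(X.shape[1])
            ])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        if np.all(vifs < cap):
            break
        X = X.drop(columns=[X.columns[int(np.argmax(vifs))]])
    return X


def stepwise_aic(y, X: pd.DataFrame, vif_cap: float = 10.0) -> ModelReport:
    """VIF pruning (< cap) followed by bidirectional AIC model selection.

    Starts from the intercept-only model and alternates forward additions
    and backward deletions until AIC no longer improves.  An empty final
    model (intercept only) is permitted.  The report carries the final OLS
    fit, its AIC/adjusted R2/RSE, the selected predictors and their VIFs.
    """
    y = np.asarray(y, dtype=float)
    X = pd.get_dummies(pd.DataFrame(X), drop_first=True, dtype=float)
    X = _vif_prune(X, vif_cap)

    def fit_aic(cols):
        design = sm.add_constant(X[list(cols)].astype(float), has_constant="add")
        return sm.OLS(y, design).fit()

    selected: list[str] = []
    current = fit_aic(selected)
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, str, str]] = []
        for col in X.columns:
            if col not in selected:
                candidates.append((fit_aic(selected + [col]).aic, "add", col))
        for col in selected:
            rest = [c for c in selected if c != col]
            candidates.append((fit_aic(rest).aic, "drop", col))
        if not candidates:
            break
        best_aic, action, col = min(candidates, key=lambda c: c[0])
        if best_aic < current.aic - 1e-9:
            selected = selected + [col] if action == "add" else [c for c in selected if c != col]
            current = fit_aic(selected)
            improved = True

    if selected:
        design = sm.add_constant(X[selected].astype(float), has_constant="add").to_numpy()
        vif = pd.Series(
            [variance_inflation_factor(design, j + 1) for j in range(len(selected))],
            index=selected,
        )
    else:
        vif = pd.Series(dtype=float)
    return ModelReport(
        kind="linear", n=int(current.nobs), params=current.params, bse=current.bse,
        pvalues=current.pvalues, adj_r2=float(current.rsquared_adj),
        rse=float(np.sqrt(current.mse_resid)), aic=float(current.aic),
        vif=vif, selected=selected,
    )


def split_by_median_yield(records: pd.DataFrame, yield_col: str = "milk_yield") -> pd.Series:
    """Label farms low/high yield at the cohort median milk yield (recomputed)."""
    med = records[yield_col].median()
    return pd.Series(
        np.where(records[yield_col] > med, "FMY-high", "FMY-low"), index=records.index
    )
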
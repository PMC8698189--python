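"""Seeded synthetic-data generators for the whole pipeline.

Produces every input the downstream modules consume, with the statistical
structure the analysis assumes:

* a calibration set of paired NIR spectra and reference analytics emulating a
  311-sample TMR survey (chemistry from a correlated multivariate normal,
  sieve fractions from a Dirichlet, spectra from fixed Gaussian absorption
  bands plus a particle-size-driven scatter baseline and heteroscedastic
  noise);
* 16-point feeding-alley batches with controllable within-batch
  heterogeneity and a controllable fresh-vs-+2 h sorting shift (refusals
  enriched in coarse particles and aNDF);
* a farm cohort in which the homogeneity index depends linearly on
  mixer-wagon fullness.

Randomness: one global integer seed; each generator derives its own
independent stream as ``np.random.default_rng([seed, STREAM_ID])`` with a
fixed per-generator stream id, so identical configs give bit-identical
output and the three generators never share draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import particles
from .chemometrics import Spectrum
from .errors import ParameterError
from .indexes import AlleyBatch
from .particles import SieveFractions, normalize_fractions

_STREAM_CALIBRATION = 1
_STREAM_ALLEY = 2
_STREAM_COHORT = 3

#: Chemistry trait order used throughout the generator.
CHEMISTRY_TRAITS = ("dm", "cp", "andf", "adf", "starch")

#: Fixed between-trait correlations (aNDF-ADF strongly positive,
#: starch negatively tied to the fibre fractions; all other pairs 0).
_CHEM_CORR = np.array([
    [1.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 1.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 1.00, 0.85, -0.50],
    [0.00, 0.00, 0.85, 1.00, -0.35],
    [0.00, 0.00, -0.50, -0.35, 1.00],
])

#: Gaussian absorption bands: trait -> (centre nm, width nm, absorbance per % unit).
#: The moisture band reads 100 - DM.  Plumbing constants: chosen only so the
#: pretreatments and PLS have realistic covariance structure to exploit.
ABSORPTION_BANDS = {
    "moisture": ((1450.0, 45.0, 0.0040), (970.0, 30.0, 0.0015)),
    "cp": ((1510.0, 35.0, 0.0100),),
    "andf": ((1364.0, 50.0, 0.0060),),
    "adf": ((1210.0, 40.0, 0.0050),),
    "starch": ((1528.0, 38.0, 0.0040),),
}

#: Reference GMPL (mm) against which the scatter baseline is scaled.
_SCATTER_REFERENCE_GMPL = 6.73

#: Strength of the coarseness tilt that couples sieve draws to the DM latent.
_GMPL_TILT = 0.15

#: Relative +2 h shift per index trait at sorting_effect = 1 (refusals keep
#: coarse particles and fibre; fine, starch-rich material is eaten first).
SORTING_SHIFTS = {
    "S4": +0.06, "S5": -0.12, "bottom": -0.18, "GMPL": +0.25,
    "CP": -0.03, "aNDF": +0.08, "starch": -0.12,
}


def _default_chem_means() -> dict:
    # cohort-table chemistry; ADF is not tabulated there and uses a typical
    # maize-silage-based TMR value
    return {"dm": 49.2, "cp": 15.2, "andf": 33.1, "adf": 21.5, "starch": 26.0}


def _default_chem_sds() -> dict:
    return {"dm": 4.35, "cp": 0.62, "andf": 1.61, "adf": 1.40, "starch": 1.18}


@dataclass
class GeneratorConfig:
    """All knobs for the three generators; defaults are the study conditions."""

    seed: int = 0
    n_samples: int = 311
    n_points: int = 16
    heterogeneity: float = 5.0          # target within-batch CV scale, %
    sorting_effect: float = 0.3         # 0 = no fresh-vs-2h shift, 1 = strong
    wavelength_start: float = 902.0
    wavelength_end: float = 1660.0
    wavelength_step: float = 2.0
    chemistry_means: dict = field(default_factory=_default_chem_means)
    chemistry_sds: dict = field(default_factory=_default_chem_sds)
    sieve_mean_fractions: tuple = (2.30, 7.79, 20.0, 34.2, 17.9, 17.8)
    fullness_range: tuple = (62.2, 131.0)
    hi_intercept: float = 96.0
    hi_slope: float = -0.19
    hi_noise_sd: float = 4.33
    spectral_noise_sd: float = 0.002    # absorbance units
    scatter_strength: float = 1.0       # 0 disables the particle-size baseline
    sieve_concentration: float = 150.0  # Dirichlet concentration (higher = tighter)
    gmpl_dm_correlation: float = -0.71

    def __post_init__(self):
        scalars = {
            "heterogeneity": self.heterogeneity,
            "sorting_effect": self.sorting_effect,
            "wavelength_start": self.wavelength_start,
            "wavelength_end": self.wavelength_end,
            "wavelength_step": self.wavelength_step,
            "hi_intercept": self.hi_intercept,
            "hi_slope": self.hi_slope,
            "hi_noise_sd": self.hi_noise_sd,
            "spectral_noise_sd": self.spectral_noise_sd,
            "scatter_strength": self.scatter_strength,
            "sieve_concentration": self.sieve_concentration,
            "gmpl_dm_correlation": self.gmpl_dm_correlation,
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v}")
        if self.heterogeneity < 0:
            raise ParameterError("heterogeneity must be >= 0")
        if not (0.0 <= self.sorting_effect <= 1.0):
            raise ParameterError("sorting_effect must lie in [0, 1]")
        if self.hi_noise_sd < 0 or self.spectral_noise_sd < 0:
            raise ParameterError("noise SDs must be >= 0")
        if self.sieve_concentration <= 0:
            raise ParameterError("sieve_concentration must be > 0")
        if not (-1.0 < self.gmpl_dm_correlation < 1.0):
            raise ParameterError("gmpl_dm_correlation must lie in (-1, 1)")
        for trait in CHEMISTRY_TRAITS:
            if trait not in self.chemistry_means or trait not in self.chemistry_sds:
                raise ParameterError(f"chemistry means/sds must cover {trait!r}")
            if not np.isfinite(self.chemistry_means[trait]):
                raise ParameterError(f"chemistry mean for {trait!r} must be finite")
            sd = self.chemistry_sds[trait]
            if not np.isfinite(sd) or sd < 0:
                raise ParameterError(f"chemistry sd for {trait!r} must be >= 0")
        fr = np.asarray(self.sieve_mean_fractions, dtype=float)
        if fr.shape != (6,) or not np.all(np.isfinite(fr)) or np.any(fr < 0):
            raise ParameterError("sieve_mean_fractions must be six finite nonnegative values")
        if abs(fr.sum() - 100.0) > 0.05:
            raise ParameterError(
                f"sieve_mean_fractions must sum to 100 within 0.05 (got {fr.sum():.4f})"
            )
        lo, hi = self.fullness_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi < lo:
            raise ParameterError("fullness_range must be a nonempty positive interval")
        wl = self.wavelengths()
        if len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ParameterError("wavelength grid must be strictly increasing")
        if wl[0] < 902.0 - 1e-9 or wl[-1] > 1660.0 + 1e-9:
            raise ParameterError("wavelength grid must lie within [902, 1660] nm")

    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start, self.wavelength_end + 1e-9, self.wavelength_step
        )

    # -- plain key-value config file ------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sieve_mean_fractions"] = list(self.sieve_mean_fractions)
        d["fullness_range"] = list(self.fullness_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sieve_mean_fractions" in d:
            d["sieve_mean_fractions"] = tuple(d["sieve_mean_fractions"])
        if "fullness_range" in d:
            d["fullness_range"] = tuple(d["fullness_range"])
        return cls(**d)


@dataclass(frozen=True)
class TMRSample:
    """Reference analytics for one TMR sample (chemistry % + sieve fractions)."""

    dm: float
    cp: float
    andf: float
    adf: float
    starch: float
    fractions: SieveFractions
    sample_id: str | None = None

    @property
    def gmpl(self) -> float:
        return particles.gmpl(self.fractions)

    @property
    def pef(self) -> float:
        return particles.cumulative_and_pef(self.fractions).pef

    @property
    def pendf(self) -> float:
        return particles.pendf(self.andf, self.pef)


# ---------------------------------------------------------------------------
# Calibration set
# ---------------------------------------------------------------------------

def _band_matrix(wl: np.ndarray) -> dict:
    out = {}
    for trait, bands in ABSORPTION_BANDS.items():
        profile = np.zeros_like(wl)
        for centre, width, amp in bands:
            profile += amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        out[trait] = profile
    return out


def _scatter_baseline(wl: np.ndarray) -> np.ndarray:
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.6 + 0.25 * u + 0.10 * u**2


def generate_calibration_set(config: GeneratorConfig) -> list[tuple[Spectrum, TMRSample]]:
    """Paired (spectrum, reference sample) calibration data.

    Chemistry is multivariate normal with the configured means/SDs and the
    fixed correlation structure; sieve fractions are Dirichlet around the
    configured mean fractions, tilted toward coarser strata by a latent that
    is negatively correlated with DM (so GMPL and DM co-vary realistically).
    Each spectrum is the sum of per-constituent Gaussian bands, a
    multiplicative slowly varying baseline scaled by GMPL (light-scattering
    cross-sensitivity — the very signal that lets PLS see particle size),
    and heteroscedastic Gaussian noise.
    """
    if config.n_samples < 10:
        raise ParameterError("n_samples must be >= 10 for a calibration set")
    rng = np.random.default_rng([config.seed, _STREAM_CALIBRATION])
    n = config.n_samples
    wl = config.wavelengths()

    # chemistry
    L = np.linalg.cholesky(_CHEM_CORR)
    z = rng.standard_normal((n, len(CHEMISTRY_TRAITS))) @ L.T
    means = np.array([config.chemistry_means[t] for t in CHEMISTRY_TRAITS])
    sds = np.array([config.chemistry_sds[t] for t in CHEMISTRY_TRAITS])
    chem = means + sds * z
    chem = np.clip(chem, 0.1, None)

    # sieve fractions, coupled to DM through a coarseness latent
    rho = config.gmpl_dm_correlation
    z_coarse = rho * z[:, 0] + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    mean_props = np.asarray(config.sieve_mean_fractions, dtype=float)
    mean_props = mean_props / mean_props.sum()
    alpha = mean_props * config.sieve_concentration
    dirichlet = rng.dirichlet(alpha, size=n)
    log_mid = np.log(particles.STRATUM_MIDPOINTS_MM)
    tilt = np.exp(_GMPL_TILT * z_coarse[:, None] * (log_mid - log_mid.mean()))
    weights = dirichlet * tilt
    fractions = 100.0 * weights / weights.sum(axis=1, keepdims=True)

    bands = _band_matrix(wl)
    baseline = _scatter_baseline(wl)

    pairs = []
    for i in range(n):
        sample_id = f"cal{i + 1:04d}"
        frac = normalize_fractions(fractions[i])
        sample = TMRSample(
            dm=float(chem[i, 0]), cp=float(chem[i, 1]), andf=float(chem[i, 2]),
            adf=float(chem[i, 3]), starch=float(chem[i, 4]),
            fractions=frac, sample_id=sample_id,
        )
        concentrations = {
            "moisture": 100.0 - sample.dm,
            "cp": sample.cp, "andf": sample.andf,
            "adf": sample.adf, "starch": sample.starch,
        }
        absorbance = np.zeros_like(wl)
        for trait, profile in bands.items():
            absorbance = absorbance + concentrations[trait] * profile
        scatter = config.scatter_strength * (sample.gmpl / _SCATTER_REFERENCE_GMPL) * baseline
        absorbance = absorbance + scatter
        if config.spectral_noise_sd > 0:
            noise_sd = config.spectral_noise_sd * (0.5 + np.abs(absorbance))
            absorbance = absorbance + rng.standard_normal(len(wl)) * noise_sd
        pairs.append((Spectrum(wl, absorbance, sample_id), sample))
    return pairs


def calibration_frames(pairs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide spectra table and reference analytics table for a calibration set."""
    wl = pairs[0][0].wavelengths
    spectra = pd.DataFrame(
        [s.absorbance for s, _ in pairs],
        columns=[f"{w:g}" for w in wl],
    )
    spectra.insert(0, "sample_id", [s.sample_id for s, _ in pairs])
    rows = []
    for _, t in pairs:
        arr = t.fractions.as_array()
        rows.append({
            "sample_id": t.sample_id, "dm": t.dm, "cp": t.cp, "andf": t.andf,
            "adf": t.adf, "starch": t.starch,
            "s1": arr[0], "s2": arr[1], "s3": arr[2],
            "s4": arr[3], "s5": arr[4], "bottom": arr[5],
            "gmpl": t.gmpl, "pef": t.pef, "pendf": t.pendf,
        })
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feeding-alley batches
# ---------------------------------------------------------------------------

def _alley_trait_means(config: GeneratorConfig) -> dict:
    frac = normalize_fractions(config.sieve_mean_fractions)
    arr = frac.as_array()
    return {
        "S4": arr[3], "S5": arr[4], "bottom": arr[5],
        "GMPL": particles.gmpl(frac),
        "CP": config.chemistry_means["cp"],
        "aNDF": config.chemistry_means["andf"],
        "starch": config.chemistry_means["starch"],
    }


def generate_alley_batch(config: GeneratorConfig, include_later: bool = True) -> AlleyBatch:
    """One distribution event: fresh (and +2 h) index traits at each alley point.

    Fresh point values vary around the batch means with a per-trait CV set by
    ``heterogeneity`` (plus a negligible machine-noise floor so a
    zero-heterogeneity batch is constant only up to numerical noise).  The
    +2 h refusals shift the trait means by ``sorting_effect`` times the fixed
    relative shifts (coarse fractions, GMPL and aNDF up; S5/bottom/starch
    down), with the same point-to-point CV; ``sorting_effect = 0`` draws the
    +2 h points from exactly the fresh distribution.
    """
    if config.n_points < 3:
        raise ParameterError("n_points must be >= 3")
    rng = np.random.default_rng([config.seed, _STREAM_ALLEY])
    means = _alley_trait_means(config)
    cv = config.heterogeneity / 100.0
    floor = 1e-9  # machine-noise floor, relative

    def draw(mean_map):
        data = {}
        for trait, mu in mean_map.items():
            noise = cv * rng.standard_normal(config.n_points)
            machine = floor * rng.standard_normal(config.n_points)
            data[trait] = np.clip(mu * (1.0 + noise + machine), 1e-6 * mu, None)
        return pd.DataFrame(data)

    fresh = draw(means)
    later = None
    if include_later:
        shifted = {
            trait: mu * (1.0 + config.sorting_effect * SORTING_SHIFTS[trait])
            for trait, mu in means.items()
        }
        later = draw(shifted)
    return AlleyBatch(fresh=fresh, later=later, metadata={"seed": config.seed})


def alley_batch_frame(batch: AlleyBatch) -> pd.DataFrame:
    """Long-format alley table: point_id, time in {fresh, 2h}, trait columns."""
    frames = []
    for time, df in (("fresh", batch.fresh), ("2h", batch.later)):
        if df is None:
            continue
        block = df.copy()
        block.insert(0, "time", time)
        block.insert(0, "point_id", np.arange(1, len(df) + 1))
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Farm cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GeneratorConfig, n_farms: int, n_visits_per_farm: int = 1
) -> pd.DataFrame:
    """Farm-cohort records with a linear Hi-vs-fullness law.

    Fullness is uniform on ``fullness_range``; Hi follows
    ``hi_intercept + hi_slope * fullness + N(0, hi_noise_sd)`` clipped to
    [0, 100].  The remaining covariates vary around the cohort reference
    means; DM, GMPL and total intake share the published correlation
    structure and peNDF derives from aNDF and a GMPL-driven effectiveness
    factor.  With ``n_visits_per_farm > 1`` each visit jitters the farm-level
    numerics by a small (2% CV) amount; categorical fields stay constant.
    """
    if n_farms < 5:
        raise ParameterError("n_farms must be >= 5")
    if n_visits_per_farm < 1:
        raise ParameterError("n_visits_per_farm must be >= 1")
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    lo, hi_f = config.fullness_range
    fullness = rng.uniform(lo, hi_f, size=n_farms)
    hi_index = np.clip(
        config.hi_intercept + config.hi_slope * fullness
        + config.hi_noise_sd * rng.standard_normal(n_farms),
        0.0, 100.0,
    )
    si = np.clip(0.25 + 0.13 * rng.standard_normal(n_farms), 0.0, 1.0)

    # DM / GMPL / total intake block with the published correlation signs
    r_dg, r_di = config.gmpl_dm_correlation, -0.87
    corr = np.array([
        [1.0, r_dg, r_di],
        [r_dg, 1.0, r_dg * r_di],
        [r_di, r_dg * r_di, 1.0],
    ])
    zb = rng.standard_normal((n_farms, 3)) @ np.linalg.cholesky(corr).T
    dm = config.chemistry_means["dm"] + config.chemistry_sds["dm"] * zb[:, 0]
    gmpl = np.clip(6.14 + 0.87 * zb[:, 1], 1.5, 20.0)
    total_intake = np.clip(47.2 + 7.51 * zb[:, 2], 25.0, None)

    cp = config.chemistry_means["cp"] + config.chemistry_sds["cp"] * rng.standard_normal(n_farms)
    andf = config.chemistry_means["andf"] + config.chemistry_sds["andf"] * rng.standard_normal(n_farms)
    starch = (
        config.chemistry_means["starch"]
        + config.chemistry_sds["starch"] * rng.standard_normal(n_farms)
    )
    pef = np.clip(0.25 + 0.05 * gmpl + 0.08 * rng.standard_normal(n_farms), 0.05, 0.95)
    pendf = andf * pef

    farm_level = pd.DataFrame({
        "farm": [f"farm{i + 1:02d}" for i in range(n_farms)],
        "fullness": fullness,
        "hi": hi_index,
        "si": si,
        "cows": np.round(np.clip(254 + 234 * rng.standard_normal(n_farms), 40, None)),
        "dmi": np.clip(23.2 + 1.59 * rng.standard_normal(n_farms), 10.0, None),
        "total_intake": total_intake,
        "milking_days": np.clip(175 + 17.6 * rng.standard_normal(n_farms), 60.0, None),
        "milk_yield": np.clip(33.8 + 3.78 * rng.standard_normal(n_farms), 10.0, None),
        "gmpl": gmpl,
        "dm": np.clip(dm, 20.0, 80.0),
        "cp": np.clip(cp, 5.0, None),
        "starch": np.clip(starch, 5.0, None),
        "andf": np.clip(andf, 10.0, None),
        "pendf": pendf,
        "mw_volume": np.clip(25.2 + 4.83 * rng.standard_normal(n_farms), 10.0, None),
        "augers": rng.choice([1, 2], size=n_farms, p=[0.3, 0.7]).astype(float),
        "loading_time": np.clip(1697 + 587 * rng.standard_normal(n_farms), 300.0, None),
        "operating_time": np.clip(2192 + 529 * rng.standard_normal(n_farms), 600.0, None),
        "mixing_time": np.clip(561 + 331 * rng.standard_normal(n_farms), 60.0, None),
        "mw_type": rng.choice(
            ["self-propelled", "towed"], size=n_farms, p=[15 / 19, 4 / 19]
        ),
    })
    if n_visits_per_farm == 1:
        out = farm_level.copy()
        out.insert(1, "visit", 1)
        return out

    numeric = [c for c in farm_level.columns if c not in ("farm", "mw_type")]
    rows = []
    for _, rec in farm_level.iterrows():
        for visit in range(1, n_visits_per_farm + 1):
            row = rec.to_dict()
            row["visit"] = visit
            for c in numeric:
                row[c] = max(float(rec[c]) * (1.0 + 0.02 * rng.standard_normal()), 0.0)
            rows.append(row)
    out = pd.DataFrame(rows)
    return out[["farm", "visit"] + [c for c in farm_level.columns if c != "farm"]]
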
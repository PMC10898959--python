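"""Synthetic health-checkup cohort generator with known exposure-response truth.

The generator emulates the statistical structure of a large Taiwanese paid
health-checkup population with residential air-pollution exposure: six
correlated pollutant exposure series (PM2.5, PM10, CO, O3, SO2, NO2, all in
µg/m³), demographic and lifestyle covariates, cardiometabolic labs, a
sonographic steatosis flag, and a binary MASLD-driving outcome generated
from a configurable true logit per pollutant.  Because the true link
function f_j for every pollutant and every coefficient is recorded, every
downstream stage (classification, exclusion, inflection search, link
selection, joint modelling) can be validated against ground truth.

Exposure model
--------------
Monthly standardised levels combine a persistent person-level component
(capturing where someone lives) with an AR(1) month-to-month component, both
sharing the configured cross-pollutant correlation matrix via a Gaussian
copula.  The mixture weights are chosen so that the trailing 36-month mean
of each pollutant has exactly the configured mean and SD (before truncation
of negative concentrations at zero, whose effect is negligible at the
default moments).

Outcome model
-------------
latent logit_i = intercept + sum_j f_j(3-year mean exposure_ij) + covariate
effects.  The intercept is calibrated by bisection so the expected MASLD
prevalence among participants who survive the exclusion cascade equals the
configured target.  Cases receive sonographic steatosis plus at least one
cardiometabolic criterion; non-cases receive no steatosis except for a small
configurable fraction converted to cryptogenic steatotic liver disease
(steatosis with all five criteria false), which the downstream cascade
removes — the classifier, not the generator, decides labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "POLLUTANTS",
    "TABLE1_MEANS",
    "TABLE1_SDS",
    "DEFAULT_CORR",
    "LinkShape",
    "TrueLink",
    "SimConfig",
    "generate_cohort",
    "generate_exclusion_fixture",
    "draw_window_means",
    "default_true_links",
]

#: Pollutants in reporting order.
POLLUTANTS = ("pm25", "pm10", "co", "o3", "so2", "no2")

#: Cohort-wide 3-year-average exposure means (µg/m³), pooled over the
#: MASLD / no-MASLD strata of the reference population.
TABLE1_MEANS: dict[str, float] = {
    "pm25": 30.58,
    "pm10": 51.71,
    "co": 704.0,
    "o3": 52.8,
    "so2": 10.8,
    "no2": 37.5,
}

#: Matching pooled SDs (µg/m³).
TABLE1_SDS: dict[str, float] = {
    "pm25": 6.55,
    "pm10": 13.0,
    "co": 234.9,
    "o3": 6.5,
    "so2": 3.96,
    "no2": 9.64,
}

#: Default cross-pollutant correlation of 3-year means.  The PM2.5-PM10
#: (0.77) and PM10-SO2 (0.68) entries follow the reference population;
#: the remainder are typical urban monitoring values (O3 weakly negative
#: with fresh traffic emissions NO2/CO).  Positive definite.
DEFAULT_CORR = np.array(
    [
        [1.00, 0.77, 0.45, 0.30, 0.55, 0.50],
        [0.77, 1.00, 0.40, 0.35, 0.68, 0.50],
        [0.45, 0.40, 1.00, -0.10, 0.40, 0.65],
        [0.30, 0.35, -0.10, 1.00, 0.20, -0.15],
        [0.55, 0.68, 0.40, 0.20, 1.00, 0.45],
        [0.50, 0.50, 0.65, -0.15, 0.45, 1.00],
    ]
)


class LinkShape(str, Enum):
    LINEAR = "linear"
    HINGE = "hinge"
    PIECEWISE_JUMP = "piecewise_jump"
    SPLINE = "spline"


@dataclass(frozen=True)
class TrueLink:
    """True exposure contribution f(x) to the latent logit, in log-odds.

    shape:
      LINEAR          f(x) = slope_above * x
      HINGE           f(x) = slope_below*x + (slope_above-slope_below)*(x-c)+
      PIECEWISE_JUMP  two slopes around the cutpoint plus a level jump
      SPLINE          restricted cubic spline with given knots and coefs
    """

    shape: LinkShape
    cutpoint: float | None = None
    slope_below: float = 0.0
    slope_above: float = 0.0
    jump: float = 0.0
    knots: tuple[float, ...] | None = None
    coefs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", LinkShape(self.shape))
        if self.shape in (LinkShape.HINGE, LinkShape.PIECEWISE_JUMP):
            if self.cutpoint is None:
                raise ValueError(f"{self.shape.value} requires a cutpoint")
        if self.shape is LinkShape.SPLINE:
            if self.knots is None or self.coefs is None:
                raise ValueError("spline requires knots and coefs")
            if len(self.coefs) != len(self.knots) - 1:
                raise ValueError("spline needs k-1 coefs for k knots")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape is LinkShape.LINEAR:
            return self.slope_above * x
        if self.shape is LinkShape.HINGE:
            return self.slope_below * x + (
                self.slope_above - self.slope_below
            ) * np.maximum(0.0, x - self.cutpoint)
        if self.shape is LinkShape.PIECEWISE_JUMP:
            above = (x >= self.cutpoint).astype(float)
            return (
                self.slope_below * x
                + above * (self.jump + (self.slope_above - self.slope_below) * (x - self.cutpoint))
            )
        from .link_basis import rcs_basis

        return rcs_basis(x, self.knots) @ np.asarray(self.coefs, dtype=float)

    def to_dict(self) -> dict:
        d = {"shape": self.shape.value}
        for k in ("cutpoint", "slope_below", "slope_above", "jump"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.knots is not None:
            d["knots"] = list(self.knots)
            d["coefs"] = list(self.coefs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueLink":
        return cls(
            shape=LinkShape(d["shape"]),
            cutpoint=d.get("cutpoint"),
            slope_below=d.get("slope_below", 0.0),
            slope_above=d.get("slope_above", 0.0),
            jump=d.get("jump", 0.0),
            knots=tuple(d["knots"]) if "knots" in d else None,
            coefs=tuple(d["coefs"]) if "coefs" in d else None,
        )


def default_true_links() -> dict[str, TrueLink]:
    """Truth emulating the non-linear shapes reported for each pollutant.

    PM2.5 hinge at 34.64, PM10 and CO two-segment with a small jump at
    57.93 / 643.6, O3 and SO2 3-knot splines (SO2 essentially null), NO2 a
    4-knot decrease-rise-plateau spline.  Slopes are log-odds per µg/m³ on
    the scale of the reported adjusted odds ratios.
    """
    return {
        "pm25": TrueLink(LinkShape.HINGE, cutpoint=34.64, slope_below=0.0, slope_above=0.035),
        "pm10": TrueLink(
            LinkShape.PIECEWISE_JUMP,
            cutpoint=57.93,
            slope_below=-0.008,
            slope_above=0.019,
            jump=0.05,
        ),
        "co": TrueLink(
            LinkShape.PIECEWISE_JUMP,
            cutpoint=643.6,
            slope_below=0.0006,
            slope_above=0.0001,
            jump=0.02,
        ),
        "o3": TrueLink(
            LinkShape.SPLINE, knots=(45.0, 53.0, 61.0), coefs=(-0.004, 0.08)
        ),
        "so2": TrueLink(LinkShape.LINEAR, slope_above=0.0),
        "no2": TrueLink(
            LinkShape.SPLINE,
            knots=(26.0, 34.0, 43.0, 52.0),
            coefs=(-0.008, 0.15, -0.25),
        ),
    }


#: Marginal per-rule flag probabilities emulating the enrollment flow of the
#: reference population (each as a fraction of the deduplicated cohort).
DEFAULT_EXCLUSION_FRACTIONS: dict[str, float] = {
    "missing_exposure_or_sono": 0.02,
    "age_under_18": 0.014,
    "missing_masld_fields": 0.092,
    "missing_alcohol": 0.062,
    "cirrhosis_hcc": 0.0014,
    "hepatitis": 0.114,
    "excess_alcohol": 0.019,
    "sono_abnormality": 0.0074,
    "cryptogenic": 0.0246,
}

DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": 0.045,          # per year, centred at the cohort mean
    "sex:male": 1.1,
    "smoking:current": 0.2,
    "smoking:former": 0.1,
    "regular_exercise": -0.05,
}


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic cohort draw."""

    n_participants: int = 10_000
    pollutant_means: dict[str, float] = field(default_factory=lambda: dict(TABLE1_MEANS))
    pollutant_sds: dict[str, float] = field(default_factory=lambda: dict(TABLE1_SDS))
    pollutant_corr: np.ndarray = field(default_factory=lambda: DEFAULT_CORR.copy())
    true_links: dict[str, TrueLink] = field(default_factory=default_true_links)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    intercept_calibration_target: float = 0.406
    exclusion_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FRACTIONS)
    )
    months_of_exposure: int = 48
    ar1_rho: float = 0.9
    persistent_var_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 < self.intercept_calibration_target < 1.0:
            raise ValueError("prevalence target must be in (0, 1)")
        if self.months_of_exposure < 48:
            raise ValueError("months_of_exposure must be >= 48")
        R = np.asarray(self.pollutant_corr, dtype=float)
        if R.shape != (len(POLLUTANTS), len(POLLUTANTS)):
            raise ValueError("pollutant_corr must be 6x6")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("pollutant_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("pollutant_corr must be positive semi-definite")
        self.pollutant_corr = R
        for p in POLLUTANTS:
            if self.pollutant_sds[p] <= 0:
                raise ValueError(f"SD for {p} must be > 0")
        if not 0.0 < self.persistent_var_fraction < 1.0:
            raise ValueError("persistent_var_fraction must be in (0, 1)")


def _ar1_window_mean_variance(rho: float, window: int) -> float:
    """Variance of the mean of `window` consecutive unit-variance AR(1) draws."""
    k = np.arange(1, window)
    return (window + 2.0 * np.sum((window - k) * rho**k)) / window**2


def _chol(R: np.ndarray) -> np.ndarray:
    # tolerate a semidefinite matrix via a tiny jitter
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))


def draw_window_means(
    rng: np.random.Generator,
    n: int,
    means: Mapping[str, float] | None = None,
    sds: Mapping[str, float] | None = None,
    corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw 3-year-average exposures directly from the Gaussian copula.

    Shortcut used for fast simulation studies where the monthly series is
    irrelevant; moments and correlation match :func:`generate_cohort`'s
    window means (negative draws truncated at zero).
    """
    means = dict(TABLE1_MEANS) if means is None else means
    sds = dict(TABLE1_SDS) if sds is None else sds
    R = DEFAULT_CORR if corr is None else np.asarray(corr, dtype=float)
    z = rng.standard_normal((n, len(POLLUTANTS))) @ _chol(R).T
    out = {}
    for j, p in enumerate(POLLUTANTS):
        out[p] = np.maximum(0.0, means[p] + sds[p] * z[:, j])
    return pd.DataFrame(out)


def _monthly_exposure_array(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n, 6, M) concentrations; trailing-36-month means hit configured moments."""
    n, M, rho = cfg.n_participants, cfg.months_of_exposure, cfg.ar1_rho
    L = _chol(cfg.pollutant_corr).T
    v36 = _ar1_window_mean_variance(rho, 36)
    a = np.sqrt(cfg.persistent_var_fraction)
    b = np.sqrt((1.0 - cfg.persistent_var_fraction) / v36)

    w = rng.standard_normal((n, len(POLLUTANTS))) @ L  # persistent, corr R
    e = np.empty((n, len(POLLUTANTS), M), dtype=np.float64)
    e[:, :, 0] = rng.standard_normal((n, len(POLLUTANTS))) @ L
    innov_sd = np.sqrt(1.0 - rho**2)
    for m in range(1, M):
        e[:, :, m] = rho * e[:, :, m - 1] + innov_sd * (
            rng.standard_normal((n, len(POLLUTANTS))) @ L
        )
    z = a * w[:, :, None] + b * e
    mu = np.array([cfg.pollutant_means[p] for p in POLLUTANTS])
    sd = np.array([cfg.pollutant_sds[p] for p in POLLUTANTS])
    conc = mu[None, :, None] + sd[None, :, None] * z
    np.maximum(conc, 0.0, out=conc)
    return conc


def _draw_categorical(rng, n, levels, probs):
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics and lifestyle with frequencies matching the reference
    checkup population; 'unreported'-eligible fields carry genuine NaNs."""
    n = cfg.n_participants
    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    df["age"] = np.clip(rng.normal(40.5, 12.5, n), 18.0, 90.0).round(1)
    df["sex"] = _draw_categorical(rng, n, ["female", "male"], [0.52, 0.48])
    df["marriage"] = _draw_categorical(
        rng, n, ["single", "married", None], [0.371, 0.578, 0.051]
    )
    df["education"] = _draw_categorical(
        rng,
        n,
        ["illiterate", "elementary_middle", "high_school", "college_or_higher", None],
        [0.011, 0.086, 0.343, 0.543, 0.017],
    )
    df["income"] = _draw_categorical(
        rng, n, ["lt_28k", "28k_to_70k", "ge_70k", None], [0.405, 0.398, 0.073, 0.124]
    )
    df["smoking"] = _draw_categorical(
        rng, n, ["never", "former", "current", None], [0.765, 0.063, 0.162, 0.010]
    )
    df["alcohol_status"] = _draw_categorical(
        rng, n, ["never", "former", "current"], [0.853, 0.022, 0.125]
    )
    current = df["alcohol_status"] == "current"
    df["alcohol_drinks_per_day"] = np.where(
        current, rng.integers(1, 4, n).astype(float), 0.0
    )
    df["alcohol_days_per_week"] = np.where(
        current, rng.integers(1, 8, n).astype(float), 0.0
    )
    df["alcohol_years"] = np.where(current, rng.integers(0, 20, n).astype(float), 0.0)
    for col, probs in {
        "vegetable_intake": [0.172, 0.601, 0.227],
        "fruit_intake": [0.325, 0.550, 0.125],
        "sugary_drink_intake": [0.353, 0.482, 0.165],
        "fried_food_intake": [0.293, 0.529, 0.178],
    }.items():
        df[col] = _draw_categorical(rng, n, ["seldom", "moderate", "frequent"], probs)
    df["regular_exercise"] = rng.random(n) < 0.328
    df["enrollment_year"] = rng.integers(2010, 2018, n)
    month = rng.integers(1, 13, n)
    day = rng.integers(1, 29, n)
    df["checkup_date"] = pd.to_datetime(
        {"year": df["enrollment_year"], "month": month, "day": day}
    )
    return df


def _covariate_eta(df: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Log-odds contribution of covariates; numeric effects are centred."""
    eta = np.zeros(len(df))
    for key, beta in effects.items():
        if ":" in key:
            col, level = key.split(":", 1)
            eta += beta * (df[col] == level).to_numpy(dtype=float)
        else:
            v = df[key].to_numpy(dtype=float)
            eta += beta * (v - np.nanmean(v))
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for the intercept with mean expit(intercept + eta) = target."""
    from scipy.special import expit

    lo, hi = -30.0, 30.0
    f = lambda b: float(np.mean(expit(b + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("prevalence calibration unachievable for this target")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


_CASE_LABS = dict(
    bmi=(26.2, 3.4), sbp=(123.5, 16.9), dbp=(77.1, 11.2), tg=(148.9, 94.4),
    glucose=(102.0, 22.0), hba1c=(5.8, 0.8), ldl=(124.1, 32.5),
    cholesterol=(202.5, 36.1), alt=(37.5, 28.6),
    wc_male=(88.0, 8.0), wc_female=(79.7, 8.1),
    hdl_male=(49.2, 9.7), hdl_female=(57.3, 12.6),
)
_CONTROL_LABS = dict(
    bmi=(21.3, 2.6), sbp=(111.0, 15.4), dbp=(69.5, 10.1), tg=(80.7, 44.2),
    glucose=(92.0, 12.0), hba1c=(5.4, 0.4), ldl=(106.8, 29.4),
    cholesterol=(187.0, 32.8), alt=(19.7, 13.5),
    wc_male=(77.7, 6.9), wc_female=(68.2, 5.9),
    hdl_male=(57.1, 12.4), hdl_female=(68.3, 14.7),
)


def _draw_labs(df: pd.DataFrame, case: np.ndarray, rng: np.random.Generator) -> None:
    """Cardiometabolic labs drawn conditionally on intended case status."""
    n = len(df)
    male = (df["sex"] == "male").to_numpy()

    def mix(key):
        m1, s1 = _CASE_LABS[key]
        m0, s0 = _CONTROL_LABS[key]
        m = np.where(case, m1, m0)
        s = np.where(case, s1, s0)
        return rng.normal(m, s, n)

    df["bmi"] = np.clip(mix("bmi"), 14, 60).round(1)
    wc = np.where(male, mix("wc_male"), mix("wc_female"))
    df["wc"] = np.clip(wc, 50, 160).round(1)
    df["glucose"] = np.clip(mix("glucose"), 55, 400).round(0)
    df["hba1c"] = np.clip(mix("hba1c"), 3.8, 15).round(1)
    df["sbp"] = np.clip(mix("sbp"), 70, 240).round(0)
    df["dbp"] = np.clip(mix("dbp"), 40, 140).round(0)
    df["tg"] = np.clip(mix("tg"), 25, 1500).round(0)
    hdl = np.where(male, mix("hdl_male"), mix("hdl_female"))
    df["hdl"] = np.clip(hdl, 15, 150).round(0)
    df["ldl"] = np.clip(mix("ldl"), 30, 300).round(0)
    df["cholesterol"] = np.clip(mix("cholesterol"), 80, 450).round(0)
    df["alt"] = np.clip(mix("alt"), 3, 500).round(0)
    df["antihypertensive_tx"] = rng.random(n) < np.where(case, 0.15, 0.03)
    df["lipid_lowering_tx"] = rng.random(n) < np.where(case, 0.08, 0.02)
    df["antidiabetic_tx"] = rng.random(n) < np.where(case, 0.06, 0.005)
    df["hx_diabetes"] = rng.random(n) < np.where(case, 0.099, 0.014)


def _criteria_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 5) boolean cardiometabolic criteria ignoring missingness."""
    male = (df["sex"] == "male").to_numpy()
    c1 = (df["bmi"] >= 23) | np.where(male, df["wc"] > 94, df["wc"] > 80)
    c2 = (
        (df["glucose"] >= 100)
        | (df["hba1c"] >= 5.7)
        | df["hx_diabetes"]
        | df["antidiabetic_tx"]
    )
    c3 = (df["sbp"] >= 130) | (df["dbp"] >= 85) | df["antihypertensive_tx"]
    c4 = (df["tg"] >= 150) | df["lipid_lowering_tx"]
    c5 = np.where(male, df["hdl"] <= 40, df["hdl"] <= 50) | df["lipid_lowering_tx"]
    return np.column_stack([c1, c2, c3, c4, np.asarray(c5, dtype=bool)])


def _force_no_criteria(df: pd.DataFrame, idx: np.ndarray, rng: np.random.Generator) -> None:
    """Overwrite labs so all five criteria are definitively false."""
    m = idx.sum() if idx.dtype == bool else len(idx)
    male = (df.loc[idx, "sex"] == "male").to_numpy()
    df.loc[idx, "bmi"] = rng.uniform(18.5, 22.8, m).round(1)
    df.loc[idx, "wc"] = np.where(
        male, rng.uniform(70, 93, m), rng.uniform(60, 79, m)
    ).round(1)
    df.loc[idx, "glucose"] = rng.uniform(75, 99, m).round(0)
    df.loc[idx, "hba1c"] = rng.uniform(4.8, 5.6, m).round(1)
    df.loc[idx, "sbp"] = rng.uniform(95, 128, m).round(0)
    df.loc[idx, "dbp"] = rng.uniform(55, 83, m).round(0)
    df.loc[idx, "tg"] = rng.uniform(40, 148, m).round(0)
    df.loc[idx, "hdl"] = np.where(
        male, rng.uniform(42, 80, m), rng.uniform(52, 90, m)
    ).round(0)
    for col in ("antihypertensive_tx", "lipid_lowering_tx", "antidiabetic_tx", "hx_diabetes"):
        df.loc[idx, col] = False


_MASLD_FIELDS = ("bmi", "wc", "glucose", "hba1c", "sbp", "dbp", "tg", "hdl")


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (participant table, monthly exposure table, truth record).

    The monthly exposure table is long-format with columns
    ``participant_id, pollutant, month, value`` where ``month`` is a pandas
    monthly Period column (serialised as yyyy-mm).  The truth record holds
    every true link, every coefficient, the calibrated intercept and the
    per-rule exclusion flags actually drawn, so downstream estimates can be
    compared against ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    df = _draw_covariates(cfg, rng)
    conc = _monthly_exposure_array(cfg, rng)  # (n, 6, M)
    window3 = conc[:, :, -36:].mean(axis=2)  # trailing 36 months

    # exclusion flags, independent of outcome
    fr = cfg.exclusion_fractions
    flags: dict[str, np.ndarray] = {}
    for rule in (
        "missing_exposure_or_sono",
        "age_under_18",
        "missing_masld_fields",
        "missing_alcohol",
        "cirrhosis_hcc",
        "hepatitis",
        "excess_alcohol",
        "sono_abnormality",
    ):
        flags[rule] = rng.random(n) < fr.get(rule, 0.0)
    excluded_pre = np.zeros(n, dtype=bool)
    for rule in flags:
        excluded_pre |= flags[rule]

    # latent logit on the true 3-year means
    eta = _covariate_eta(df, cfg.covariate_effects)
    for j, p in enumerate(POLLUTANTS):
        eta += cfg.true_links[p](window3[:, j])

    f_cryp = fr.get("cryptogenic", 0.0)
    t = cfg.intercept_calibration_target
    # retained prevalence equals t after cryptogenic non-cases are removed
    adj_target = t * (1.0 - f_cryp) / (1.0 - t * f_cryp)
    intercept = _calibrate_intercept(eta[~excluded_pre], adj_target)
    from scipy.special import expit

    p_case = expit(intercept + eta)
    case = rng.random(n) < p_case

    _draw_labs(df, case, rng)
    crit = _criteria_matrix(df)
    # guarantee cases satisfy at least one criterion (bump BMI into range)
    fix = case & ~crit.any(axis=1)
    if fix.any():
        df.loc[fix, "bmi"] = rng.uniform(23.0, 25.0, int(fix.sum())).round(1)

    steatosis = case.copy()
    cryptogenic = (~case) & (~excluded_pre) & (rng.random(n) < f_cryp)
    if cryptogenic.any():
        steatosis |= cryptogenic
        _force_no_criteria(df, cryptogenic, rng)
    df["steatosis_on_us"] = steatosis

    # history / abnormality flags
    df["hx_cirrhosis"] = flags["cirrhosis_hcc"] & (rng.random(n) < 0.8)
    df["hx_hcc"] = flags["cirrhosis_hcc"] & ~df["hx_cirrhosis"]
    df["hx_hepatitis"] = flags["hepatitis"]
    df["significant_sono_abnormality"] = flags["sono_abnormality"]

    # rule-triggering field overrides
    u18 = flags["age_under_18"]
    if u18.any():
        df.loc[u18, "age"] = rng.uniform(12.0, 17.9, int(u18.sum())).round(1)
    mm = flags["missing_masld_fields"]
    if mm.any():
        df.loc[mm, list(_MASLD_FIELDS)] = np.nan
        for col in ("antihypertensive_tx", "lipid_lowering_tx", "antidiabetic_tx", "hx_diabetes"):
            df.loc[mm, col] = False
        df.loc[mm, "steatosis_on_us"] = True
    ma = flags["missing_alcohol"]
    if ma.any():
        df.loc[ma, "alcohol_status"] = "current"
        df.loc[ma, "alcohol_days_per_week"] = np.nan
    ea = flags["excess_alcohol"] & ~ma
    if ea.any():
        m = int(ea.sum())
        df.loc[ea, "alcohol_status"] = "current"
        df.loc[ea, "alcohol_drinks_per_day"] = rng.integers(2, 6, m).astype(float)
        df.loc[ea, "alcohol_days_per_week"] = rng.integers(3, 8, m).astype(float)
        df.loc[ea, "alcohol_years"] = rng.integers(2, 20, m).astype(float)
    sono_missing = flags["missing_exposure_or_sono"] & (rng.random(n) < 0.5)
    exposure_missing = flags["missing_exposure_or_sono"] & ~sono_missing
    if sono_missing.any():
        df["steatosis_on_us"] = df["steatosis_on_us"].astype(object)
        df.loc[sono_missing, "steatosis_on_us"] = np.nan

    exposure = _long_exposure_frame(df, conc, exposure_missing, rng)

    truth = {
        "seed": cfg.seed,
        "intercept": intercept,
        "adjusted_prevalence_target": adj_target,
        "prevalence_target": t,
        "true_links": {p: cfg.true_links[p].to_dict() for p in POLLUTANTS},
        "covariate_effects": dict(cfg.covariate_effects),
        "n_cases_intended": int(case.sum()),
        "n_cryptogenic": int(cryptogenic.sum()),
        "exclusion_flag_counts": {k: int(v.sum()) for k, v in flags.items()},
        "window3_means": {
            p: float(window3[:, j].mean()) for j, p in enumerate(POLLUTANTS)
        },
    }
    return df, exposure, truth


def _long_exposure_frame(
    df: pd.DataFrame,
    conc: np.ndarray,
    exposure_missing: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Melt the (n, 6, M) array to long format with real calendar months.

    Participants flagged as exposure-missing keep only a random ~60% of
    months, pushing trailing-window coverage below the completeness rule.
    """
    n, npol, M = conc.shape
    index_ord = (
        df["checkup_date"].dt.year.to_numpy() * 12
        + df["checkup_date"].dt.month.to_numpy()
        - 1
    )  # month ordinal, Jan year Y = Y*12
    # month m (0..M-1) is index_ord - (M - m) i.e. strictly before index month
    offsets = np.arange(M) - M
    month_ord = index_ord[:, None] + offsets[None, :]  # (n, M)

    pid = np.repeat(df["id"].to_numpy(), npol * M)
    pol = np.tile(np.repeat(np.array(POLLUTANTS, dtype=object), M), n)
    months = np.tile(month_ord[:, None, :], (1, npol, 1)).reshape(-1)
    values = conc.reshape(-1)

    keep = np.ones(values.size, dtype=bool)
    if exposure_missing.any():
        drop_person = np.repeat(exposure_missing, npol * M)
        keep = ~(drop_person & (rng.random(values.size) < 0.4))
    out = pd.DataFrame(
        {
            "participant_id": pid[keep],
            "pollutant": pol[keep],
            "month": pd.PeriodIndex.from_ordinals(
                months[keep].astype("int64") - 1970 * 12, freq="M"
            ),
            "value": values[keep],
        }
    )
    return out


# ---------------------------------------------------------------------------
# exclusion-cascade fixture


def generate_exclusion_fixture(seed: int = 0) -> tuple[pd.DataFrame, dict[str, int]]:
    """A ~100-row participant table exercising every exclusion rule once or more.

    Each engineered record triggers exactly one rule under first-trigger
    (sequential) semantics, so the expected cascade counts are known by
    construction and returned alongside the table.
    """
    rng = np.random.default_rng(seed)
    counts = {
        "missing_exposure_or_sono": 2,
        "duplicate_record": 2,
        "age_under_18": 4,
        "missing_masld_fields": 6,
        "missing_alcohol": 5,
        "cirrhosis_hcc": 3,
        "hepatitis": 7,
        "excess_alcohol": 4,
        "sono_abnormality": 3,
        "cryptogenic": 5,
    }
    n_clean_case, n_clean_control = 30, 29
    rows: list[dict] = []

    def base(pid: int) -> dict:
        return {
            "id": pid,
            "checkup_date": pd.Timestamp(2014, 6, 15),
            "age": float(rng.integers(25, 60)),
            "sex": "female" if rng.random() < 0.5 else "male",
            "alcohol_status": "never",
            "alcohol_drinks_per_day": 0.0,
            "alcohol_days_per_week": 0.0,
            "alcohol_years": 0.0,
            "bmi": 21.0, "wc": 70.0, "glucose": 90.0, "hba1c": 5.2,
            "sbp": 115.0, "dbp": 70.0, "tg": 100.0, "hdl": 65.0,
            "antihypertensive_tx": False, "lipid_lowering_tx": False,
            "antidiabetic_tx": False, "hx_diabetes": False,
            "hx_cirrhosis": False, "hx_hcc": False, "hx_hepatitis": False,
            "steatosis_on_us": False,
            "significant_sono_abnormality": False,
            "pm25_3yr": float(rng.normal(30, 5)),
            "enrollment_year": 2014,
        }

    pid = 0
    for _ in range(counts["missing_exposure_or_sono"]):
        pid += 1
        r = base(pid)
        r["pm25_3yr"] = np.nan
        rows.append(r)
    for _ in range(counts["duplicate_record"]):
        pid += 1
        r = base(pid)
        rows.append(r)
        r2 = dict(r)
        r2["checkup_date"] = pd.Timestamp(2015, 3, 1)  # later record, removed
        rows.append(r2)
    for _ in range(counts["age_under_18"]):
        pid += 1
        r = base(pid)
        r["age"] = float(rng.integers(12, 18))
        rows.append(r)
    for _ in range(counts["missing_masld_fields"]):
        pid += 1
        r = base(pid)
        r["steatosis_on_us"] = True
        for f in _MASLD_FIELDS:
            r[f] = np.nan
        rows.append(r)
    for _ in range(counts["missing_alcohol"]):
        pid += 1
        r = base(pid)
        r["alcohol_status"] = "current"
        r["alcohol_days_per_week"] = np.nan
        rows.append(r)
    for _ in range(counts["cirrhosis_hcc"]):
        pid += 1
        r = base(pid)
        r["hx_cirrhosis"] = True
        rows.append(r)
    for _ in range(counts["hepatitis"]):
        pid += 1
        r = base(pid)
        r["hx_hepatitis"] = True
        rows.append(r)
    for _ in range(counts["excess_alcohol"]):
        pid += 1
        r = base(pid)
        r.update(
            alcohol_status="current",
            alcohol_drinks_per_day=3.0,
            alcohol_days_per_week=5.0,
            alcohol_years=4.0,
        )
        rows.append(r)
    for _ in range(counts["sono_abnormality"]):
        pid += 1
        r = base(pid)
        r["significant_sono_abnormality"] = True
        rows.append(r)
    for _ in range(counts["cryptogenic"]):
        pid += 1
        r = base(pid)
        r["steatosis_on_us"] = True  # all criteria false in base -> cryptogenic
        rows.append(r)
    for _ in range(n_clean_case):
        pid += 1
        r = base(pid)
        r["steatosis_on_us"] = True
        r["bmi"] = 26.0  # criterion 1
        rows.append(r)
    for _ in range(n_clean_control):
        pid += 1
        rows.append(base(pid))

    table = pd.DataFrame(rows)
    truth = dict(counts)
    truth["retained"] = n_clean_case + n_clean_control + counts["duplicate_record"]
    truth["n_input"] = len(table)
    return table, truth
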
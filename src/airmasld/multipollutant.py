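"""Joint multi-pollutant logistic models, segment odds ratios, diagnostics
and predicted exposure-response curves.

One logistic regression simultaneously contains all six pollutants (PM2.5,
PM10, O3, CO, SO2, NO2), each encoded through its selected link function,
plus the adjustment covariates and enrollment year.  Variants: exposure
categorised at the inflection points (lowest segment as reference), all
links forced linear, and subsets of pollutants (e.g. dropping PM10 for
collinearity).  Segment-wise adjusted odds ratios (per 1 µg/m³) come with
delta-method confidence intervals; for spline links the per-unit aOR within
a segment is the observed-exposure-weighted average derivative of the
fitted logit.  Collinearity is reported as tolerance / VIF per design
column and pairwise Pearson correlation with Fisher-z intervals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .link_basis import LinkKind, LinkSpec, basis_matrix, rcs_basis_derivative

__all__ = [
    "MultiPollutantModel",
    "PredictedCurve",
    "fit_multipollutant",
    "fit_categorized",
    "fit_all_linear",
    "fit_subset",
    "segment_or",
    "segment_table",
    "collinearity_diagnostics",
    "predicted_curve",
    "compare_models",
    "cohort_fingerprint",
]

_Z95 = norm.ppf(0.975)


def cohort_fingerprint(cohort: pd.DataFrame, outcome_col: str = "masld") -> str:
    """Hash of participant ids and outcomes; guards AIC comparability."""
    ids = (
        cohort["id"].to_numpy()
        if "id" in cohort
        else cohort.index.to_numpy()
    )
    h = hashlib.sha256()
    h.update(np.asarray(ids).astype("int64").tobytes())
    h.update(cohort[outcome_col].to_numpy(dtype=np.int8).tobytes())
    return h.hexdigest()


@dataclass
class MultiPollutantModel:
    """A fitted joint logistic model over several pollutant encodings."""

    specs: dict[str, LinkSpec]
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n_params: int
    column_blocks: dict[str, list[str]]
    exposures: dict[str, np.ndarray]
    design_means: pd.Series
    fingerprint: str
    n_obs: int
    categorized_cutpoints: dict[str, list[float]] | None = None
    diagnostics: pd.DataFrame | None = None
    pollutant_correlations: pd.DataFrame | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    def to_dict(self) -> dict:
        return {
            "specs": {p: s.to_json() for p, s in self.specs.items()},
            "params": self.params.to_dict(),
            "llf": self.llf,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "fingerprint": self.fingerprint,
        }


@dataclass
class PredictedCurve:
    """Adjusted logit along an exposure grid, co-pollutants and covariates
    held at their sample means (observed proportions for dummies)."""

    pollutant: str
    grid: np.ndarray
    logit: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"exposure": self.grid, "adjusted_logit": self.logit}
        ).assign(pollutant=self.pollutant)


def _assemble_design(
    cohort: pd.DataFrame,
    specs: dict[str, LinkSpec],
    covariates: pd.DataFrame | None,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, np.ndarray]]:
    n = len(cohort)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    blocks: dict[str, list[str]] = {}
    exposures: dict[str, np.ndarray] = {}
    for p, spec in specs.items():
        col = p if p in cohort else f"{p}_3yr"
        x = cohort[col].to_numpy(dtype=float)
        exposures[p] = x
        B = basis_matrix(x, spec)
        names = spec.column_names()
        blocks[p] = names
        for name, column in zip(names, B.T):
            cols[name] = column
    if covariates is not None:
        for name in covariates.columns:
            cols[str(name)] = covariates[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cohort.index)
    return X, blocks, exposures


def _fit(X: pd.DataFrame, y: np.ndarray) -> sm.discrete.discrete_model.BinaryResults:
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient joint design")
    res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("joint logistic fit did not converge")
    return res


def fit_multipollutant(
    cohort: pd.DataFrame,
    specs: dict[str, LinkSpec],
    covariates: pd.DataFrame | None = None,
    include: list[str] | None = None,
    outcome_col: str = "masld",
    with_diagnostics: bool = True,
) -> MultiPollutantModel:
    """Fit the joint logistic model with each pollutant's selected encoding.

    ``covariates`` is a ready-made model matrix (see
    :func:`airmasld.cohort_build.encode_covariates`); metabolic comorbidities
    are intentionally not part of it.  ``include`` restricts the pollutant
    set (default: every key of ``specs``).
    """
    use = {p: specs[p] for p in (include if include is not None else specs)}
    y = cohort[outcome_col].to_numpy(dtype=float)
    X, blocks, exposures = _assemble_design(cohort, use, covariates)
    res = _fit(X, y)
    model = MultiPollutantModel(
        specs=use,
        params=res.params,
        cov_params=res.cov_params(),
        llf=float(res.llf),
        n_params=X.shape[1],
        column_blocks=blocks,
        exposures=exposures,
        design_means=X.mean(axis=0),
        fingerprint=cohort_fingerprint(cohort, outcome_col),
        n_obs=len(cohort),
    )
    if with_diagnostics:
        pollutant_cols = [c for names in blocks.values() for c in names]
        model.diagnostics = collinearity_diagnostics(X.drop(columns="const"))
        model.pollutant_correlations = pearson_correlations(
            pd.DataFrame(exposures, index=cohort.index)
        )
    return model


def fit_all_linear(
    cohort: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    pollutants: list[str] | None = None,
    outcome_col: str = "masld",
) -> MultiPollutantModel:
    """Sensitivity variant: every pollutant enters linearly."""
    if pollutants is None:
        from .synthetic_cohort import POLLUTANTS

        pollutants = [
            p for p in POLLUTANTS if p in cohort or f"{p}_3yr" in cohort
        ]
    specs = {p: LinkSpec(p, LinkKind.LINEAR) for p in pollutants}
    return fit_multipollutant(cohort, specs, covariates, outcome_col=outcome_col)


def fit_subset(
    cohort: pd.DataFrame,
    specs: dict[str, LinkSpec],
    exclude: list[str],
    covariates: pd.DataFrame | None = None,
    outcome_col: str = "masld",
) -> MultiPollutantModel:
    """Sensitivity variant dropping pollutants (e.g. PM10 for collinearity)."""
    include = [p for p in specs if p not in set(exclude)]
    return fit_multipollutant(cohort, specs, covariates, include, outcome_col)


def fit_categorized(
    cohort: pd.DataFrame,
    cutpoints: dict[str, list[float]],
    covariates: pd.DataFrame | None = None,
    outcome_col: str = "masld",
) -> MultiPollutantModel:
    """Joint model with exposures categorised at the inflection points.

    Each pollutant becomes segment indicators (lowest segment = reference);
    the aOR of a non-reference segment is ``exp(coefficient)`` against the
    reference.  Raises if any segment is empty.
    """
    y = cohort[outcome_col].to_numpy(dtype=float)
    n = len(cohort)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    blocks: dict[str, list[str]] = {}
    exposures: dict[str, np.ndarray] = {}
    for p, cuts in cutpoints.items():
        col = p if p in cohort else f"{p}_3yr"
        x = cohort[col].to_numpy(dtype=float)
        exposures[p] = x
        edges = [-np.inf] + sorted(cuts) + [np.inf]
        names = []
        for s in range(1, len(edges) - 1):
            ind = ((x >= edges[s]) & (x < edges[s + 1])).astype(float)
            if ind.sum() == 0:
                raise ValueError(f"empty segment {s} for {p}")
            name = f"{p}_seg{s}"
            cols[name] = ind
            names.append(name)
        if (x < edges[1]).sum() == 0:
            raise ValueError(f"empty reference segment for {p}")
        blocks[p] = names
    if covariates is not None:
        for name in covariates.columns:
            cols[str(name)] = covariates[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cohort.index)
    res = _fit(X, y)
    return MultiPollutantModel(
        specs={},
        params=res.params,
        cov_params=res.cov_params(),
        llf=float(res.llf),
        n_params=X.shape[1],
        column_blocks=blocks,
        exposures=exposures,
        design_means=X.mean(axis=0),
        fingerprint=cohort_fingerprint(cohort, outcome_col),
        n_obs=n,
        categorized_cutpoints={p: sorted(c) for p, c in cutpoints.items()},
    )


# ---------------------------------------------------------------------------
# segment odds ratios


def _or_ci(est: float, se: float) -> tuple[float, float, float]:
    return (
        float(np.exp(est)),
        float(np.exp(est - _Z95 * se)),
        float(np.exp(est + _Z95 * se)),
    )


def segment_or(
    model: MultiPollutantModel,
    pollutant: str,
    bounds: tuple[float, float],
    endpoint_contrast: bool = False,
) -> dict:
    """Adjusted odds ratio per 1 µg/m³ within an exposure segment.

    linear: exp(slope).  threshold: structurally 1 below the cutpoint
    (zero-width interval), exp(hinge slope) above.  interaction: exp of the
    relevant segment slope.  RCS: exp of the observed-exposure-weighted mean
    derivative of the fitted logit over the segment with a delta-method
    interval; with ``endpoint_contrast=True`` the per-unit aOR is instead
    derived from the logit difference between the segment endpoints divided
    by the segment width.
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("segment bounds must satisfy lo < hi")
    x = model.exposures[pollutant]
    if hi < np.min(x) or lo > np.max(x):
        raise ValueError("segment lies outside the observed exposure support")
    if model.categorized_cutpoints is not None:
        raise ValueError("use the coefficient table directly for categorized models")
    spec = model.specs[pollutant]
    names = model.column_blocks[pollutant]
    beta = model.params[names].to_numpy()
    V = model.cov_params.loc[names, names].to_numpy()

    if spec.kind is LinkKind.LINEAR:
        or_, lo_, hi_ = _or_ci(beta[0], np.sqrt(V[0, 0]))
    elif spec.kind is LinkKind.THRESHOLD:
        if hi <= spec.cutpoint:
            return {
                "pollutant": pollutant, "lo": lo, "hi": hi,
                "aor": 1.0, "ci_low": 1.0, "ci_high": 1.0, "structural": True,
            }
        or_, lo_, hi_ = _or_ci(beta[0], np.sqrt(V[0, 0]))
    elif spec.kind is LinkKind.INTERACTION:
        if hi <= spec.cutpoint:
            contrast = np.array([1.0, 0.0, 0.0])
        else:
            contrast = np.array([1.0, 0.0, 1.0])
        est = float(contrast @ beta)
        se = float(np.sqrt(contrast @ V @ contrast))
        or_, lo_, hi_ = _or_ci(est, se)
    else:  # RCS
        in_seg = (x >= lo) & (x < hi)
        if not in_seg.any():
            raise ValueError("no observed exposures inside the segment")
        if endpoint_contrast:
            from .link_basis import rcs_basis

            b_hi = rcs_basis(np.array([hi]), spec.knots)[0]
            b_lo = rcs_basis(np.array([lo]), spec.knots)[0]
            contrast = (b_hi - b_lo) / (hi - lo)
        else:
            D = rcs_basis_derivative(x[in_seg], spec.knots)
            contrast = D.mean(axis=0)
        est = float(contrast @ beta)
        se = float(np.sqrt(contrast @ V @ contrast))
        or_, lo_, hi_ = _or_ci(est, se)
    return {
        "pollutant": pollutant, "lo": lo, "hi": hi,
        "aor": or_, "ci_low": lo_, "ci_high": hi_, "structural": False,
    }


def segment_table(
    model: MultiPollutantModel, segment_bounds: dict[str, list[tuple[float, float]]]
) -> pd.DataFrame:
    """Per-segment aOR table (one row per pollutant segment)."""
    rows = [
        segment_or(model, p, b) for p, bl in segment_bounds.items() for b in bl
    ]
    return pd.DataFrame(rows)


def categorized_or_table(model: MultiPollutantModel) -> pd.DataFrame:
    """aORs (vs the lowest segment) from a categorised joint model."""
    if model.categorized_cutpoints is None:
        raise ValueError("model is not categorized")
    rows = []
    for p, names in model.column_blocks.items():
        rows.append(
            {"pollutant": p, "segment": 0, "aor": 1.0, "ci_low": 1.0,
             "ci_high": 1.0, "reference": True}
        )
        for s, name in enumerate(names, start=1):
            b = float(model.params[name])
            se = float(np.sqrt(model.cov_params.loc[name, name]))
            or_, lo_, hi_ = _or_ci(b, se)
            rows.append(
                {"pollutant": p, "segment": s, "aor": or_, "ci_low": lo_,
                 "ci_high": hi_, "reference": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics


def collinearity_diagnostics(design: pd.DataFrame) -> pd.DataFrame:
    """Tolerance and VIF per design column.

    VIF_j = 1 / (1 - R²_j) where R²_j comes from the least-squares
    regression of column j on all the other columns plus an intercept;
    tolerance is 1/VIF.  Perfect collinearity yields infinite VIF rather
    than an error.
    """
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    rows = []
    n = X.shape[0]
    for j, name in enumerate(names):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss == 0:
            r2 = 1.0
        else:
            r2 = 1.0 - np.sum(resid**2) / tss
        tol = max(0.0, 1.0 - r2)
        vif = np.inf if tol == 0 else 1.0 / tol
        rows.append({"term": name, "r_squared": r2, "tolerance": tol, "vif": vif})
    return pd.DataFrame(rows).set_index("term")


def pearson_correlations(exposures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between exposure columns with Fisher-z 95% CIs."""
    cols = list(exposures.columns)
    n = len(exposures)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(
                np.corrcoef(exposures[cols[i]], exposures[cols[j]])[0, 1]
            )
            z = np.arctanh(np.clip(r, -0.999999, 0.999999))
            se = 1.0 / np.sqrt(max(n - 3, 1))
            rows.append(
                {
                    "a": cols[i], "b": cols[j], "r": r,
                    "ci_low": float(np.tanh(z - _Z95 * se)),
                    "ci_high": float(np.tanh(z + _Z95 * se)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# predicted curves and model comparison


def predicted_curve(
    model: MultiPollutantModel,
    pollutant: str,
    grid: np.ndarray | None = None,
    n_points: int = 200,
    extrapolation_margin: float = 0.0,
) -> PredictedCurve:
    """Adjusted logit across an exposure grid with everything else at means.

    The pollutant's own basis is evaluated on the grid while every other
    design column (co-pollutants, covariate dummies, enrollment year) is
    fixed at its sample mean — for dummies, the observed proportion.  Grids
    outside the observed range by more than ``extrapolation_margin`` times
    the range raise.
    """
    x = model.exposures[pollutant]
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if grid is None:
        grid = np.linspace(xmin, xmax, n_points)
    grid = np.asarray(grid, dtype=float)
    span = xmax - xmin
    if grid.min() < xmin - extrapolation_margin * span or grid.max() > xmax + extrapolation_margin * span:
        raise ValueError("grid extends beyond the observed exposure range")

    base = model.design_means.copy()
    row = pd.DataFrame(
        np.tile(base.to_numpy(), (grid.size, 1)), columns=base.index
    )
    row["const"] = 1.0
    names = model.column_blocks[pollutant]
    if model.categorized_cutpoints is not None:
        edges = [-np.inf] + model.categorized_cutpoints[pollutant] + [np.inf]
        for s, name in enumerate(names, start=1):
            row[name] = ((grid >= edges[s]) & (grid < edges[s + 1])).astype(float)
    else:
        B = basis_matrix(grid, model.specs[pollutant])
        for name, columnn in zip(names, B.T):
            row[name] = columnn
    logit = row[model.params.index].to_numpy() @ model.params.to_numpy()
    return PredictedCurve(pollutant=pollutant, grid=grid, logit=logit)


def compare_models(models: dict[str, MultiPollutantModel]) -> pd.DataFrame:
    """AIC ranking of models fitted on the identical cohort and outcome.

    Refuses (raises) when cohort fingerprints differ, since AIC is only
    comparable on identical data.  Output ordering is by AIC, independent
    of input order.
    """
    fps = {m.fingerprint for m in models.values()}
    if len(fps) > 1:
        raise ValueError("models were fitted on different cohorts; AIC not comparable")
    rows = [
        {"model": name, "aic": m.aic, "llf": m.llf, "n_params": m.n_params}
        for name, m in models.items()
    ]
    out = pd.DataFrame(rows).sort_values(["aic", "model"], kind="stable")
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out.reset_index(drop=True)
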
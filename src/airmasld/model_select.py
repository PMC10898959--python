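"""Stepwise identification of the best-fitted link function per pollutant.

The algorithm mirrors the study procedure:

1. Box-Tidwell linearity gate: test the Wald significance of the
   ``x * ln(x)`` interaction in a logistic model containing ``x``; if not
   significant at alpha, the linear link is retained and the search stops.
2. Otherwise build the 100-percentile-bin empirical-logit curve and estimate
   the inflection point by segmented weighted non-linear least squares.
3. Fit the candidate encodings — linear, threshold(c), interaction(c), and a
   4-knot restricted cubic spline — as one-pollutant logistic models
   (covariate-adjusted and unadjusted) and compare covariate-adjusted AICs.
4. Candidates within ``aic_delta`` (default 10) of the minimum are deemed
   equally fitted and the simplest wins, in the fixed order
   threshold < interaction < RCS(3) < ... < RCS(7).  The linear fit is
   reported alongside but is not an eligible winner at this stage: by
   construction it already failed the linearity gate.
5. If the 4-knot spline survives step 4, splines with 3-7 knots are
   evaluated and the same rule is re-applied among them (fewer knots are
   simpler).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .link_basis import LinkKind, LinkSpec, basis_matrix, default_knots
from .inflection_search import binned_logit, fit_segmented

__all__ = [
    "CandidateFit",
    "SelectionResult",
    "box_tidwell",
    "fit_candidate",
    "aic_parsimony_choose",
    "select_link",
    "simplicity_rank",
]


@dataclass
class CandidateFit:
    """One fitted one-pollutant logistic model and its information criterion."""

    spec: LinkSpec | None
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n_params: int
    adjusted: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    def label(self) -> str:
        if self.spec is None:
            return "intercept_only"
        if self.spec.kind is LinkKind.RCS:
            return f"rcs{len(self.spec.knots)}"
        return self.spec.kind.value


@dataclass
class SelectionResult:
    pollutant: str
    box_tidwell_p: float
    inflection: float | None
    aic_table: dict[str, float]
    unadjusted_aic_table: dict[str, float]
    chosen: LinkSpec
    tie_rule_applied: bool
    candidates: dict[str, CandidateFit] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "box_tidwell_p": self.box_tidwell_p,
            "inflection": self.inflection,
            "aic_table": self.aic_table,
            "unadjusted_aic_table": self.unadjusted_aic_table,
            "chosen": self.chosen.to_json(),
            "tie_rule_applied": self.tie_rule_applied,
            "errors": self.errors,
        }


def _fit_logit(design: np.ndarray, y: np.ndarray, colnames: list[str]):
    model = sm.Logit(y, pd.DataFrame(design, columns=colnames))
    return model.fit(disp=0, maxiter=200, method="newton")


def box_tidwell(
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    use_lr: bool = False,
) -> float:
    """Box-Tidwell linearity test p-value for a logistic dose-response.

    Adds ``x * ln(x)`` alongside ``x`` (plus covariates) and returns the
    Wald p-value of the interaction term; ``p >= alpha`` means the
    proportional-odds (linear) assumption is retained.  Exposures with
    ``min(x) <= 0`` are shifted by ``1 - min(x)`` before taking logs.
    With ``use_lr=True`` a likelihood-ratio p-value is returned instead.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant exposure: linearity is undefined")
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    xs = x + shift
    xlnx = xs * np.log(xs)

    blocks = [np.ones_like(x), x, xlnx]
    names = ["const", "x", "x_lnx"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        blocks.append(C)
        if isinstance(covariates, pd.DataFrame):
            names += list(covariates.columns)
        else:
            names += [f"c{i}" for i in range(C.shape[1])]
    design = np.column_stack(blocks)
    try:
        res = _fit_logit(design, y, names)
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        raise RuntimeError(f"Box-Tidwell fit failed: {e}") from e
    if not use_lr:
        return float(res.pvalues["x_lnx"])
    reduced = _fit_logit(np.delete(design, 2, axis=1), y, [n for n in names if n != "x_lnx"])
    from scipy.stats import chi2

    lr = 2.0 * (res.llf - reduced.llf)
    return float(chi2.sf(max(lr, 0.0), df=1))


def fit_candidate(
    cohort: pd.DataFrame,
    pollutant: str,
    spec: LinkSpec | None,
    covariates: pd.DataFrame | None = None,
    adjusted: bool = True,
    outcome_col: str = "masld",
) -> CandidateFit:
    """Maximum-likelihood one-pollutant logistic fit for a given encoding.

    The design is intercept + basis(spec) and, when ``adjusted``, the
    supplied covariate model matrix (which should already contain the
    enrollment-year dummies).  ``spec=None`` fits the exposure-free
    (intercept-only + covariates) reference model.  AIC is ``2k - 2*loglik``.
    """
    y = cohort[outcome_col].to_numpy(dtype=float)
    n = len(cohort)
    if spec is None:
        names = ["const"]
        blocks = [np.ones((n, 1))]
    else:
        exposure_col = pollutant if pollutant in cohort else f"{pollutant}_3yr"
        x = cohort[exposure_col].to_numpy(dtype=float)
        B = basis_matrix(x, spec)
        names = ["const"] + spec.column_names()
        blocks = [np.ones((n, 1)), B]
    if adjusted and covariates is not None:
        blocks.append(np.asarray(covariates, dtype=float))
        names += list(covariates.columns)
    design = np.column_stack(blocks)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design is rank deficient for this candidate")
    res = _fit_logit(design, y, names)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    return CandidateFit(
        spec=spec,
        params=res.params,
        cov_params=res.cov_params(),
        llf=float(res.llf),
        n_params=design.shape[1],
        adjusted=adjusted and covariates is not None,
    )


def simplicity_rank(spec: LinkSpec) -> int:
    """Fixed parsimony order: linear < threshold < interaction < RCS(3..7)."""
    if spec.kind is LinkKind.LINEAR:
        return 0
    if spec.kind is LinkKind.THRESHOLD:
        return 1
    if spec.kind is LinkKind.INTERACTION:
        return 2
    return 3 + (len(spec.knots) - 3)


def aic_parsimony_choose(
    candidates: list[CandidateFit],
    delta: float = 10.0,
    linear_eligible: bool = False,
) -> tuple[CandidateFit, bool]:
    """Among candidates within ``delta`` AIC of the minimum, return the
    simplest; second element reports whether the tie rule overrode the
    strict AIC minimiser.

    By default the linear link is not an eligible winner here: it competes
    at the earlier linearity-test stage, and this comparison is run only
    among the non-linear families once proportional odds has been rejected
    (the linear fit may still be present for reporting).  Pass
    ``linear_eligible=True`` for a plain within-delta parsimony choice over
    everything supplied.
    """
    finite = [c for c in candidates if np.isfinite(c.aic)]
    if not linear_eligible:
        nonlin = [
            c for c in finite
            if c.spec is not None and c.spec.kind is not LinkKind.LINEAR
        ]
        if nonlin:
            finite = nonlin
    if not finite:
        raise ValueError("no candidate with finite AIC")
    best_aic = min(c.aic for c in finite)
    tied = [c for c in finite if c.aic <= best_aic + delta]
    chosen = min(tied, key=lambda c: simplicity_rank(c.spec))
    strict = min(finite, key=lambda c: c.aic)
    return chosen, chosen is not strict


def select_link(
    cohort: pd.DataFrame,
    pollutant: str,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_bins: int = 100,
    aic_delta: float = 10.0,
    default_rcs_knots: int = 4,
    outcome_col: str = "masld",
) -> SelectionResult:
    """Run the full stepwise link-function identification for one pollutant.

    Selection is decided on covariate-adjusted AICs (unadjusted fits are
    reported when covariates are supplied).  Candidate fits that fail are
    recorded under ``errors`` and selection proceeds over the successes.
    """
    exposure_col = pollutant if pollutant in cohort else f"{pollutant}_3yr"
    x = cohort[exposure_col].to_numpy(dtype=float)
    y = cohort[outcome_col].to_numpy(dtype=float)

    p_bt = box_tidwell(x, y, covariates)
    linear_spec = LinkSpec(pollutant, LinkKind.LINEAR)
    if p_bt >= alpha:
        fit = fit_candidate(cohort, pollutant, linear_spec, covariates, True, outcome_col)
        return SelectionResult(
            pollutant=pollutant,
            box_tidwell_p=p_bt,
            inflection=None,
            aic_table={"linear": fit.aic},
            unadjusted_aic_table={},
            chosen=linear_spec,
            tie_rule_applied=False,
            candidates={"linear": fit},
        )

    curve = binned_logit(x, y, n_bins=n_bins)
    seg = fit_segmented(curve)
    c_hat = seg.cutpoint

    specs = [
        linear_spec,
        LinkSpec(pollutant, LinkKind.THRESHOLD, cutpoint=c_hat),
        LinkSpec(pollutant, LinkKind.INTERACTION, cutpoint=c_hat),
        LinkSpec(pollutant, LinkKind.RCS, knots=default_knots(x, default_rcs_knots)),
    ]
    fits: dict[str, CandidateFit] = {}
    unadj: dict[str, float] = {}
    errors: dict[str, str] = {}
    for spec in specs:
        label = spec.kind.value if spec.kind is not LinkKind.RCS else f"rcs{len(spec.knots)}"
        try:
            fits[label] = fit_candidate(cohort, pollutant, spec, covariates, True, outcome_col)
            if covariates is not None:
                unadj[label] = fit_candidate(
                    cohort, pollutant, spec, None, False, outcome_col
                ).aic
        except Exception as e:  # propagate per-candidate failures as records
            errors[label] = str(e)

    chosen_fit, tie = aic_parsimony_choose(list(fits.values()), aic_delta)

    if chosen_fit.spec.kind is LinkKind.RCS:
        rcs_fits: list[CandidateFit] = []
        for k in range(3, 8):
            label = f"rcs{k}"
            if label in fits:
                rcs_fits.append(fits[label])
                continue
            try:
                spec_k = LinkSpec(pollutant, LinkKind.RCS, knots=default_knots(x, k))
                fits[label] = fit_candidate(
                    cohort, pollutant, spec_k, covariates, True, outcome_col
                )
                if covariates is not None:
                    unadj[label] = fit_candidate(
                        cohort, pollutant, spec_k, None, False, outcome_col
                    ).aic
                rcs_fits.append(fits[label])
            except Exception as e:
                errors[label] = str(e)
        chosen_fit, tie_rcs = aic_parsimony_choose(rcs_fits, aic_delta)
        tie = tie or tie_rcs

    return SelectionResult(
        pollutant=pollutant,
        box_tidwell_p=p_bt,
        inflection=c_hat,
        aic_table={k: f.aic for k, f in fits.items()},
        unadjusted_aic_table=unadj,
        chosen=chosen_fit.spec,
        tie_rule_applied=tie,
        candidates=fits,
        errors=errors,
    )
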
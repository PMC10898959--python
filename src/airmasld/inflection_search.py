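"""Percentile-binned empirical-logit curves and segmented inflection-point search.

When the linearity test rejects proportional odds, the exposure range is cut
into (up to) 100 percentile bins and the empirical logit of the outcome is
computed per bin.  A continuous broken-stick model

    g(x) = a + b1 * x + (b2 - b1) * max(0, x - c)

is then fitted to the binned curve by weighted non-linear least squares
(weights = bin sizes), profiling over the breakpoint ``c``: for fixed ``c``
the model is linear in ``(a, b1, b2 - b1)``, so the search is a coarse grid
over interior bin means followed by bounded local refinement.  The estimated
``c`` is the inflection point used to build the threshold and interaction
candidate encodings downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["BinnedLogitCurve", "SegmentedFit", "binned_logit", "fit_segmented"]


@dataclass(frozen=True)
class BinnedLogitCurve:
    """Per-bin summary of an exposure-outcome relationship.

    ``logit`` uses the continuity-corrected empirical logit
    ``ln((cases + 0.5) / (n - cases + 0.5))`` so it is finite even for
    all-case or no-case bins.
    """

    mean_exposure: np.ndarray
    n: np.ndarray
    cases: np.ndarray
    logit: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.mean_exposure.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_exposure": self.mean_exposure,
                "n": self.n,
                "cases": self.cases,
                "empirical_logit": self.logit,
            }
        )


@dataclass(frozen=True)
class SegmentedFit:
    """A fitted continuous broken-stick on a binned logit curve."""

    cutpoint: float
    intercept: float
    slope_below: float
    slope_above: float
    sse: float
    converged: bool
    iterations: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.slope_below * x
            + (self.slope_above - self.slope_below) * np.maximum(0.0, x - self.cutpoint)
        )

    def to_dict(self) -> dict:
        return {
            "cutpoint": self.cutpoint,
            "intercept": self.intercept,
            "slope_below": self.slope_below,
            "slope_above": self.slope_above,
            "sse": self.sse,
            "converged": self.converged,
            "iterations": self.iterations,
        }


def binned_logit(
    exposure: np.ndarray, outcome: np.ndarray, n_bins: int = 100
) -> BinnedLogitCurve:
    """Cut exposures into percentile bins and compute per-bin empirical logits.

    Bins are equal-count by rank; tied exposure values are kept in one bin
    (quantile binning), so fewer than ``n_bins`` bins may result under heavy
    ties.  Requires at least ``n_bins`` observations.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size:
        raise ValueError("exposure and outcome lengths differ")
    if x.size < n_bins:
        raise ValueError(f"need at least {n_bins} observations, got {x.size}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # rank-based equal-count bins, then merge bins whose exposure ranges
    # collide because of ties (qcut semantics)
    edges = np.quantile(xs, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        bin_id = np.zeros(xs.size, dtype=int)
    else:
        bin_id = np.searchsorted(edges, xs, side="right") - 1
        bin_id = np.clip(bin_id, 0, edges.size - 2)
    df = pd.DataFrame({"bin": bin_id, "x": xs, "y": ys})
    g = df.groupby("bin", sort=True).agg(
        mean_exposure=("x", "mean"), n=("y", "size"), cases=("y", "sum")
    )
    n = g["n"].to_numpy(dtype=float)
    cases = g["cases"].to_numpy(dtype=float)
    logit = np.log((cases + 0.5) / (n - cases + 0.5))
    return BinnedLogitCurve(
        mean_exposure=g["mean_exposure"].to_numpy(),
        n=n.astype(int),
        cases=cases.astype(int),
        logit=logit,
    )


def _broken_stick_sse(
    c: float, x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted LS of y on [1, x, (x-c)+]; returns (SSE, coefficients)."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ beta
    return float(np.sum(w * resid**2)), beta


def fit_segmented(
    curve: BinnedLogitCurve,
    percentile_bounds: tuple[float, float] = (5.0, 95.0),
    refine_xtol: float = 1e-8,
) -> SegmentedFit:
    """Estimate the inflection point of a binned logit curve.

    Minimises the bin-size-weighted SSE of the continuous broken-stick model
    over breakpoints inside the ``percentile_bounds`` percentile range of bin
    means.  Profiling: every interior bin mean is tried as a grid candidate
    (ties broken toward the smaller breakpoint), then a bounded golden-section
    refinement runs between the grid neighbours of the winner.  The refined
    point is only kept when it does not increase the SSE, so the returned fit
    is never worse than the best grid candidate.
    """
    x = np.asarray(curve.mean_exposure, dtype=float)
    y = np.asarray(curve.logit, dtype=float)
    w = np.asarray(curve.n, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 bins to fit a segmented model")
    if np.ptp(x) == 0:
        raise ValueError("all bin exposures equal; no breakpoint is identifiable")

    lo, hi = np.percentile(x, percentile_bounds)
    candidates = x[(x >= lo) & (x <= hi)]
    if candidates.size == 0:
        candidates = np.array([float(np.median(x))])

    sses = np.array([_broken_stick_sse(c, x, y, w)[0] for c in candidates])
    best_i = int(np.argmin(sses))  # argmin takes first minimum -> smaller c on ties
    best_c = float(candidates[best_i])
    best_sse, best_beta = _broken_stick_sse(best_c, x, y, w)

    # local refinement between the grid neighbours of the winner
    left = candidates[best_i - 1] if best_i > 0 else max(lo, best_c - np.ptp(x) / 50)
    right = (
        candidates[best_i + 1]
        if best_i < candidates.size - 1
        else min(hi, best_c + np.ptp(x) / 50)
    )
    iterations = candidates.size
    converged = True
    if right > left:
        res = minimize_scalar(
            lambda c: _broken_stick_sse(float(c), x, y, w)[0],
            bounds=(float(left), float(right)),
            method="bounded",
            options={"xatol": refine_xtol},
        )
        iterations += int(res.nfev)
        converged = bool(res.success)
        if res.fun <= best_sse:
            best_c = float(res.x)
            best_sse, best_beta = _broken_stick_sse(best_c, x, y, w)

    a, b1, delta = best_beta
    return SegmentedFit(
        cutpoint=best_c,
        intercept=float(a),
        slope_below=float(b1),
        slope_above=float(b1 + delta),
        sse=best_sse,
        converged=converged,
        iterations=iterations,
    )
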
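"""Exposure-encoding ("link function") design bases for logistic dose-response models.

Four families encode a pollutant concentration in the linear predictor of a
logistic regression:

* LINEAR      — one column, the concentration itself (proportional odds).
* THRESHOLD   — one hinge column ``max(0, x - c)``: flat baseline below the
  inflection point ``c``, linear above it.
* INTERACTION — three columns ``[x, 1{x >= c}, x * 1{x >= c}]``: separate
  slopes below/above ``c`` with a level shift at ``c``.
* RCS         — restricted cubic spline (Harrell form): piecewise cubic,
  continuous through the second derivative, constrained to be linear
  outside the boundary knots; ``k`` knots yield ``k - 1`` columns.

Boundary conventions at ``x == c`` are fixed so results are reproducible:
the hinge is 0 (baseline side) while the interaction indicator is 1
(upper side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "LinkKind",
    "LinkSpec",
    "linear_basis",
    "threshold_basis",
    "interaction_basis",
    "rcs_basis",
    "rcs_basis_derivative",
    "default_knots",
    "basis_matrix",
    "KNOT_QUANTILES",
]


class LinkKind(str, Enum):
    LINEAR = "linear"
    THRESHOLD = "threshold"
    INTERACTION = "interaction"
    RCS = "rcs"


@dataclass(frozen=True)
class LinkSpec:
    """A concrete exposure encoding for one pollutant.

    Parameters
    ----------
    pollutant : str
        Name of the pollutant column this spec applies to.
    kind : LinkKind
        Which of the four families to use.
    cutpoint : float, optional
        Inflection point in µg/m³; required for THRESHOLD and INTERACTION.
    knots : tuple of float, optional
        Strictly increasing knot locations in µg/m³; required for RCS,
        with 3 <= k <= 7.
    """

    pollutant: str
    kind: LinkKind
    cutpoint: float | None = None
    knots: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        kind = LinkKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in (LinkKind.THRESHOLD, LinkKind.INTERACTION):
            if self.cutpoint is None or not np.isfinite(self.cutpoint):
                raise ValueError(f"{kind.value} link requires a finite cutpoint")
            if self.knots is not None:
                raise ValueError(f"{kind.value} link does not take knots")
        elif kind is LinkKind.RCS:
            if self.knots is None:
                raise ValueError("rcs link requires knots")
            knots = tuple(float(t) for t in self.knots)
            if not 3 <= len(knots) <= 7:
                raise ValueError("rcs requires between 3 and 7 knots")
            if np.any(np.diff(knots) <= 0):
                raise ValueError("knots must be strictly increasing")
            object.__setattr__(self, "knots", knots)
            if self.cutpoint is not None:
                raise ValueError("rcs link does not take a cutpoint")
        else:  # LINEAR
            if self.cutpoint is not None or self.knots is not None:
                raise ValueError("linear link takes neither cutpoint nor knots")

    @property
    def n_columns(self) -> int:
        if self.kind in (LinkKind.LINEAR, LinkKind.THRESHOLD):
            return 1
        if self.kind is LinkKind.INTERACTION:
            return 3
        return len(self.knots) - 1

    def column_names(self) -> list[str]:
        p = self.pollutant
        if self.kind is LinkKind.LINEAR:
            return [p]
        if self.kind is LinkKind.THRESHOLD:
            return [f"{p}_hinge"]
        if self.kind is LinkKind.INTERACTION:
            return [p, f"{p}_above", f"{p}_x_above"]
        return [p] + [f"{p}_rcs{j}" for j in range(2, len(self.knots))]

    def to_json(self) -> str:
        d = {"pollutant": self.pollutant, "kind": self.kind.value}
        if self.cutpoint is not None:
            d["cutpoint"] = self.cutpoint
        if self.knots is not None:
            d["knots"] = list(self.knots)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "LinkSpec":
        d = json.loads(s)
        return cls(
            pollutant=d["pollutant"],
            kind=LinkKind(d["kind"]),
            cutpoint=d.get("cutpoint"),
            knots=tuple(d["knots"]) if "knots" in d else None,
        )


def linear_basis(x: np.ndarray) -> np.ndarray:
    """Identity encoding: a single column equal to the exposure."""
    x = np.asarray(x, dtype=float)
    return x.reshape(-1, 1)


def threshold_basis(x: np.ndarray, cutpoint: float) -> np.ndarray:
    """Hinge encoding ``max(0, x - c)``; zero at and below the cutpoint."""
    x = np.asarray(x, dtype=float)
    return np.maximum(0.0, x - cutpoint).reshape(-1, 1)


def interaction_basis(x: np.ndarray, cutpoint: float) -> np.ndarray:
    """Two-segment encoding ``[x, 1{x >= c}, x * 1{x >= c}]``.

    Spans separate slopes below and above ``c`` plus a discontinuity at
    ``c``; nests the hinge since ``max(0, x-c) = x*d - c*d`` for the dummy
    ``d = 1{x >= c}``.
    """
    x = np.asarray(x, dtype=float)
    above = (x >= cutpoint).astype(float)
    return np.column_stack([x, above, x * above])


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    With knots ``t_1 < ... < t_k`` the first column is ``x`` and column
    ``j+1`` (j = 1..k-2) is::

        [ (x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                     + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

    The division by ``(t_k - t_1)^2`` keeps the nonlinear columns on the
    scale of ``x`` for numerical conditioning.  The spanned functions are
    cubic between knots, C² everywhere and linear outside ``[t_1, t_k]``.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if not 3 <= k <= 7:
        raise ValueError("rcs requires between 3 and 7 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    tau = (t[-1] - t[0]) ** 2
    cols = [x]
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        a = np.maximum(0.0, x - t[j]) ** 3
        b = np.maximum(0.0, x - t[-2]) ** 3 * (t[-1] - t[j]) / denom
        c = np.maximum(0.0, x - t[-1]) ** 3 * (t[-2] - t[j]) / denom
        cols.append((a - b + c) / tau)
    return np.column_stack(cols)


def rcs_basis_derivative(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Analytic d/dx of every :func:`rcs_basis` column (same shape)."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    tau = (t[-1] - t[0]) ** 2
    denom = t[-1] - t[-2]
    cols = [np.ones_like(x)]
    for j in range(t.size - 2):
        a = 3.0 * np.maximum(0.0, x - t[j]) ** 2
        b = 3.0 * np.maximum(0.0, x - t[-2]) ** 2 * (t[-1] - t[j]) / denom
        c = 3.0 * np.maximum(0.0, x - t[-1]) ** 2 * (t[-2] - t[j]) / denom
        cols.append((a - b + c) / tau)
    return np.column_stack(cols)


#: Quantile placements for k = 3..7 knots (the standard recommendation).
KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def default_knots(x_sample: np.ndarray, k: int) -> tuple[float, ...]:
    """Place ``k`` knots at the standard quantiles of an exposure sample.

    Raises if the sample is degenerate (tied quantiles would collapse
    adjacent knots).
    """
    if k not in KNOT_QUANTILES:
        raise ValueError(f"k must be in {sorted(KNOT_QUANTILES)}, got {k}")
    x = np.asarray(x_sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} observations to place {k} knots")
    knots = tuple(float(q) for q in np.quantile(x, KNOT_QUANTILES[k]))
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate sample: knot quantiles coincide")
    return knots


def basis_matrix(x: np.ndarray, spec: LinkSpec) -> np.ndarray:
    """Evaluate the basis a :class:`LinkSpec` describes on exposures ``x``."""
    if spec.kind is LinkKind.LINEAR:
        return linear_basis(x)
    if spec.kind is LinkKind.THRESHOLD:
        return threshold_basis(x, spec.cutpoint)
    if spec.kind is LinkKind.INTERACTION:
        return interaction_basis(x, spec.cutpoint)
    return rcs_basis(x, spec.knots)
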
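"""Multi-response desirability optimization over the design box.

Each fitted response Y_k(x) is rescaled to an individual desirability

    d_k = clip((Y_k - L_k) / (H_k - L_k), 0, 1)        (maximize goal)

and the overall desirability is the weighted geometric mean

    D(x) = ( prod_k d_k^{w_k} )^{1 / sum_k w_k} .

By default the anchors (L_k, H_k) are the observed minimum and maximum of
each response over the design runs, so D measures how close a candidate
operating point comes to the best response level actually observed.

The optimizer maximizes D over the coded cube [-1, 1]^3 by deterministic
multi-start local search (L-BFGS-B from a fixed coarse grid of starting
points), followed by a stationarity check on a 0.01-step coded grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .design import DesignTable, FactorLevels
from .rsm import ResponseSurfaceRegressor

__all__ = ["DesirabilitySpec", "DesirabilityResult", "optimize_desirability"]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Anchors for one response's desirability transform (maximize goal).

    ``low`` maps to d = 0 and ``high`` to d = 1; predictions outside the
    anchor interval are clipped.
    """

    low: float
    high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError("anchor 'high' must exceed 'low'")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    def score(self, y: np.ndarray | float) -> np.ndarray | float:
        return np.clip((y - self.low) / (self.high - self.low), 0.0, 1.0)

    @classmethod
    def from_design(cls, design: DesignTable, response: str, weight: float = 1.0
                    ) -> "DesirabilitySpec":
        """Anchor at the observed min/max of a measured response column."""
        y = design.response(response)
        return cls(low=float(y.min()), high=float(y.max()), weight=weight)


@dataclass(frozen=True)
class DesirabilityResult:
    """Optimum returned by :func:`optimize_desirability`."""

    conditions_coded: np.ndarray
    conditions_actual: np.ndarray
    predicted: dict[str, float]
    individual: dict[str, float]
    overall: float


def _overall(d_values: Sequence[float], weights: Sequence[float]) -> float:
    d = np.asarray(d_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(d <= 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


def optimize_desirability(
    fits: Mapping[str, ResponseSurfaceRegressor],
    specs: Mapping[str, DesirabilitySpec],
    levels: FactorLevels,
    n_grid_starts: int = 9,
) -> DesirabilityResult:
    """Maximize overall desirability over the coded design cube.

    Parameters
    ----------
    fits : mapping response name -> fitted ResponseSurfaceRegressor
    specs : mapping response name -> DesirabilitySpec (same keys as fits)
    levels : FactorLevels
        Used to report the optimum in actual units.
    n_grid_starts : int
        Starting points per coded axis for the multi-start local search.

    Notes
    -----
    The search is fully deterministic: L-BFGS-B is launched from every
    node of a fixed ``n_grid_starts^3`` lattice and the best converged
    point is kept.  A final 0.01-step neighbor check guards against a
    start-dependent local optimum.
    """
    if not fits:
        raise ValueError("at least one fitted response is required")
    if set(fits) != set(specs):
        raise ValueError("fits and specs must share the same response names")
    names = sorted(fits)
    weights = [specs[k].weight for k in names]

    def neg_overall(x: np.ndarray) -> float:
        d = [float(specs[k].score(fits[k].predict_coded(x)[0])) for k in names]
        return -_overall(d, weights)

    best_x, best_val = None, np.inf
    grid = np.linspace(-1.0, 1.0, n_grid_starts)
    for a in grid:
        for b in grid:
            for c in grid:
                res = minimize(neg_overall, np.array([a, b, c]),
                               method="L-BFGS-B", bounds=[(-1.0, 1.0)] * 3)
                if res.fun < best_val:
                    best_val, best_x = res.fun, res.x

    # local 0.01-step polish: accept any improving coded-grid neighbor
    step = 0.01
    improved = True
    while improved:
        improved = False
        for delta in np.eye(3):
            for sign in (+1.0, -1.0):
                cand = np.clip(best_x + sign * step * delta, -1.0, 1.0)
                val = neg_overall(cand)
                if val < best_val - 1e-12:
                    best_x, best_val, improved = cand, val, True

    predicted = {k: float(fits[k].predict_coded(best_x)[0]) for k in names}
    individual = {k: float(specs[k].score(predicted[k])) for k in names}
    return DesirabilityResult(
        conditions_coded=best_x,
        conditions_actual=levels.decode(best_x),
        predicted=predicted,
        individual=individual,
        overall=-best_val,
    )
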
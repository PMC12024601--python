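"""Response-surface layer: Box-Behnken design generation, chart-scored
responses, linear least-squares fit with ANOVA and the R-squared triple
(plain / adjusted / PRESS-predicted), affine prediction, and single-response
desirability optimization over the factor box.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .errors import BoundsError, FitError
from .reba_core import Adjustments, RebaPoints, reba_total

__all__ = [
    "FactorSpec", "Design", "LinearModel", "OptimizationResult",
    "DEFAULT_FACTORS", "REFERENCE_MODEL",
    "bbd_design", "score_design", "fit_linear", "predict",
    "desirability", "optimize_desirability",
]

FACTOR_NAMES = ("neck", "trunk", "upper_arm", "lower_arm")


@dataclass(frozen=True)
class FactorSpec:
    """Four factors (neck, trunk, upper arm, lower arm) with natural low and
    high levels each."""

    low: tuple[float, float, float, float]
    high: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.low) != 4 or len(self.high) != 4:
            raise BoundsError("exactly four factors are supported")
        if any(l >= h for l, h in zip(self.low, self.high)):
            raise BoundsError("each factor needs low < high")

    def decode(self, coded: np.ndarray) -> np.ndarray:
        """Linear decoding: -1 -> low, 0 -> midpoint, +1 -> high."""
        lo = np.asarray(self.low, dtype=float)
        hi = np.asarray(self.high, dtype=float)
        return lo + (np.asarray(coded, dtype=float) + 1.0) / 2.0 * (hi - lo)


#: Default factor ranges: min/max of the seated subjects' observed points.
DEFAULT_FACTORS = FactorSpec(low=(2, 3, 3, 1), high=(3, 5, 6, 2))


@dataclass
class Design:
    coded: np.ndarray
    natural: np.ndarray
    responses: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.coded)


@dataclass
class LinearModel:
    intercept: float
    coefficients: dict
    residuals: np.ndarray
    r2: float
    adjusted_r2: float
    predicted_r2: float
    anova: dict  # per-term {"F": ..., "p": ...} plus "model"
    n_obs: int


@dataclass
class OptimizationResult:
    goal: str
    solutions: list  # ranked (levels tuple, predicted response, desirability)


def bbd_design(factors: FactorSpec = DEFAULT_FACTORS,
               center_replicates: int = 4) -> Design:
    """Four-factor Box-Behnken design: all six factor pairs at the four
    (+/-1, +/-1) edge combinations with the other factors at center
    (24 runs), plus center replicates."""
    if center_replicates < 0:
        raise BoundsError("center_replicates must be >= 0")
    rows = []
    for i, j in itertools.combinations(range(4), 2):
        for a, b in ((-1, -1), (1, -1), (-1, 1), (1, 1)):
            row = [0, 0, 0, 0]
            row[i], row[j] = a, b
            rows.append(row)
    rows.extend([[0, 0, 0, 0]] * center_replicates)
    coded = np.array(rows, dtype=float)
    return Design(coded=coded, natural=factors.decode(coded))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def score_design(design: Design, legs: int = 1, wrist: int = 2,
                 adj: Adjustments = Adjustments(),
                 level_rounding: str = "half_up") -> Design:
    """Attach chart-scored responses: each run's natural levels are rounded
    to integer grades (half-up), legs/wrist held fixed, and scored by the
    REBA chart."""
    if level_rounding not in ("half_up", "none"):
        raise BoundsError(f"unknown level rounding {level_rounding!r}")
    responses = []
    for row in design.natural:
        if level_rounding == "half_up":
            n, t, ua, la = (_round_half_up(v) for v in row)
        else:
            n, t, ua, la = (int(v) for v in row)
        pts = RebaPoints(neck=n, trunk=t, legs=legs, upper_arm=ua,
                         lower_arm=la, wrist=wrist)
        responses.append(reba_total(pts, adj).total)
    return Design(coded=design.coded.copy(), natural=design.natural.copy(),
                  responses=np.array(responses, dtype=float))


def fit_linear(design: Design) -> LinearModel:
    """Ordinary least squares of the responses on the natural levels.

    Reports adjusted R-squared (n - p - 1 denominator), PRESS-based
    predicted R-squared, and per-term F (= squared t) with p-values.
    """
    if design.responses is None:
        raise FitError("design carries no responses; score it first")
    y = np.asarray(design.responses, dtype=float)
    n = len(y)
    if n < 6:
        raise FitError("need at least 6 runs to fit four factors")
    X = np.column_stack([np.ones(n), design.natural])
    p = X.shape[1] - 1
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = n - p - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if sst > 0 else 1.0

    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    press = float((((resid) / (1.0 - h)) ** 2).sum())
    pred_r2 = 1.0 - press / sst if sst > 0 else 1.0

    sigma2 = sse / dof if dof > 0 else 0.0
    anova = {}
    for k, name in enumerate(FACTOR_NAMES, start=1):
        if sigma2 > 0:
            t_stat = beta[k] / math.sqrt(sigma2 * XtX_inv[k, k])
            F = t_stat ** 2
            p_val = float(stats.f.sf(F, 1, dof))
        else:
            F, p_val = float("inf"), 0.0
        anova[name] = {"F": float(F), "p": p_val}
    ssr = sst - sse
    if sigma2 > 0 and p > 0:
        F_model = (ssr / p) / sigma2
        p_model = float(stats.f.sf(F_model, p, dof))
    else:
        F_model, p_model = float("inf"), 0.0
    anova["model"] = {"F": float(F_model), "p": p_model}

    return LinearModel(
        intercept=float(beta[0]),
        coefficients=dict(zip(FACTOR_NAMES, map(float, beta[1:]))),
        residuals=resid, r2=float(r2), adjusted_r2=float(adj_r2),
        predicted_r2=float(pred_r2), anova=anova, n_obs=n)


#: The pinned reference model (see medreba.datasets.REFERENCE_MODEL_COEFFS).
def _reference_model() -> LinearModel:
    from .datasets import REFERENCE_MODEL_COEFFS as c
    return LinearModel(
        intercept=c["intercept"],
        coefficients={k: c[k] for k in FACTOR_NAMES},
        residuals=np.array([]), r2=float("nan"),
        adjusted_r2=float("nan"), predicted_r2=float("nan"),
        anova={}, n_obs=0)


REFERENCE_MODEL = _reference_model()


def predict(model: LinearModel, levels: Sequence[float],
            rounded: bool = False) -> float:
    """Affine evaluation of the model at four factor levels."""
    levels = tuple(float(v) for v in levels)
    if len(levels) != 4 or not all(math.isfinite(v) for v in levels):
        raise BoundsError("predict requires four finite levels")
    y = model.intercept + sum(model.coefficients[name] * v
                              for name, v in zip(FACTOR_NAMES, levels))
    return float(_round_half_up(y)) if rounded else float(y)


def desirability(y_hat: float, goal: str, low: float, high: float) -> float:
    """Derringer-Suich single-response desirability, clipped to [0, 1]."""
    if low >= high:
        raise BoundsError("desirability bounds require low < high")
    if goal == "maximize":
        d = (y_hat - low) / (high - low)
    elif goal == "minimize":
        d = (high - y_hat) / (high - low)
    else:
        raise BoundsError(f"unknown goal {goal!r}")
    return min(1.0, max(0.0, d))


def optimize_desirability(model: LinearModel,
                          factors: FactorSpec = DEFAULT_FACTORS,
                          goal: str = "minimize",
                          response_bounds: Optional[tuple] = None,
                          starts: int = 100, seed: int = 0,
                          design: Optional[Design] = None) -> OptimizationResult:
    """Multi-start bounded local search of the desirability over the factor
    box; returns unique solutions ranked by desirability (descending).

    ``response_bounds`` defaults to the (min, max) of the design responses
    when a scored design is supplied.
    """
    if goal not in ("minimize", "maximize"):
        raise BoundsError(f"unknown goal {goal!r}")
    if starts < 1:
        raise BoundsError("starts must be >= 1")
    if response_bounds is None:
        if design is None or design.responses is None:
            raise BoundsError(
                "response_bounds or a scored design must be supplied")
        response_bounds = (float(design.responses.min()),
                           float(design.responses.max()))
    low, high = response_bounds
    if low >= high:
        raise BoundsError("response bounds require low < high")

    box = list(zip(factors.low, factors.high))
    rng = np.random.default_rng(seed)

    # optimize the unclipped ramp (monotone in the prediction) so the search
    # does not stall on the clipped d = 0/1 plateaus; clip when reporting
    sign = 1.0 if goal == "maximize" else -1.0

    def neg_ramp(x):
        return -sign * (predict(model, x) - low) / (high - low)

    seen = {}
    x0s = [np.array(factors.low, dtype=float),
           np.array(factors.high, dtype=float)]
    x0s += [rng.uniform([b[0] for b in box], [b[1] for b in box])
            for _ in range(max(0, starts - len(x0s)))]
    for x0 in x0s[:starts]:
        res = minimize(neg_ramp, x0, method="L-BFGS-B", bounds=box)
        levels = tuple(round(float(v), 6) for v in res.x)
        ramp = -float(res.fun)
        if levels not in seen or ramp > seen[levels][0]:
            seen[levels] = (ramp, levels)
    ranked = sorted(seen.values(), key=lambda s: (-s[0], s[1]))
    solutions = [
        (levels, predict(model, levels),
         desirability(predict(model, levels), goal, low, high))
        for _, levels in ranked]
    return OptimizationResult(goal=goal, solutions=solutions)
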
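"""Sigmoidal melting-curve model, nonlinear fitting and the slope filter.

The soluble fraction of a denaturing protein is modeled with the
three-parameter sigmoid standard in thermal proteome profiling,

    f(T) = (1 - p) / (1 + exp(-(a/T - b))) + p

with scale ``a`` (degC units), offset ``b`` (dimensionless) and plateau
``p`` (non-denaturing residual fraction, 0 <= p < 1).  For a, b > 0 the
curve decreases strictly in T.  Temperatures are in degrees Celsius
throughout; a Kelvin convention would rescale the fitted a and b but not
the qualitative Tm/slope behavior, so the Celsius choice is fixed and
documented rather than configurable.

Closed forms used everywhere downstream:

* melting point  Tm = a / (b + ln(1 - 2 p)),  the root of f(T) = 1/2 on the
  normalized scale; undefined when p >= 1/2 (the curve never reaches
  half-maximum).
* inflection slope  df/dT at a/T - b = 0, i.e.  -(1 - p) b^2 / (4 a),
  the steepest descent of the curve.  Flat curves (|slope| < 0.06 by
  default) give irreproducible Tm estimates and are filtered out.

Fitting is bounded nonlinear least squares (scipy ``least_squares``, trf)
with a 5 x 5 x 3 multi-start grid over (a, b, p) seeded from a coarse Tm
guess; every start is scored, the best-ranked starts are refined, and the
smallest residual wins (ties broken by smallest a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import ValidationError
from .quant_io import MeltProfile, TemperatureGradient

__all__ = [
    "SigmoidParams",
    "MeltingCurveFit",
    "sigmoid",
    "compute_tm",
    "compute_slope",
    "fit_melting_curve",
    "passes_slope_filter",
    "SLOPE_THRESHOLD",
    "MIN_POINTS",
    "PARAM_BOUNDS",
]

#: Flat-curve exclusion threshold on the absolute inflection slope.
SLOPE_THRESHOLD = 0.06
#: Minimum finite points for a well-determined 3-parameter fit (of 10).
MIN_POINTS = 8
#: Box bounds for (a, b, p) during fitting.
PARAM_BOUNDS = ((100.0, 1.0, 0.0), (20000.0, 400.0, 0.49))


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters (a, b, p) of the melting sigmoid."""

    a: float
    b: float
    p: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError("sigmoid parameters require a > 0 and b > 0")
        if not (0.0 <= self.p < 1.0):
            raise ValidationError("plateau p must lie in [0, 1)")


def sigmoid(t, a: float, b: float, p: float):
    """Evaluate f(T) = (1-p)/(1+exp(-(a/T - b))) + p (vectorized in t)."""
    t = np.asarray(t, dtype=float)
    return (1.0 - p) * expit(a / t - b) + p


def compute_tm(params: SigmoidParams) -> Optional[float]:
    """Closed-form melting point: the T where f(T) = 1/2.

    Solving (1-p)/(1+exp(-(a/T-b))) + p = 1/2 gives
    ``Tm = a / (b + ln(1 - 2p))``.  Returns ``None`` when p >= 1/2 (the
    plateau sits above half-maximum) or when the denominator is not
    positive (the crossing would lie at a non-physical temperature).
    """
    if params.p >= 0.5:
        return None
    denom = params.b + math.log1p(-2.0 * params.p)
    if denom <= 0.0:
        return None
    return params.a / denom


def compute_slope(params: SigmoidParams) -> float:
    """df/dT at the inflection point a/T - b = 0: -(1-p) b^2 / (4a)."""
    return -(1.0 - params.p) * params.b * params.b / (4.0 * params.a)


@dataclass(frozen=True)
class MeltingCurveFit:
    """Fitted melting curve with diagnostics.

    ``tm`` and ``slope`` are ``None`` for non-converged or degenerate fits.
    ``r_squared`` is 1 - SS_res/SS_tot and can be arbitrarily negative.
    """

    params: Optional[SigmoidParams]
    tm: Optional[float]
    slope: Optional[float]
    r_squared: Optional[float]
    n_points: int
    converged: bool
    message: str = ""

    def predict(self, t):
        if self.params is None:
            raise ValidationError("cannot predict from an unfitted curve")
        return sigmoid(t, self.params.a, self.params.b, self.params.p)


def _unfittable(n_points: int, message: str) -> MeltingCurveFit:
    return MeltingCurveFit(None, None, None, None, n_points, False, message)


def _start_grid(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """5 x 5 x 3 start grid over (a, b, p) seeded from a coarse Tm guess."""
    below = np.nonzero(y < 0.5)[0]
    tm_guess = t[below[0]] if below.size else t[-1]
    a_grid = np.geomspace(200.0, 15000.0, 5)
    b_factors = np.array([0.90, 0.97, 1.0, 1.03, 1.10])
    p_grid = np.array([0.0, 0.15, 0.30])
    lo, hi = PARAM_BOUNDS
    starts = []
    for a in a_grid:
        b0 = np.clip(a / tm_guess, lo[1], hi[1])
        for f in b_factors:
            b = float(np.clip(b0 * f, lo[1], hi[1]))
            for p in p_grid:
                starts.append((a, b, p))
    return np.array(starts)


def _residuals(theta, t, y):
    a, b, p = theta
    return (1.0 - p) * expit(a / t - b) + p - y


def _jacobian(theta, t, y):
    a, b, p = theta
    s = expit(a / t - b)
    w = (1.0 - p) * s * (1.0 - s)
    return np.column_stack((w / t, -w, 1.0 - s))


def fit_melting_curve(
    profile: MeltProfile,
    gradient: TemperatureGradient,
    *,
    min_points: int = MIN_POINTS,
    n_refine: int = 3,
) -> MeltingCurveFit:
    """Fit the melting sigmoid to one normalized profile.

    Curves with fewer than ``min_points`` finite points, or with no
    discernible transition (essentially constant data), come back flagged
    unfittable (``converged=False``) rather than raising.  Non-finite
    (infinite) abundances raise :class:`ValidationError`.

    ``n_refine`` bounded least-squares refinements are run from the
    best-scoring entries of the multi-start grid; the refined fit with the
    smallest residual sum of squares wins, ties broken by smallest ``a``.
    """
    t_all = np.asarray(gradient.temperatures, dtype=float)
    if np.any(t_all <= 0):
        raise ValidationError("temperatures must be strictly positive (degC)")
    y_all = np.asarray(profile.rel_abundance, dtype=float)
    if y_all.shape != t_all.shape:
        raise ValidationError(
            f"{profile.protein_id}: profile length {y_all.size} does not match "
            f"gradient length {t_all.size}"
        )
    if np.any(np.isinf(y_all)):
        raise ValidationError(f"{profile.protein_id}: non-finite abundance")

    mask = np.isfinite(y_all)
    n = int(mask.sum())
    if n < min_points:
        return _unfittable(n, f"only {n} finite points (need {min_points})")
    t, y = t_all[mask], y_all[mask]
    if float(np.ptp(y)) < 1e-9:
        return _unfittable(n, "no melting transition (constant profile)")

    starts = _start_grid(t, y)
    # score every grid start, refine only the most promising ones
    a_s, b_s, p_s = starts[:, 0:1], starts[:, 1:2], starts[:, 2:3]
    pred = (1.0 - p_s) * expit(a_s / t[None, :] - b_s) + p_s
    sse0 = np.sum((pred - y[None, :]) ** 2, axis=1)
    order = np.argsort(sse0, kind="stable")[: max(1, n_refine)]

    lo, hi = PARAM_BOUNDS
    best = None  # (sse, a, theta, success)
    for i in order:
        x0 = np.clip(starts[i], lo, hi)
        try:
            res = least_squares(
                _residuals, x0, jac=_jacobian, args=(t, y),
                bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-10, max_nfev=400,
            )
        except Exception:  # pragma: no cover - scipy failure is unexpected
            continue
        sse = float(2.0 * res.cost)
        cand = (sse, float(res.x[0]), res.x, bool(res.success))
        if best is None:
            best = cand
        elif sse < best[0] * (1.0 - 1e-9):
            best = cand
        elif sse <= best[0] * (1.0 + 1e-9) and cand[1] < best[1]:
            best = cand  # tie: prefer smaller a

    if best is None:
        return _unfittable(n, "all optimizer starts failed")

    sse, _, theta, success = best
    params = SigmoidParams(float(theta[0]), float(theta[1]), float(theta[2]))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("-inf")
    if not success:
        return MeltingCurveFit(params, None, None, r2, n, False, "did not converge")
    return MeltingCurveFit(
        params=params,
        tm=compute_tm(params),
        slope=compute_slope(params),
        r_squared=r2,
        n_points=n,
        converged=True,
    )


def passes_slope_filter(fit: MeltingCurveFit, threshold: float = SLOPE_THRESHOLD) -> bool:
    """Flat-curve quality gate: keep curves with |inflection slope| >= threshold.

    The boundary value passes (curves *below* the threshold are excluded).
    Non-converged fits or fits without a defined slope fail the filter.
    """
    if threshold <= 0:
        return fit.converged and fit.slope is not None
    if not fit.converged or fit.slope is None:
        return False
    return abs(fit.slope) >= threshold
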
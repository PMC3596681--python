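"""Sum-of-squared-residuals objectives for fitting the deviation ODEs.

Two modes:

* single shooting -- integrate once from the first observation over the
  whole span and score residuals at every sample time;
* multiple shooting -- split the span at every observation time into
  k = n - 1 subintervals, restart each one from the *observed* (g, i) at
  its left endpoint, and sum the squared endpoint errors.

Because every subinterval restarts on the data, the multiple-shooting
objective stays finite even for parameter sets whose trajectory diverges
over the full span -- the practical failure mode of single shooting that
motivates the mode in the first place.

Both accept either a validated :class:`~gttfit.model.AckermanParams` or a
raw 4-vector: optimizers probe candidate vectors whose feasibility
(positivity) is their own concern, and the objective must be able to score
an unstable candidate rather than refuse it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .integrate import IntegratorConfig, integrate, sample_at
from .model import AckermanParams, GTTSeries

__all__ = ["ObjectiveConfig", "ResidualSet", "residuals_single", "ssr_multiple_shooting", "make_objective"]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Objective mode, optional per-observation weights and integrator.

    ``weights``, when given, has one non-negative entry per residual in the
    objective's ordering (all glucose residuals time-ascending, then all
    insulin residuals); default is unit weights.
    """

    mode: str = "single"
    weights: np.ndarray | None = None
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self):
        if self.mode not in ("single", "multiple"):
            raise ValidationError(f"unknown objective mode {self.mode!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValidationError("weights must be non-negative")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class ResidualSet:
    """Signed observation-minus-model residuals and their weighted SSR.

    Ordering: all glucose residuals time-ascending, then all insulin
    residuals time-ascending.
    """

    residuals: np.ndarray
    ssr: float


def _rhs_from(params):
    """Accept AckermanParams or a raw (p1, p2, p3, p4) vector."""
    if isinstance(params, AckermanParams):
        p1, p2, p3, p4 = params.p1, params.p2, params.p3, params.p4
    else:
        p1, p2, p3, p4 = (float(v) for v in params)

    def rhs(t, y):
        return (-p1 * y[0] - p2 * y[1], -p4 * y[1] + p3 * y[0])

    return rhs


def _weighted_ssr(residuals: np.ndarray, weights) -> float:
    if weights is None:
        return float(np.dot(residuals, residuals))
    w = np.asarray(weights, dtype=float)
    if w.shape != residuals.shape:
        raise ValidationError(
            f"weights shape {w.shape} does not match residual count {residuals.shape}"
        )
    return float(np.sum(w * residuals * residuals))


def residuals_single(params, data: GTTSeries, config: ObjectiveConfig) -> ResidualSet:
    """Single-shooting residuals: one integration over the full span.

    The first sample supplies the initial condition and therefore
    contributes an exactly zero residual (it is not an independent
    observation of the fitted trajectory).
    """
    if len(data) < 2:
        raise ValidationError("at least 2 samples required")
    rhs = _rhs_from(params)
    y0 = (data.g[0], data.i[0])
    traj = integrate(rhs, y0, data.times[0], data.times[-1], config.integrator)
    pred = sample_at(traj, data.times)
    r_g = data.g - pred[:, 0]
    r_i = data.i - pred[:, 1]
    r_g[0] = 0.0  # initial condition, not a residual
    r_i[0] = 0.0
    residuals = np.concatenate([r_g, r_i])
    return ResidualSet(residuals=residuals, ssr=_weighted_ssr(residuals, config.weights))


def ssr_multiple_shooting(params, data: GTTSeries, config: ObjectiveConfig) -> ResidualSet:
    """Multiple-shooting SSR: restart from the data at every observation.

    The span is partitioned at every sample time into k = n - 1
    subintervals.  Each is integrated from the *observed* (g, i) at its
    left endpoint; the residual is taken at its right endpoint, and the SSR
    sums over all subintervals.  With two samples this reduces exactly to
    single shooting (one subinterval, same initial condition).
    """
    if len(data) < 2:
        raise ValidationError("at least 2 samples required")
    rhs = _rhs_from(params)
    n = len(data)
    r_g = np.empty(n - 1)
    r_i = np.empty(n - 1)
    for k in range(n - 1):
        y0 = (data.g[k], data.i[k])
        traj = integrate(rhs, y0, data.times[k], data.times[k + 1], config.integrator)
        end = traj.states[-1]
        r_g[k] = data.g[k + 1] - end[0]
        r_i[k] = data.i[k + 1] - end[1]
    residuals = np.concatenate([r_g, r_i])
    return ResidualSet(residuals=residuals, ssr=_weighted_ssr(residuals, config.weights))


def make_objective(data: GTTSeries, config: ObjectiveConfig):
    """Return ``f(params) -> ssr`` in the configured mode (optimizer food)."""
    fn = residuals_single if config.mode == "single" else ssr_multiple_shooting

    def objective(params) -> float:
        return fn(params, data, config).ssr

    return objective
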
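"""Parameter estimation: perturbation search and a Gauss-Newton comparator.

The perturbation search is a derivative-free pattern search: at each
iteration every parameter is tried at three levels -- nudged down, left
alone, nudged up -- and all ``3**m`` combinations are scored; the best
improving candidate becomes the new centre.  When no candidate improves,
the perturbation size shrinks (range reduction) and the enumeration
repeats, until the SSR stops changing, the perturbation hits its floor, or
the iteration cap is reached.  The search needs no gradients, tolerates
non-smooth objectives, and its SSR trace is non-increasing by construction.

Gauss-Newton, the classical comparator, linearises the model residuals and
solves the normal equations each step.  It converges fast near the
optimum but fails outright -- singular normal matrix, divergence -- from
poor starts; those failures are raised as distinct errors rather than
returned as silently wrong answers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import Diverged, NumericalError, SingularNormalEquations, ValidationError
from .model import GTTSeries
from .objective import ObjectiveConfig, make_objective, residuals_single, ssr_multiple_shooting

__all__ = [
    "PerturbConfig",
    "FitResult",
    "perturbation_step",
    "perturbation_search",
    "finite_difference_gradient",
    "gauss_newton",
    "gauss_newton_core",
]

_TINY = 1e-300


@dataclass(frozen=True)
class PerturbConfig:
    """Tuning knobs of the perturbation search.

    delta_fraction
        Relative perturbation per parameter (Delta p_j = delta_fraction * |p_j|);
        starts coarse (0.1) and is refined by range reduction.
    reduction_factor
        Multiplicative shrink applied to delta_fraction when a full
        enumeration fails to improve.
    max_iterations
        Cap on enumeration sweeps.
    ssr_rel_tol
        Relative SSR change across one shrink cycle below which the search
        declares convergence.
    min_delta_fraction
        Floor on delta_fraction; reaching it stops the search.
    enforce_positive
        Score candidates with any non-positive coordinate as +inf (the
        model's rate constants are positive); disable for unconstrained
        objectives.
    abs_delta_floor
        Absolute floor on each Delta p_j so parameters at zero can still move.
    """

    delta_fraction: float = 0.1
    reduction_factor: float = 0.5
    max_iterations: int = 500
    ssr_rel_tol: float = 1e-8
    min_delta_fraction: float = 1e-6
    enforce_positive: bool = True
    abs_delta_floor: float = 1e-12

    def __post_init__(self):
        if not 0 < self.delta_fraction < 1:
            raise ValidationError("delta_fraction must lie in (0, 1)")
        if not 0 < self.reduction_factor < 1:
            raise ValidationError("reduction_factor must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class FitResult:
    """Outcome of an iterative fit.

    ``ssr_trace`` records the SSR after each iteration; ``ssr`` equals its
    last entry.  For the perturbation search the trace is non-increasing by
    construction (Gauss-Newton steps may transiently increase it).
    ``termination`` is ``converged``, ``max_iterations`` or ``delta_floor``.
    """

    params: np.ndarray
    ssr: float
    ssr_trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    termination: str = "converged"


def _safe_eval(objective, candidate) -> float:
    """Objective value, with failures scored +inf instead of raised."""
    try:
        val = float(objective(candidate))
    except NumericalError:
        return math.inf
    except (ValidationError, FloatingPointError, OverflowError, ZeroDivisionError):
        return math.inf
    return val if math.isfinite(val) else math.inf


def perturbation_step(params, deltas, objective, current_ssr: float,
                      enforce_positive: bool = True):
    """One full ``3**m`` enumeration around ``params``.

    Every coordinate takes each of {p_j - Delta_j, p_j, p_j + Delta_j}; all
    combinations are scored (exactly ``3**m`` objective evaluations) and the
    best candidate is returned if it improves on ``current_ssr``, else the
    input point is returned unchanged.  Ties break to the first candidate in
    lexicographic (-, 0, +) coordinate order.  Candidates with a
    non-positive coordinate are scored +inf without an objective call when
    ``enforce_positive`` is set; an objective that raises on a candidate
    scores it +inf rather than aborting the step.
    """
    p = np.asarray(params, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValidationError("params must be a non-empty 1-D vector")
    if d.shape != p.shape or np.any(d <= 0):
        raise ValidationError("deltas must be positive and match params")
    best_ssr = current_ssr
    best = None
    for signs in itertools.product((-1.0, 0.0, 1.0), repeat=p.size):
        cand = p + np.asarray(signs) * d
        if enforce_positive and np.any(cand <= 0):
            continue  # scored +inf, no objective call
        ssr = _safe_eval(objective, cand)
        if ssr < best_ssr:  # strict: ties keep the earlier candidate
            best_ssr, best = ssr, cand
    if best is None:
        return p, current_ssr
    return best, best_ssr


def perturbation_search(init, data: GTTSeries, obj_config: ObjectiveConfig,
                        config: PerturbConfig = PerturbConfig()) -> FitResult:
    """Fit the deviation-ODE parameters by perturbation search.

    Starts from ``init`` (strictly positive), with Delta p_j =
    delta_fraction * |p_j| recomputed after every accepted move.  A full
    non-improving enumeration triggers range reduction (delta_fraction *=
    reduction_factor).  Stops when the relative SSR change across a shrink
    cycle falls below ``ssr_rel_tol``, when delta_fraction drops below
    ``min_delta_fraction``, or at ``max_iterations``.
    """
    p = np.asarray(init, dtype=float)
    if np.any(p <= 0):
        raise ValidationError(f"initial parameters must be strictly positive, got {p}")
    objective = make_objective(data, obj_config)

    n_eval = 0

    def counted(cand):
        nonlocal n_eval
        n_eval += 1
        return objective(cand)

    ssr = _safe_eval(counted, p)
    trace = [ssr]
    frac = config.delta_fraction
    cycle_ssr = ssr  # SSR at the last range reduction
    termination = "max_iterations"
    for _ in range(config.max_iterations):
        if ssr <= _TINY:
            termination = "converged"
            break
        deltas = np.maximum(frac * np.abs(p), config.abs_delta_floor)
        new_p, new_ssr = perturbation_step(p, deltas, counted, ssr,
                                           enforce_positive=config.enforce_positive)
        if new_ssr < ssr:
            p, ssr = new_p, new_ssr
            trace.append(ssr)
            continue
        trace.append(ssr)
        # Full enumeration failed to improve: reduce the search range.
        # Converge only on a cycle with *some* but negligible relative
        # progress; a zero-progress cycle keeps shrinking, since a narrow
        # curved SSR valley can stall a coarse grid while finer perturbations
        # still descend (the delta floor bounds the extra cost).
        gain = cycle_ssr - ssr
        if 0 < gain <= config.ssr_rel_tol * max(cycle_ssr, _TINY):
            termination = "converged"
            break
        cycle_ssr = ssr
        frac *= config.reduction_factor
        if frac < config.min_delta_fraction:
            termination = "delta_floor"
            break
    return FitResult(params=p, ssr=ssr, ssr_trace=trace,
                     n_evaluations=n_eval, termination=termination)


def finite_difference_gradient(objective, params, deltas, scheme: str = "central"):
    """Per-coordinate difference-quotient gradient of a scalar objective.

    forward:  (f(p + D) - f(p)) / D
    backward: (f(p) - f(p - D)) / D
    central:  (f(p + D/2) - f(p - D/2)) / D   (second-order accurate)
    """
    p = np.asarray(params, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if d.shape != p.shape or np.any(d <= 0):
        raise ValidationError("deltas must be positive and match params")
    if scheme not in ("forward", "backward", "central"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    grad = np.empty_like(p)
    f0 = float(objective(p)) if scheme in ("forward", "backward") else None
    for j in range(p.size):
        e = np.zeros_like(p)
        e[j] = d[j]
        if scheme == "forward":
            grad[j] = (float(objective(p + e)) - f0) / d[j]
        elif scheme == "backward":
            grad[j] = (f0 - float(objective(p - e))) / d[j]
        else:
            grad[j] = (float(objective(p + e / 2)) - float(objective(p - e / 2))) / d[j]
    return grad


def gauss_newton_core(residual_fn, init, max_iter: int = 50, tol: float = 1e-10,
                      fd_rel_step: float = 1e-6) -> FitResult:
    """Gauss-Newton on a generic residual function ``r(p) -> vector``.

    Iterates ``p <- p + solve(J'J, J'r)`` with J the central finite-difference
    Jacobian of the *model predictions* (equivalently ``-dr/dp``).  Raises
    :class:`SingularNormalEquations` when J'J is numerically singular and
    :class:`Diverged` when the SSR grows five iterations in a row.
    """
    p = np.asarray(init, dtype=float)
    r = np.asarray(residual_fn(p), dtype=float)
    if r.size < p.size:
        raise ValidationError(
            f"need at least as many residuals ({r.size}) as parameters ({p.size})"
        )
    ssr = float(r @ r)
    trace = [ssr]
    n_eval = 1
    n_grow = 0
    termination = "max_iterations"
    for _ in range(max_iter):
        # central-difference Jacobian of residuals
        J = np.empty((r.size, p.size))
        for j in range(p.size):
            h = fd_rel_step * max(abs(p[j]), 1e-8)
            e = np.zeros_like(p)
            e[j] = h
            J[:, j] = (np.asarray(residual_fn(p + e)) - np.asarray(residual_fn(p - e))) / (2 * h)
            n_eval += 2
        # residuals are observation-minus-model, so J = -d(model)/dp and the
        # Gauss-Newton step p += (Jm'Jm)^-1 Jm' r becomes, with Jm = -J:
        JtJ = J.T @ J
        cond = np.linalg.cond(JtJ)
        if not np.isfinite(cond) or cond > 1e14:
            raise SingularNormalEquations(
                f"normal-equations singular (condition number {cond:.3g})"
            )
        step = np.linalg.solve(JtJ, -J.T @ r)
        p = p + step
        r = np.asarray(residual_fn(p), dtype=float)
        n_eval += 1
        new_ssr = float(r @ r)
        trace.append(new_ssr)
        if new_ssr > ssr:
            n_grow += 1
            if n_grow >= 5:
                raise Diverged("diverged: SSR grew for 5 consecutive iterations")
        else:
            n_grow = 0
        ssr = new_ssr
        if np.linalg.norm(step) < tol * (1.0 + np.linalg.norm(p)):
            termination = "converged"
            break
    return FitResult(params=p, ssr=ssr, ssr_trace=trace,
                     n_evaluations=n_eval, termination=termination)


def gauss_newton(init, data: GTTSeries, obj_config: ObjectiveConfig,
                 max_iter: int = 50, tol: float = 1e-10) -> FitResult:
    """Gauss-Newton fit of the deviation-ODE parameters.

    Thin wrapper around :func:`gauss_newton_core` with the residual vector
    of the configured objective mode.
    """
    res_fn = residuals_single if obj_config.mode == "single" else ssr_multiple_shooting

    def residual_fn(p):
        return res_fn(p, data, obj_config).residuals

    return gauss_newton_core(residual_fn, init, max_iter=max_iter, tol=tol)
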
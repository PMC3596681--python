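"""Fixed-step ODE integration for the small non-stiff systems in this package.

Euler (first-order), midpoint RK2 and classical RK4 on a uniform grid; the
final step is shortened so the trajectory lands exactly on the requested end
time.  The systems here (two states, rate constants of order 1e-2/min) are
far from stiff, so a fixed step of 0.1 min makes the discretisation error
negligible against measurement scales; adaptive control would buy nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrationBlowUp, ValidationError
from .model import Trajectory

__all__ = ["IntegratorConfig", "integrate", "sample_at"]

_METHODS = ("euler", "rk2", "rk4")


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration scheme and step size [min].

    When used inside a fitting objective the step should not exceed the
    smallest inter-sample gap (the grid must be able to resolve every
    observation time).
    """

    method: str = "rk4"
    step: float = 0.1

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValidationError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if not self.step > 0:
            raise ValidationError(f"step must be positive, got {self.step}")


def _grid(t0: float, t1: float, h: float) -> np.ndarray:
    n_full = int(np.floor((t1 - t0) / h + 1e-12))
    grid = t0 + h * np.arange(n_full + 1)
    if grid[-1] < t1 - 1e-12 * max(1.0, abs(t1)):
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1  # land exactly on t1, bit-for-bit
    return grid


def integrate(rhs, y0, t0: float, t1: float, config: IntegratorConfig) -> Trajectory:
    """Integrate ``y' = rhs(t, y)`` from t0 to t1 on a uniform grid.

    ``rhs`` returns a sequence of derivatives matching the shape of ``y0``.
    Raises :class:`IntegrationBlowUp` (with the offending time) if the state
    becomes non-finite.
    """
    if not t1 > t0:
        raise ValidationError(f"t1 must exceed t0, got [{t0}, {t1}]")
    y = np.asarray(y0, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError(f"initial state must be finite, got {y0}")
    times = _grid(t0, t1, config.step)
    states = np.empty((times.size, y.size))
    states[0] = y
    method = config.method
    # overflow en route to a detected blow-up is handled, not warned about
    with np.errstate(over="ignore", invalid="ignore"):
        _integrate_loop(rhs, y, times, states, method)
    return Trajectory(times=times, states=states)


def _integrate_loop(rhs, y, times, states, method):
    for k in range(times.size - 1):
        t, h = times[k], times[k + 1] - times[k]
        if method == "euler":
            y = y + h * np.asarray(rhs(t, y))
        elif method == "rk2":  # midpoint rule
            k1 = np.asarray(rhs(t, y))
            y = y + h * np.asarray(rhs(t + h / 2.0, y + (h / 2.0) * k1))
        else:  # classical rk4
            k1 = np.asarray(rhs(t, y))
            k2 = np.asarray(rhs(t + h / 2.0, y + (h / 2.0) * k1))
            k3 = np.asarray(rhs(t + h / 2.0, y + (h / 2.0) * k2))
            k4 = np.asarray(rhs(t + h, y + h * k3))
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationBlowUp(times[k + 1])
        states[k + 1] = y


def sample_at(traj: Trajectory, times) -> np.ndarray:
    """States at query times by linear interpolation; exact at grid points.

    Queries outside the trajectory span raise :class:`ValidationError`.
    """
    q = np.atleast_1d(np.asarray(times, dtype=float))
    lo, hi = traj.times[0], traj.times[-1]
    if np.any(q < lo) or np.any(q > hi):
        raise ValidationError(f"query times outside trajectory span [{lo}, {hi}]")
    # np.interp returns the exact endpoint values at grid points
    out = np.column_stack(
        [np.interp(q, traj.times, traj.states[:, j]) for j in range(traj.states.shape[1])]
    )
    return out
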
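"""Glucose-insulin regulatory dynamics during a glucose tolerance test (GTT).

The core model is Ackerman's pair of coupled linear ODEs for the deviations
of blood glucose ``g(t)`` and plasma insulin ``i(t)`` from their fasting
baselines::

    dg/dt = -p1*g - p2*i
    di/dt = -p4*i + p3*g

with four strictly positive rate constants.  ``p1`` and ``p4`` are
self-clearance rates, ``p2`` is insulin-driven glucose utilisation and
``p3`` is glucose-stimulated insulin secretion.  The glucose bolus that
starts the test is an impulse at t = 0 and is absorbed into the initial
condition ``g(0)``; the right-hand side carries no forcing term for t > 0.

Eliminating ``i`` turns the system into a damped harmonic oscillator

    g'' + 2*alpha*g' + omega0^2 * g = 0

with decay constant ``alpha = (p1 + p4)/2`` and natural frequency
``omega0^2 = p2*p3 + p1*p4``.  The undamped period ``T = 2*pi/omega0`` is
the diagnostic quantity: empirically, healthy subjects return to baseline
with T below four hours while diabetic subjects exceed it.

The module also carries the Bergman minimal model of glucose kinetics as a
simulation-only plugin (remote insulin-action compartment X(t)); it shares
the integrator interface but no fitting machinery is attached to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "AckermanParams",
    "GTTSeries",
    "DampingConstants",
    "MinimalModelParams",
    "Trajectory",
    "ackerman_rhs",
    "characteristic_constants",
    "closed_form_trajectory",
    "damped_solution",
    "minimal_model_rhs",
]

#: Relative tolerance inside which alpha^2 == omega0^2 counts as critical
#: damping.  Exact equality is measure-zero in floating point.
CRITICAL_REL_TOL = 1e-12


@dataclass(frozen=True)
class AckermanParams:
    """The four positive rate constants of the coupled deviation ODEs.

    Parameters
    ----------
    p1 : float
        Glucose self-clearance rate [1/min].
    p2 : float
        Insulin-driven glucose utilisation rate [(mg/dL)/(uU/mL)/min].
    p3 : float
        Glucose-driven insulin secretion rate [(uU/mL)/(mg/dL)/min].
    p4 : float
        Insulin clearance rate [1/min].
    """

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self):
        vals = (self.p1, self.p2, self.p3, self.p4)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"rate constants must be finite, got {vals}")
        if not all(v > 0 for v in vals):
            raise ValidationError(f"rate constants must be strictly positive, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "AckermanParams":
        p1, p2, p3, p4 = (float(v) for v in arr)
        return cls(p1, p2, p3, p4)


@dataclass
class GTTSeries:
    """Timestamped glucose/insulin deviations from fasting baselines.

    ``times`` are minutes from the glucose bolus, strictly increasing and
    starting at 0.  ``g`` and ``i`` are deviations (signed, may be negative)
    of glucose [mg/dL] and insulin [uU/mL] from the fasting values
    ``g_baseline``/``i_baseline`` (optional, absolute units).
    """

    times: np.ndarray
    g: np.ndarray
    i: np.ndarray
    g_baseline: float | None = None
    i_baseline: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if not (self.times.shape == self.g.shape == self.i.shape) or self.times.ndim != 1:
            raise ValidationError(
                "times, g and i must be 1-D arrays of equal length, got shapes "
                f"{self.times.shape}, {self.g.shape}, {self.i.shape}"
            )
        if self.times.size and self.times[0] != 0.0:
            raise ValidationError(f"first sample time must be 0, got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(self.g)) and np.all(np.isfinite(self.i))):
            raise ValidationError("deviations must be finite")

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "GTTSeries":
        return GTTSeries(
            self.times.copy(), self.g.copy(), self.i.copy(),
            self.g_baseline, self.i_baseline,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "glucose_dev": self.g, "insulin_dev": self.i}
        )


@dataclass(frozen=True)
class DampingConstants:
    """Damped-oscillator summary of an Ackerman parameter set.

    ``alpha`` [1/min] is the exponential decay constant (p1+p4)/2,
    ``omega0_sq`` [1/min^2] the squared natural frequency p2*p3 + p1*p4,
    ``omega`` the damped angular frequency sqrt(omega0_sq - alpha^2)
    (defined only in the under-damped regime, else None), and
    ``period_min`` the undamped period T = 2*pi/sqrt(omega0_sq) in minutes.
    """

    alpha: float
    alpha_sq: float
    omega0_sq: float
    omega: float | None
    period_min: float
    damping_class: str  # "under" | "critical" | "over"


@dataclass(frozen=True)
class MinimalModelParams:
    """Bergman minimal-model parameters (simulation only).

    ``p1_sg`` is glucose effectiveness S_G [1/min], ``p2`` the decay rate of
    remote insulin action [1/min], ``p3`` the insulin-dependent uptake gain
    [1/min^2 per (uU/mL)], ``g0`` the theoretical glycemia at time 0 [mg/dL],
    ``g_basal``/``i_basal`` the basal glucose [mg/dL] and insulin [uU/mL].
    """

    p1_sg: float
    p2: float
    p3: float
    g0: float
    g_basal: float
    i_basal: float

    def __post_init__(self):
        if min(self.p1_sg, self.p2, self.p3) < 0:
            raise ValidationError("minimal-model rates must be non-negative")
        if self.g0 <= 0:
            raise ValidationError("g0 must be positive")


@dataclass
class Trajectory:
    """A dense solution: ``times`` (strictly increasing grid, minutes) and
    ``states`` with one row per grid point (columns are state variables,
    e.g. (g, i) or (G, X))."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValidationError("one state vector per grid point required")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory grid must be strictly increasing")


def ackerman_rhs(state, params: AckermanParams):
    """Time derivatives (dg/dt, di/dt) of the deviation system.

    ``state`` is the pair (g, i) of deviations.  The glucose impulse is
    absorbed into the initial condition, so there is no forcing term.
    """
    g, i = float(state[0]), float(state[1])
    if not (math.isfinite(g) and math.isfinite(i)):
        raise ValidationError(f"non-finite state ({g}, {i})")
    return (-params.p1 * g - params.p2 * i, -params.p4 * i + params.p3 * g)


def characteristic_constants(params: AckermanParams) -> DampingConstants:
    """Damping constants and period of the equivalent second-order oscillator.

    The period uses the *undamped* natural frequency, T = 2*pi/omega0 --
    this is the diagnostic convention, not the damped frequency.
    """
    alpha = (params.p1 + params.p4) / 2.0
    alpha_sq = alpha * alpha
    omega0_sq = params.p2 * params.p3 + params.p1 * params.p4
    diff = alpha_sq - omega0_sq
    if abs(diff) <= CRITICAL_REL_TOL * max(alpha_sq, omega0_sq):
        damping_class = "critical"
    elif diff < 0:
        damping_class = "under"
    else:
        damping_class = "over"
    omega = math.sqrt(omega0_sq - alpha_sq) if damping_class == "under" else None
    period_min = 2.0 * math.pi / math.sqrt(omega0_sq)
    return DampingConstants(
        alpha=alpha,
        alpha_sq=alpha_sq,
        omega0_sq=omega0_sq,
        omega=omega,
        period_min=period_min,
        damping_class=damping_class,
    )


def closed_form_trajectory(
    params: AckermanParams, g0: float, i0: float, times
) -> Trajectory:
    """Exact under-damped solution of the linear system at the given times.

    Both deviations satisfy the same second-order oscillator, so each is
    ``exp(-alpha*t) * (c1*cos(omega*t) + c2*sin(omega*t))`` with c1 the
    initial value and c2 = (y'(0) + alpha*y(0)) / omega, where the initial
    slopes come from the first-order system.  Serves as the analytic oracle
    for the numerical integrators.

    Raises
    ------
    ValidationError
        If the parameter set is not under-damped (names the actual class).
    """
    consts = characteristic_constants(params)
    if consts.damping_class != "under":
        raise ValidationError(
            "closed-form trajectory requires an under-damped parameter set; "
            f"this one is {consts.damping_class}-damped"
        )
    t = np.asarray(times, dtype=float)
    alpha, omega = consts.alpha, consts.omega
    dg0 = -params.p1 * g0 - params.p2 * i0
    di0 = -params.p4 * i0 + params.p3 * g0
    envelope = np.exp(-alpha * t)
    cos_t, sin_t = np.cos(omega * t), np.sin(omega * t)
    g = envelope * (g0 * cos_t + ((dg0 + alpha * g0) / omega) * sin_t)
    i = envelope * (i0 * cos_t + ((di0 + alpha * i0) / omega) * sin_t)
    return Trajectory(times=t, states=np.column_stack([g, i]))


def damped_solution(kind: str, c1: float, c2: float, alpha: float, omega: float, t):
    """Scalar damped-oscillator solution families.

    under:    exp(-alpha*t) * (c1*cos(omega*t) + c2*sin(omega*t))
    critical: (c1 + c2*t) * exp(-alpha*t)
    over:     c1*exp(-(alpha-omega)*t) + c2*exp(-(alpha+omega)*t)

    Vectorised over ``t``.
    """
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    t = np.asarray(t, dtype=float)
    if kind == "under":
        if omega <= 0:
            raise ValidationError("under-damped solution requires omega > 0")
        return np.exp(-alpha * t) * (c1 * np.cos(omega * t) + c2 * np.sin(omega * t))
    if kind == "critical":
        return (c1 + c2 * t) * np.exp(-alpha * t)
    if kind == "over":
        if omega <= 0:
            raise ValidationError("over-damped solution requires omega > 0")
        return c1 * np.exp(-(alpha - omega) * t) + c2 * np.exp(-(alpha + omega) * t)
    raise ValidationError(f"unknown damping kind {kind!r}; expected under/critical/over")


def minimal_model_rhs(state, params: MinimalModelParams, insulin_at_t: float):
    """Bergman minimal-model derivatives (dG/dt, dX/dt).

    dG/dt = -(p1_sg + X) * G + p1_sg * G_b
    dX/dt = -p2 * X + p3 * (I(t) - I_b)

    ``state`` is (G, X) with G absolute glucose [mg/dL] and X the remote
    insulin action [1/min]; ``insulin_at_t`` is plasma insulin [uU/mL].
    """
    G, X = float(state[0]), float(state[1])
    if G < 0:
        raise ValidationError(f"glucose concentration must be non-negative, got {G}")
    if insulin_at_t < 0:
        raise ValidationError("insulin input must be non-negative")
    dG = -(params.p1_sg + X) * G + params.p1_sg * params.g_basal
    dX = -params.p2 * X + params.p3 * (insulin_at_t - params.i_basal)
    return (dG, dX)
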
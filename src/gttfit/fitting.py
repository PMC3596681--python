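"""Model/Results interface for fitting the glucose-insulin deviation ODEs.

Follows the fitting idiom of the statistical-modelling ecosystem: a model
object is built from data, ``fit()`` returns a results object carrying the
estimates and diagnostics, and simulation/plotting hang off those objects::

    >>> from gttfit import AckermanModel, table1_fixture
    >>> case1, _ = table1_fixture()
    >>> res = AckermanModel(case1).fit(start_params=[0.01, 0.01, 0.01, 0.01])
    >>> res.diagnosis().call
    'normal'
    >>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .integrate import IntegratorConfig
from .model import (
    AckermanParams,
    GTTSeries,
    Trajectory,
    characteristic_constants,
    closed_form_trajectory,
)
from .objective import ObjectiveConfig, make_objective, residuals_single
from .optimize import FitResult, PerturbConfig, gauss_newton, perturbation_search
from .diagnostics import DEFAULT_THRESHOLD_MIN, DiagnosisReport, classify_subject

__all__ = ["AckermanModel", "AckermanResults"]

#: Order-of-magnitude default start for the four rate constants [1/min and
#: cross-rates]; published GTT fits put them around 1e-2 to 1e-3.
DEFAULT_START = (0.01, 0.01, 0.01, 0.01)

REPORT_SCHEMA_VERSION = 1


class AckermanModel:
    """The coupled glucose-insulin deviation ODEs, bound to one GTT series.

    Parameters
    ----------
    data : GTTSeries
        Deviations from fasting baselines; the first sample (at t = 0)
        supplies the initial condition for simulation and fitting.
    """

    def __init__(self, data: GTTSeries):
        if len(data) < 2:
            raise ValidationError("a GTT series needs at least 2 samples to fit")
        self.data = data

    @classmethod
    def from_dataframe(cls, df, time_unit: str = "min") -> "AckermanModel":
        """Build from a DataFrame with columns time, glucose_dev, insulin_dev."""
        missing = [c for c in ("time", "glucose_dev", "insulin_dev") if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s) {missing}")
        times = np.asarray(df["time"], dtype=float)
        if time_unit == "h":
            times = times * 60.0
        elif time_unit != "min":
            raise ValidationError(f"time_unit must be 'min' or 'h', got {time_unit!r}")
        return cls(GTTSeries(times=times,
                             g=np.asarray(df["glucose_dev"], dtype=float),
                             i=np.asarray(df["insulin_dev"], dtype=float)))

    @classmethod
    def from_csv(cls, path, time_unit: str | None = None) -> "AckermanModel":
        from .data_io import read_gtt_csv

        return cls(read_gtt_csv(path, time_unit=time_unit))

    def simulate(self, params: AckermanParams, times=None) -> Trajectory:
        """Trajectory from the data's initial condition.

        Uses the exact closed form in the under-damped regime and falls back
        to RK4 integration otherwise.
        """
        if times is None:
            times = np.linspace(self.data.times[0], self.data.times[-1], 200)
        times = np.asarray(times, dtype=float)
        if characteristic_constants(params).damping_class == "under":
            return closed_form_trajectory(params, self.data.g[0], self.data.i[0], times)
        from .integrate import integrate, sample_at
        from .objective import _rhs_from

        traj = integrate(_rhs_from(params), (self.data.g[0], self.data.i[0]),
                         times[0], times[-1], IntegratorConfig())
        return Trajectory(times=times, states=sample_at(traj, times))

    def fit(self, start_params=None, method: str = "perturb",
            objective_mode: str = "single",
            integrator: IntegratorConfig | None = None,
            weights=None,
            perturb_config: PerturbConfig | None = None,
            gn_max_iter: int = 50, gn_tol: float = 1e-10) -> "AckermanResults":
        """Estimate the four rate constants by minimising the SSR.

        ``method`` is ``'perturb'`` (derivative-free perturbation search,
        the default and the robust choice) or ``'gauss-newton'`` (fast near
        the optimum, may fail from poor starts).  ``objective_mode`` selects
        single or multiple shooting.
        """
        start = np.asarray(start_params if start_params is not None else DEFAULT_START,
                           dtype=float)
        if isinstance(start_params, AckermanParams):
            start = start_params.as_array()
        obj_config = ObjectiveConfig(
            mode=objective_mode,
            weights=weights,
            integrator=integrator if integrator is not None else IntegratorConfig(),
        )
        if method == "perturb":
            raw = perturbation_search(start, self.data, obj_config,
                                      perturb_config or PerturbConfig())
        elif method == "gauss-newton":
            raw = gauss_newton(start, self.data, obj_config,
                               max_iter=gn_max_iter, tol=gn_tol)
        else:
            raise ValidationError(f"unknown method {method!r}")
        return AckermanResults(self, raw, obj_config, method)


class AckermanResults:
    """Fitted rate constants plus oscillator diagnostics for one GTT series.

    Attributes
    ----------
    params : AckermanParams
        The estimated rate constants.
    ssr : float
        Final sum of squared residuals.
    ssr_trace : list of float
        Objective value per iteration.
    """

    def __init__(self, model: AckermanModel, raw: FitResult,
                 obj_config: ObjectiveConfig, method: str):
        self.model = model
        self.raw = raw
        self.obj_config = obj_config
        self.method = method
        self.params = AckermanParams.from_array(raw.params)
        self.ssr = raw.ssr
        self.ssr_trace = list(raw.ssr_trace)
        self.n_evaluations = raw.n_evaluations
        self.termination = raw.termination

    @property
    def damping(self):
        return characteristic_constants(self.params)

    @property
    def period_min(self) -> float:
        return self.damping.period_min

    def diagnosis(self, threshold_min: float = DEFAULT_THRESHOLD_MIN) -> DiagnosisReport:
        return classify_subject(self.params, threshold_min=threshold_min)

    def residuals(self):
        return residuals_single(self.params, self.model.data, self.obj_config)

    def predict(self, times=None):
        """Fitted deviations as a DataFrame (default: a dense grid over the span)."""
        traj = self.model.simulate(self.params, times)
        import pandas as pd

        return pd.DataFrame({"time_min": traj.times,
                             "glucose_dev": traj.states[:, 0],
                             "insulin_dev": traj.states[:, 1]})

    def to_dict(self) -> dict:
        """JSON-ready report (schema_version 1)."""
        d = self.damping
        diag = self.diagnosis()
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "method": self.method,
            "objective_mode": self.obj_config.mode,
            "params": {"p1": self.params.p1, "p2": self.params.p2,
                       "p3": self.params.p3, "p4": self.params.p4},
            "ssr": self.ssr,
            "ssr_trace": self.ssr_trace,
            "n_evaluations": self.n_evaluations,
            "termination": self.termination,
            "damping": {"alpha": d.alpha, "alpha_sq": d.alpha_sq,
                        "omega0_sq": d.omega0_sq, "omega": d.omega,
                        "period_min": d.period_min, "damping_class": d.damping_class},
            "diagnosis": {"call": diag.call, "period_min": diag.period_min,
                          "threshold_min": diag.threshold_min},
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        d = self.damping
        diag = self.diagnosis()
        lines = [
            "Glucose-insulin deviation ODE fit",
            "=" * 49,
            f"Method:            {self.method} ({self.obj_config.mode} shooting)",
            f"Observations:      {len(self.model.data)} sample times (g and i)",
            f"SSR:               {self.ssr:.6g}",
            f"Iterations:        {len(self.ssr_trace) - 1}"
            f"   objective evaluations: {self.n_evaluations}",
            f"Termination:       {self.termination}",
            "-" * 49,
            f"p1 (glucose clearance)   {self.params.p1:.6g}  1/min",
            f"p2 (insulin action)      {self.params.p2:.6g}  (mg/dL)/(uU/mL)/min",
            f"p3 (insulin secretion)   {self.params.p3:.6g}  (uU/mL)/(mg/dL)/min",
            f"p4 (insulin clearance)   {self.params.p4:.6g}  1/min",
            "-" * 49,
            f"alpha^2:           {d.alpha_sq:.6g}  1/min^2",
            f"omega0^2:          {d.omega0_sq:.6g}  1/min^2",
            f"damping:           {d.damping_class}",
            f"period T:          {d.period_min:.2f} min",
            f"diagnosis:         {diag.call} (T {'<' if diag.call == 'normal' else '>='} "
            f"{diag.threshold_min:.0f} min)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curves (matplotlib; returns the axes)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict()
        data = self.model.data
        ax.plot(pred["time_min"], pred["glucose_dev"], "b-", label="glucose (fit)")
        ax.plot(pred["time_min"], pred["insulin_dev"], "g-", label="insulin (fit)")
        ax.plot(data.times, data.g, "bo", label="glucose (obs)")
        ax.plot(data.times, data.i, "g^", label="insulin (obs)")
        ax.set_xlabel("time [min]")
        ax.set_ylabel("deviation from baseline")
        ax.legend()
        return ax
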
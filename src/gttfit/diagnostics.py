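"""Diabetes diagnostics from GTT dynamics and clinical glycemic indices.

The oscillation-based call: the fitted deviation ODEs define an undamped
period T = 2*pi/omega0 with omega0^2 = p2*p3 + p1*p4.  Subjects whose
period is below four hours clear a glucose challenge like healthy
individuals; a period above four hours marks impaired tolerance.  The
threshold is strict -- T exactly at the bound counts as diabetic, matching
the "T < 4 h" form of the criterion.

Fasting-value indices:

* HOMA-IR  = FPG[mg/dL] * FPI / 405   (= FPG[mmol/L] * FPI / 22.5)
* HOMA-IS  = 1 / HOMA-IR
* HOMA-beta = 20 * FPI / (FPG[mmol/L] - 3.5)   [percent]
* QUICKI   = 1 / (log10 FPG[mg/dL] + log10 FPI)

Variability scores over monitoring series:

* LI (lability index): squared glucose change [mmol/L] between consecutive
  readings divided by the time gap [h], summed over a week; only gaps
  between 1 h and 12 h count.
* MAGE: mean amplitude of the day's glycemic excursions exceeding one
  sample standard deviation of that day's readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import AckermanParams, DampingConstants, characteristic_constants

__all__ = [
    "DiagnosisReport",
    "IndexInputs",
    "GlycemicSeries",
    "MGDL_PER_MMOL",
    "oscillation_period",
    "classify_damping",
    "classify_subject",
    "homa_ir",
    "homa_is",
    "homa_beta",
    "quicki",
    "lability_index",
    "lability_index_by_period",
    "mage",
]

#: mg/dL per mmol/L of glucose; ties the HOMA constants together (405 = 22.5 * 18).
MGDL_PER_MMOL = 18.0

#: Diagnostic period threshold: 4 hours in minutes.
DEFAULT_THRESHOLD_MIN = 240.0

_UNITS = ("mg/dL", "mmol/L")


@dataclass(frozen=True)
class DiagnosisReport:
    """Oscillation-based GTT diagnosis for one fitted parameter set."""

    constants: DampingConstants
    period_min: float
    call: str  # "normal" | "diabetic"
    threshold_min: float = DEFAULT_THRESHOLD_MIN


@dataclass(frozen=True)
class IndexInputs:
    """Fasting plasma glucose (``fpg``, unit tagged) and insulin (``fpi``, uU/mL)."""

    fpg: float
    fpi: float
    unit: str  # "mg/dL" | "mmol/L"

    def __post_init__(self):
        if self.unit not in _UNITS:
            raise ValidationError(f"glucose unit must be one of {_UNITS}, got {self.unit!r}")
        if not (self.fpg > 0 and self.fpi >= 0):
            raise ValidationError("fasting glucose must be positive and insulin non-negative")

    @property
    def fpg_mgdl(self) -> float:
        return self.fpg if self.unit == "mg/dL" else self.fpg * MGDL_PER_MMOL

    @property
    def fpg_mmol(self) -> float:
        return self.fpg / MGDL_PER_MMOL if self.unit == "mg/dL" else self.fpg


@dataclass
class GlycemicSeries:
    """Timestamped absolute glucose readings for variability scoring.

    ``times`` are hours from the start of the series (non-decreasing),
    ``glucose`` the readings in the tagged ``unit``; ``period_label`` is an
    optional per-reading grouping key (week or day).
    """

    times: np.ndarray
    glucose: np.ndarray
    unit: str = "mg/dL"
    period_label: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.unit not in _UNITS:
            raise ValidationError(f"glucose unit must be one of {_UNITS}, got {self.unit!r}")
        if self.times.shape != self.glucose.shape or self.times.ndim != 1:
            raise ValidationError("times and glucose must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("reading times must be non-decreasing")
        if np.any(self.glucose <= 0):
            raise ValidationError("glucose readings must be positive")
        if self.period_label is not None:
            self.period_label = np.asarray(self.period_label)
            if self.period_label.shape != self.times.shape:
                raise ValidationError("period_label must match the reading count")

    def glucose_mmol(self) -> np.ndarray:
        return self.glucose / MGDL_PER_MMOL if self.unit == "mg/dL" else self.glucose


def oscillation_period(params: AckermanParams) -> float:
    """Undamped oscillation period T = 2*pi/sqrt(p2*p3 + p1*p4) [min]."""
    return characteristic_constants(params).period_min


def classify_damping(constants: DampingConstants) -> str:
    """Damping regime: 'under' (oscillatory), 'critical' or 'over'."""
    return constants.damping_class


def classify_subject(params: AckermanParams,
                     threshold_min: float = DEFAULT_THRESHOLD_MIN) -> DiagnosisReport:
    """Normal/diabetic call from the oscillation period (strict T < threshold)."""
    constants = characteristic_constants(params)
    call = "normal" if constants.period_min < threshold_min else "diabetic"
    return DiagnosisReport(constants=constants, period_min=constants.period_min,
                           call=call, threshold_min=threshold_min)


def homa_ir(inputs: IndexInputs) -> float:
    """HOMA insulin-resistance index: FPG*FPI/405 (mg/dL) or /22.5 (mmol/L)."""
    if inputs.unit == "mg/dL":
        return inputs.fpg * inputs.fpi / 405.0
    return inputs.fpg * inputs.fpi / 22.5


def homa_is(inputs: IndexInputs) -> float:
    """HOMA insulin sensitivity: the reciprocal of HOMA-IR."""
    ir = homa_ir(inputs)
    if ir == 0:
        raise ValidationError("HOMA-IS undefined: HOMA-IR is zero (zero insulin)")
    return 1.0 / ir


def homa_beta(inputs: IndexInputs) -> float:
    """HOMA beta-cell function [percent]: 20*FPI/(FPG[mmol/L] - 3.5)."""
    fpg = inputs.fpg_mmol
    if fpg <= 3.5:
        raise ValidationError(
            f"denominator non-positive: HOMA-beta requires FPG > 3.5 mmol/L, got {fpg:g}"
        )
    return 20.0 * inputs.fpi / (fpg - 3.5)


def quicki(inputs: IndexInputs) -> float:
    """QUICKI: 1/(log10 FPG[mg/dL] + log10 FPI[uU/mL])."""
    if inputs.fpi <= 0:
        raise ValidationError("QUICKI requires positive fasting insulin")
    denom = math.log10(inputs.fpg_mgdl) + math.log10(inputs.fpi)
    if denom == 0:
        raise ValidationError("QUICKI undefined: log10(FPG) + log10(FPI) is zero")
    return 1.0 / denom


def lability_index(series: GlycemicSeries,
                   min_gap_h: float = 1.0, max_gap_h: float = 12.0) -> float:
    """Weekly lability index [(mmol/L)^2 / (h*week)].

    Sum over consecutive reading pairs of (delta glucose [mmol/L])^2 divided
    by the time gap [h]; only pairs whose gap lies in [min_gap_h, max_gap_h]
    contribute.  Pairs are strictly consecutive -- an excluded pair is
    dropped, not bridged.
    """
    if len(series.times) < 2:
        raise ValidationError("lability index requires at least 2 readings")
    gluc = series.glucose_mmol()
    dg = np.diff(gluc)
    dt = np.diff(series.times)
    mask = (dt >= min_gap_h) & (dt <= max_gap_h)
    return float(np.sum(dg[mask] ** 2 / dt[mask])) if np.any(mask) else 0.0


def lability_index_by_period(series: GlycemicSeries) -> dict:
    """Lability index per ``period_label`` group (no cross-period pairs)."""
    if series.period_label is None:
        raise ValidationError("series has no period_label to group by")
    out = {}
    for label in dict.fromkeys(series.period_label.tolist()):  # preserve order
        sel = series.period_label == label
        sub = GlycemicSeries(series.times[sel] - series.times[sel][0],
                             series.glucose[sel], series.unit)
        out[label] = lability_index(sub)
    return out


def _turning_points(values: np.ndarray) -> np.ndarray:
    """Indices of local extrema after collapsing plateaus, endpoints included."""
    # collapse runs of equal values to their first point
    keep = np.concatenate([[True], values[1:] != values[:-1]])
    idx = np.flatnonzero(keep)
    v = values[idx]
    if v.size <= 2:
        return idx
    interior = np.sign(np.diff(v[:-1])) != np.sign(np.diff(v[1:]))
    mask = np.concatenate([[True], interior, [True]])
    return idx[mask]


def mage(series: GlycemicSeries, min_readings: int = 7):
    """Mean amplitude of glycemic excursions over one day of readings.

    An excursion is the |peak - nadir| swing between consecutive turning
    points of the series; only excursions exceeding one sample standard
    deviation (ddof=1) of the day's readings qualify, and only those in the
    direction (rise or fall) of the first qualifying excursion are averaged.
    Returns the mean qualifying amplitude in the series' own unit, or
    ``None`` when no excursion qualifies (a distinct outcome, not zero).
    """
    values = series.glucose
    if values.size < min_readings:
        raise ValidationError(
            f"MAGE requires at least {min_readings} readings, got {values.size}"
        )
    sd = float(np.std(values, ddof=1))
    tp = _turning_points(values)
    if tp.size < 2 or sd == 0.0:
        return None
    swings = np.diff(values[tp])  # signed peak/nadir differences
    qualifying = np.abs(swings) > sd
    if not np.any(qualifying):
        return None
    direction = np.sign(swings[np.argmax(qualifying)])  # first qualifying excursion
    amps = np.abs(swings[qualifying & (np.sign(swings) == direction)])
    return float(np.mean(amps))
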
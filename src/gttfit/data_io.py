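"""Reading, writing and generating GTT and glycemic-monitoring series.

Ships the published two-subject GTT measurement set (four hourly samples of
glucose and insulin deviations per subject, one clinically normal and one
diabetic) as an in-memory fixture, together with the parameter sets fitted
to it; provides CSV round-trips for GTT and glycemic series; and houses the
seeded synthetic-data generator used throughout the test suite.

The generator draws the noise-free closed-form trajectory of a known
parameter set at the requested sample times and adds independent Gaussian
measurement noise per channel (the least-squares objective is the maximum
likelihood estimator exactly under that noise model).  Identical seeds give
bitwise-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .model import AckermanParams, GTTSeries, closed_form_trajectory
from .diagnostics import GlycemicSeries

__all__ = [
    "CASE1_PARAMS",
    "CASE2_PARAMS",
    "SynthConfig",
    "table1_fixture",
    "simulate_gtt",
    "read_gtt_csv",
    "write_gtt_csv",
    "read_glycemic_csv",
]

#: Published fitted rate constants for the normal (case 1) and diabetic
#: (case 2) subjects of the embedded GTT measurement set.
CASE1_PARAMS = AckermanParams(p1=0.00437, p2=0.04016, p3=0.02989, p4=0.00450)
CASE2_PARAMS = AckermanParams(p1=0.00439, p2=0.02996, p3=0.01506, p4=0.00453)

# Hourly measurements (deviations from fasting baselines) for two subjects;
# times are stored in minutes internally.
_TABLE1_TIMES_MIN = (0.0, 60.0, 120.0, 180.0)
_TABLE1 = {
    1: {"g": (80.0, -29.7, -24.8, 35.8), "i": (0.0, 46.4, -34.5, -1.5)},
    2: {"g": (80.0, 18.1, -38.8, -28.0), "i": (0.0, 41.4, 18.6, -15.9)},
}


def table1_fixture() -> tuple[GTTSeries, GTTSeries]:
    """The embedded two-subject GTT measurement set (case 1, case 2).

    Returns fresh copies on every call; callers may mutate them freely.
    """
    out = []
    for case in (1, 2):
        rec = _TABLE1[case]
        out.append(GTTSeries(
            times=np.array(_TABLE1_TIMES_MIN),
            g=np.array(rec["g"]),
            i=np.array(rec["i"]),
        ))
    return out[0], out[1]


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for a synthetic noisy GTT series.

    ``params`` and the initial deviations ``(g0, i0)`` define the noise-free
    trajectory; ``sample_times`` [min] must start at 0 and increase strictly;
    ``noise_sd_g``/``noise_sd_i`` are the Gaussian measurement SDs per
    channel (0 for noise-free data); ``seed`` fixes the generator.
    """

    params: AckermanParams
    g0: float = 80.0
    i0: float = 0.0
    sample_times: tuple = _TABLE1_TIMES_MIN
    noise_sd_g: float = 0.0
    noise_sd_i: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValidationError("sample_times must start at 0 and increase strictly")
        if self.noise_sd_g < 0 or self.noise_sd_i < 0:
            raise ValidationError("noise SDs must be non-negative")


def simulate_gtt(config: SynthConfig) -> GTTSeries:
    """Noise-free closed-form trajectory plus seeded Gaussian noise.

    Noise is independent across channels and times (PCG64 generator via
    ``numpy.random.default_rng``); identical configs give bitwise-identical
    series across runs and platforms.
    """
    times = np.asarray(config.sample_times, dtype=float)
    traj = closed_form_trajectory(config.params, config.g0, config.i0, times)
    g = traj.states[:, 0].copy()
    i = traj.states[:, 1].copy()
    rng = np.random.default_rng(config.seed)
    if config.noise_sd_g > 0:
        g = g + rng.normal(0.0, config.noise_sd_g, size=times.size)
    if config.noise_sd_i > 0:
        i = i + rng.normal(0.0, config.noise_sd_i, size=times.size)
    return GTTSeries(times=times, g=g, i=i)


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: not a readable CSV ({exc})") from exc


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # float() is correctly rounded, so 17-digit output round-trips exactly
    # (pandas' own fast parser can be one ulp off)
    raw = df[col].to_numpy()
    values = np.empty(raw.size)
    for k, cell in enumerate(raw):
        try:
            values[k] = float(cell)
        except (TypeError, ValueError):
            values[k] = np.nan
        if not np.isfinite(values[k]):
            # +2: 1-based line numbering plus one header line
            raise ParseError(
                f"{path}: non-numeric value {cell!r} in column {col!r}",
                line=k + 2,
            )
    return values


def read_gtt_csv(path, time_unit: str | None = None) -> GTTSeries:
    """Read a GTT deviation series from CSV.

    Expected columns: ``time`` (or ``time_min``/``time_h``, which declare
    the unit in the header), ``glucose_dev`` [mg/dL] and ``insulin_dev``
    [uU/mL].  ``time_unit`` ('min' or 'h') is required for a bare ``time``
    column and overrides nothing -- a suffixed header wins.  Hour inputs are
    converted to minutes.
    """
    df = _read_csv(path)
    time_col, unit = None, time_unit
    for cand, u in (("time_min", "min"), ("time_h", "h"), ("time", None)):
        if cand in df.columns:
            time_col = cand
            if u is not None:
                unit = u
            break
    if time_col is None:
        raise ParseError(f"{path}: missing time column (time, time_min or time_h)")
    missing = [c for c in ("glucose_dev", "insulin_dev") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if unit not in ("min", "h"):
        raise ParseError(
            f"{path}: time unit undeclared; pass time_unit='min'|'h' or use a "
            "time_min/time_h header"
        )
    times = _numeric_column(df, time_col, path)
    if unit == "h":
        times = times * 60.0
    g = _numeric_column(df, "glucose_dev", path)
    i = _numeric_column(df, "insulin_dev", path)
    steps = np.diff(times)
    if np.any(steps <= 0):
        k = int(np.flatnonzero(steps <= 0)[0])
        raise ParseError(f"{path}: sample times not strictly increasing", line=k + 3)
    try:
        return GTTSeries(times=times, g=g, i=i)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gtt_csv(series: GTTSeries, path) -> None:
    """Write a GTT series (times in minutes) losslessly (17 significant digits)."""
    df = pd.DataFrame({
        "time_min": series.times,
        "glucose_dev": series.g,
        "insulin_dev": series.i,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_glycemic_csv(path, unit: str | None = None) -> GlycemicSeries:
    """Read a glycemic monitoring series from CSV.

    Expected columns: ``time_h`` plus a glucose column whose header declares
    the unit (``glucose_mgdl`` or ``glucose_mmol``), or a bare ``glucose``
    column with the unit passed explicitly.  An optional ``period`` column
    becomes the grouping label for weekly scoring.
    """
    df = _read_csv(path)
    if "time_h" not in df.columns:
        raise ParseError(f"{path}: missing column 'time_h'")
    gluc_col = None
    for cand, u in (("glucose_mgdl", "mg/dL"), ("glucose_mmol", "mmol/L"), ("glucose", None)):
        if cand in df.columns:
            gluc_col = cand
            if u is not None:
                unit = u
            break
    if gluc_col is None:
        raise ParseError(f"{path}: missing glucose column (glucose, glucose_mgdl or glucose_mmol)")
    if unit not in ("mg/dL", "mmol/L"):
        raise ParseError(f"{path}: glucose unit undeclared; pass unit or use a suffixed header")
    times = _numeric_column(df, "time_h", path)
    gluc = _numeric_column(df, gluc_col, path)
    labels = df["period"].to_numpy() if "period" in df.columns else None
    try:
        return GlycemicSeries(times=times, glucose=gluc, unit=unit, period_label=labels)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
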
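"""Half-life estimation from pooled rifampicin-chase time courses.

Each transcript in each strain contributes twelve points: three biological
replicates on three different four-point schedules, with the three t = 0
arrays entering as three separate points.  Two models are available:

* log-linear -- ordinary least squares of ln(intensity) on time; the
  degradation rate constant is k = -slope and t1/2 = ln2 / k.
* delay -- a continuous piecewise model with a flat baseline up to a
  transcription-arrest delay tau followed by exponential decay, fitted by
  profiling tau over a grid and keeping the least-squares minimum.

A fit is flagged reliable when the coefficient of variation of the slope
(standard error / |slope|) is below the threshold (default 30%) and the
estimated k is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LN2, ValidationError


@dataclass
class TimeCourse:
    """One transcript's pooled chase series in one strain."""

    transcript_id: str
    strain: str
    times: np.ndarray
    intensities: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities differ in length")

    def validate(self) -> "TimeCourse":
        if self.times.size < 4:
            raise ValidationError("time course needs >= 4 points")
        if np.unique(self.times).size < 3:
            raise ValidationError("time course needs >= 3 distinct times")
        if not np.any(self.times == 0):
            raise ValidationError("time course must include t = 0")
        if np.any(self.times < 0):
            raise ValidationError("times must be non-negative")
        if np.any(self.intensities <= 0):
            raise ValidationError("intensities must be > 0")
        return self


FIT_COLUMNS = [
    "transcript_id",
    "strain",
    "model",
    "slope",
    "k",
    "t_half",
    "delay",
    "se_slope",
    "cv",
    "rss",
    "n_points",
    "reliable",
]


def half_life_from_k(k: float) -> float:
    """t1/2 = ln2 / k for a first-order decay; requires k > 0."""
    if not k > 0:
        raise ValidationError("half-life undefined for k <= 0")
    return LN2 / k


def fit_loglinear_matrix(times, ln_y: np.ndarray):
    """OLS of ln(intensity) on time for many transcripts at once.

    ``ln_y`` has one row per transcript on the shared time vector.
    Returns (slope, se_slope, rss) arrays; se uses df = n - 2.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(ln_y, dtype=float))
    n = t.size
    if np.unique(t).size < 3:
        raise ValidationError("need >= 3 distinct times")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    ybar = Y.mean(axis=1)
    slope = (Y - ybar[:, None]) @ tc / sxx
    fitted = ybar[:, None] + slope[:, None] * tc[None, :]
    resid = Y - fitted
    rss = np.einsum("ij,ij->i", resid, resid)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx)
    return slope, se, rss


def _fit_frame(ids, strain, model, slope, se, rss, n, delay):
    slope = np.asarray(slope, dtype=float)
    se = np.asarray(se, dtype=float)
    k = -slope
    with np.errstate(divide="ignore", invalid="ignore"):
        t_half = np.where(k > 0, LN2 / k, np.nan)
        cv = np.where(slope != 0, se / np.abs(slope), np.inf)
    return pd.DataFrame(
        {
            "transcript_id": ids,
            "strain": strain,
            "model": model,
            "slope": slope,
            "k": k,
            "t_half": t_half,
            "delay": np.broadcast_to(np.asarray(delay, dtype=float), slope.shape),
            "se_slope": se,
            "cv": cv,
            "rss": rss,
            "n_points": n,
            "reliable": False,
        }
    )[FIT_COLUMNS]


def fit_loglinear(tc: TimeCourse) -> pd.Series:
    """Log-linear fit of one time course; returns one DecayFit row."""
    tc.validate()
    slope, se, rss = fit_loglinear_matrix(tc.times, np.log(tc.intensities))
    df = _fit_frame(
        [tc.transcript_id], tc.strain, "loglinear", slope, se, rss, tc.times.size, 0.0
    )
    return df.iloc[0]


def fit_delay_matrix(times, ln_y: np.ndarray, tau_grid):
    """Profile the arrest delay tau over a grid, per transcript.

    For each tau the model is ln y = b0 for t <= tau and
    b0 - k (t - tau) beyond, continuous at tau (a hinge on (t - tau)+).
    The tau minimizing the residual sum of squares wins; ties go to the
    smallest tau.  Returns (slope, se_slope, rss, tau_hat).
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(ln_y, dtype=float))
    taus = np.asarray(tau_grid, dtype=float)
    if taus.size == 0 or taus[0] != 0 or not np.all(np.diff(taus) > 0):
        raise ValidationError("tau_grid must start at 0 and increase strictly")
    if taus[-1] > t.max() / 2:
        raise ValidationError("tau_grid must stay within [0, max(time)/2]")
    if np.sum(t > taus[-1]) < 3:
        raise ValidationError("fewer than 3 points beyond the largest grid tau")
    n = t.size
    g = Y.shape[0]
    best_rss = np.full(g, np.inf)
    best_slope = np.zeros(g)
    best_se = np.zeros(g)
    best_tau = np.zeros(g)
    for tau in taus:
        x = np.maximum(t - tau, 0.0)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            continue
        ybar = Y.mean(axis=1)
        slope = (Y - ybar[:, None]) @ xc / sxx
        fitted = ybar[:, None] + slope[:, None] * xc[None, :]
        resid = Y - fitted
        rss = np.einsum("ij,ij->i", resid, resid)
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
        better = rss < best_rss - 1e-14  # strict: ties keep the smaller tau
        best_slope = np.where(better, slope, best_slope)
        best_se = np.where(better, se, best_se)
        best_tau = np.where(better, tau, best_tau)
        best_rss = np.where(better, rss, best_rss)
    return best_slope, best_se, best_rss, best_tau


def fit_delay_shared(times, ln_y: np.ndarray, tau_grid) -> float:
    """Cohort-level arrest delay: the tau minimizing the summed RSS.

    A single tau shared by all transcripts is far better identified than
    per-transcript delays, since the pooled residual surface averages out
    per-transcript noise.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(ln_y, dtype=float))
    taus = np.asarray(tau_grid, dtype=float)
    best_tau, best_total = 0.0, np.inf
    for tau in taus:
        x = np.maximum(t - tau, 0.0)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            continue
        ybar = Y.mean(axis=1)
        slope = (Y - ybar[:, None]) @ xc / sxx
        resid = Y - (ybar[:, None] + slope[:, None] * xc[None, :])
        total = float(np.einsum("ij,ij->", resid, resid))
        if total < best_total - 1e-12:
            best_total, best_tau = total, float(tau)
    return best_tau


def fit_delay(tc: TimeCourse, tau_grid) -> pd.Series:
    """Delay-model fit of one time course; returns one DecayFit row."""
    tc.validate()
    slope, se, rss, tau = fit_delay_matrix(tc.times, np.log(tc.intensities), tau_grid)
    df = _fit_frame(
        [tc.transcript_id], tc.strain, "delay", slope, se, rss, tc.times.size, tau
    )
    return df.iloc[0]


def fit_cohort(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    strain: str,
    model: str = "loglinear",
    tau_grid=None,
    background_level: float | None = None,
    detection_fold: float = 3.0,
) -> pd.DataFrame:
    """Fit every transcript of one strain from a transcript x array table.

    ``expr`` is on the linear intensity scale; non-positive entries are
    floored at the smallest positive observed value before taking logs
    (rare, and logged as a fit-quality matter rather than an error).

    When ``background_level`` is given (typically the invariant-probe
    median, i.e. the array background), transcripts whose mean T0
    intensity is below ``detection_fold`` times it are flagged
    ``detected = False``: a flat background trace can pass the CV filter
    by chance with an arbitrary apparent half-life, so undetected
    transcripts must not enter downstream gene sets.
    """
    arrays = sheet.loc[sheet["strain"] == strain, "array_id"].tolist()
    times = sheet.set_index("array_id").loc[arrays, "time_min"].to_numpy(dtype=float)
    vals = expr[arrays].to_numpy(dtype=float)
    if np.any(vals <= 0):
        floor = vals[vals > 0].min()
        vals = np.maximum(vals, floor)
    ln_y = np.log(vals)
    if model == "loglinear":
        slope, se, rss = fit_loglinear_matrix(times, ln_y)
        tau = 0.0
    elif model == "delay":
        if tau_grid is None:
            tau_grid = default_tau_grid(times)
        slope, se, rss, tau = fit_delay_matrix(times, ln_y, tau_grid)
    else:
        raise ValidationError(f"unknown decay model {model!r}")
    fits = _fit_frame(expr.index, strain, model, slope, se, rss, times.size, tau)
    if background_level is not None:
        t0_arrays = sheet.loc[
            (sheet["strain"] == strain) & (sheet["time_min"] == 0.0), "array_id"
        ].tolist()
        t0_mean = expr[t0_arrays].mean(axis=1).to_numpy(dtype=float)
        fits["detected"] = t0_mean > detection_fold * background_level
    else:
        fits["detected"] = True
    return reliability_filter(fits)


def default_tau_grid(times, tau_max: float = 5.0, step: float = 0.1) -> np.ndarray:
    """Default delay grid: 0 to min(tau_max, max(time)/2) in 0.1-min steps."""
    hi = min(float(tau_max), float(np.max(times)) / 2.0)
    return np.round(np.arange(0.0, hi + step / 2, step), 10)


def reliability_filter(fits: pd.DataFrame, cv_threshold: float = 0.30) -> pd.DataFrame:
    """Flag fits as reliable when cv < threshold and k > 0."""
    out = fits.copy()
    with np.errstate(invalid="ignore"):
        out["reliable"] = (out["cv"] < cv_threshold) & (out["k"] > 0)
    return out


def common_gene_set(reliable_sets: dict[str, set] | list) -> set:
    """Transcripts reliably fitted in every strain (set intersection)."""
    sets = (
        list(reliable_sets.values())
        if isinstance(reliable_sets, dict)
        else list(reliable_sets)
    )
    if len(sets) < 2:
        raise ValidationError("need >= 2 strains to intersect")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    return common
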
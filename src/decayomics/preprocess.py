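"""Probe-level preprocessing: the two normalization paths.

The pipeline keeps two deliberately distinct routes from raw probe
intensities to transcript-level quantities, mirroring how decay and
steady-state data must be treated differently:

* **decay path** -- rank-invariant probe-set scaling between strains,
  then the per-array transcript intensity is the median of the
  transcript's probes.  No background correction or quantile
  normalization: a constant per-strain scale factor leaves the slope of
  ln(intensity) versus time untouched, which is exactly what half-life
  estimation needs.

* **steady-state path** -- normexp background correction, intra-replicate
  quantile normalization within each strain, rank-invariant scaling
  between strains, robust multi-array (median-polish) summarization on
  log2 intensities, and finally multiplication by the strain's total-RNA
  extraction yield (ug RNA per mg dry cell weight) to obtain a
  concentration in arbitrary units per mg DCW that is comparable between
  strains.

Each high-level driver stamps its outputs with the path name so the two
routes cannot be cross-wired silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProbeMatrix
from .simulate import ValidationError


# ---------------------------------------------------------------------------
# normexp background correction


@dataclass
class NormexpParams:
    """Parameters of the normal-background + exponential-signal model."""

    mu: float
    sigma: float
    alpha: float

    def validate(self) -> "NormexpParams":
        if not (self.sigma > 0):
            raise ValidationError("sigma must be > 0")
        if not (self.alpha > 0):
            raise ValidationError("alpha must be > 0")
        return self


def _histogram_mode(x: np.ndarray, lo: float, hi: float, bins: int = 256) -> float:
    counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
    # Gaussian smoothing over a few bins stabilizes the argmax
    w = np.exp(-0.5 * (np.arange(-8, 9) / 2.5) ** 2)
    w /= w.sum()
    smooth = np.convolve(counts.astype(float), w, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[int(np.argmax(smooth))])


def _density_mode(x: np.ndarray, bins: int = 256) -> float:
    """Mode of a smoothed histogram density estimate, refined by zooming.

    Array intensities span several decades while the background peak is
    narrow, so a single coarse histogram cannot resolve it; a second pass
    re-histograms the neighborhood of the coarse mode.
    """
    lo, hi = np.quantile(x, [0.001, 0.999])
    if hi <= lo:
        raise ValidationError("degenerate intensity distribution (no spread)")
    mode = _histogram_mode(x, lo, hi, bins)
    width = (hi - lo) / bins
    for _ in range(3):
        lo2 = max(lo, mode - 4 * width)
        hi2 = min(hi, mode + 4 * width)
        inside = x[(x >= lo2) & (x <= hi2)]
        if hi2 <= lo2 or inside.size < 50:
            break
        mode = _histogram_mode(inside, lo2, hi2, bins)
        new_width = (hi2 - lo2) / bins
        if new_width >= width:
            break
        width = new_width
    return mode


def estimate_normexp_params(array_intensities) -> NormexpParams:
    """Estimate (mu, sigma, alpha) from one array's intensity distribution.

    mu is the density mode (background level), sigma the RMS spread of
    values below the mode, and alpha the mean excess of values above the
    mode (the exponential signal mean).
    """
    x = np.asarray(array_intensities, dtype=float)
    if x.size < 100:
        raise ValidationError("need >= 100 intensities to estimate background")
    if np.ptp(x) == 0:
        raise ValidationError("constant intensities: background not estimable")
    mu = _density_mode(x)
    below = x[x < mu]
    above = x[x > mu]
    if below.size == 0 or above.size == 0:
        raise ValidationError("no spread around the density mode")
    sigma = float(np.sqrt(np.mean((below - mu) ** 2)))
    alpha = float(np.mean(above - mu))
    if sigma <= 0:
        sigma = 1e-8
    if alpha <= 0:
        alpha = 1e-8
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_signal(x, params: NormexpParams) -> np.ndarray:
    """Posterior mean E[signal | observed] under the normexp convolution.

    With signal S ~ Exp(alpha) and background B ~ N(mu, sigma^2) observed
    as X = S + B, the posterior of S is a normal truncated to (0, inf)
    with location m = x - mu - sigma^2/alpha and scale sigma, giving
    E[S|X=x] = m + sigma * phi(m/sigma) / Phi(m/sigma).  Computed in log
    space so deep-background values stay finite and positive.
    """
    params.validate()
    x = np.asarray(x, dtype=float)
    m = x - params.mu - params.sigma**2 / params.alpha
    z = m / params.sigma
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    out = m + params.sigma * np.exp(log_ratio)
    return np.maximum(out, 1e-12)


def background_correct(
    probes: ProbeMatrix, params: dict[str, NormexpParams] | None = None
) -> tuple[ProbeMatrix, dict[str, NormexpParams]]:
    """Apply normexp correction array by array.

    Parameters are estimated per array unless supplied.  Returns the
    corrected matrix (strictly positive, monotone in the raw values) and
    the per-array parameters used.
    """
    used: dict[str, NormexpParams] = {}
    out = {}
    for a in probes.arrays:
        p = params[a] if params is not None else estimate_normexp_params(
            probes.values[a].to_numpy()
        )
        used[a] = p
        out[a] = normexp_signal(probes.values[a].to_numpy(), p)
    corrected = pd.DataFrame(out, index=probes.values.index)
    return ProbeMatrix(probes.transcripts, corrected), used


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize_values(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of ``values``.

    After normalization every column has the same sorted vector: the mean
    of the columns' sorted input vectors.  Tied observations within a
    column receive the average of the reference values their positions
    span.
    """
    if values.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 arrays")
    x = values.to_numpy(dtype=float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values across runs of tied observations
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i + 1
            while k < n and sorted_col[k] == sorted_col[i]:
                k += 1
            if k - i > 1:
                assigned[order[i:k]] = ref[i:k].mean()
            i = k
        out[:, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(probes: ProbeMatrix, array_group) -> ProbeMatrix:
    """Quantile-normalize a group of arrays, leaving other arrays as-is."""
    group = list(array_group)
    normed = quantile_normalize_values(probes.values[group])
    values = probes.values.copy()
    values[group] = normed
    return ProbeMatrix(probes.transcripts, values)


# ---------------------------------------------------------------------------
# rank-invariant probe set and between-condition scaling


def select_invariant_probes(
    probes: ProbeMatrix,
    arrays,
    background_quantile: float = 0.25,
    rank_spread_max: float = 0.05,
) -> pd.Index:
    """Select low-intensity probes whose rank barely moves across arrays.

    A probe qualifies when its mean normalized rank (0 = dimmest) across
    the given arrays is below ``background_quantile`` and the range of its
    normalized rank is at most ``rank_spread_max``.  These probes sit in
    the array background, so their intensities track the overall
    hybridization level rather than any transcript's abundance, which is
    what makes them usable as a between-condition scaling anchor.
    """
    sub = probes.values[list(arrays)]
    n = sub.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 probes for rank-invariant selection")
    ranks = (sub.rank(axis=0, method="average") - 1.0) / (n - 1.0)
    mean_rank = ranks.mean(axis=1)
    spread = ranks.max(axis=1) - ranks.min(axis=1)
    sel = sub.index[(mean_rank < background_quantile) & (spread <= rank_spread_max)]
    if len(sel) == 0:
        raise ValidationError(
            "no rank-invariant probes found; relax background_quantile or "
            "rank_spread_max"
        )
    return sel


def scale_between_conditions(
    probes: ProbeMatrix,
    invariant: pd.Index,
    conditions: dict[str, list[str]],
    factor_arrays: dict[str, list[str]] | None = None,
) -> tuple[ProbeMatrix, dict[str, float]]:
    """Equalize the invariant-set median across conditions.

    Each condition's arrays are divided by (median of invariant-probe
    intensities in that condition / global median).  Factors are computed
    on ``factor_arrays`` (default: all arrays of the condition) but applied
    to every array of the condition, so e.g. factors derived from T0
    arrays can rescale a strain's whole chase series.
    """
    if len(invariant) == 0:
        raise ValidationError("invariant probe set is empty")
    if factor_arrays is None:
        factor_arrays = conditions
    inv_vals = probes.values.loc[invariant]
    pooled = np.concatenate(
        [inv_vals[list(factor_arrays[c])].to_numpy().ravel() for c in conditions]
    )
    global_median = float(np.median(pooled))
    if global_median == 0:
        raise ValidationError("global invariant median is zero")
    values = probes.values.copy()
    factors: dict[str, float] = {}
    for cond, arrays in conditions.items():
        med = float(np.median(inv_vals[list(factor_arrays[cond])].to_numpy()))
        if med == 0:
            raise ValidationError(f"invariant median is zero in condition {cond!r}")
        f = med / global_median
        factors[cond] = f
        values[list(arrays)] = values[list(arrays)] / f
    return ProbeMatrix(probes.transcripts, values), factors


# ---------------------------------------------------------------------------
# summarization


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D table.

    Returns (overall, row_effects, col_effects, residuals) with the
    additive decomposition x = overall + row + col + residual.  Row and
    column medians are subtracted alternately until the largest subtracted
    median falls below ``tol`` (the sweeps contract geometrically) or
    ``max_iter`` sweeps have run.
    """
    r = np.asarray(x, dtype=float).copy()
    overall = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    for _ in range(max_iter):
        rmed = np.median(r, axis=1)
        row += rmed
        r -= rmed[:, None]
        delta = np.median(col)
        overall += delta
        col -= delta

        cmed = np.median(r, axis=0)
        col += cmed
        r -= cmed[None, :]
        delta = np.median(row)
        overall += delta
        row -= delta

        if max(float(np.abs(rmed).max()), float(np.abs(cmed).max())) < tol:
            break
    return overall, row, col, r


def summarize_rma(
    probes: ProbeMatrix, arrays, tol: float = 1e-6, max_iter: int = 20
) -> pd.DataFrame:
    """Median-polish summarization of log2 probe intensities.

    Per transcript, the probes x arrays block is decomposed into probe
    (row) and array (column) effects; the transcript's log2 expression on
    each array is overall + column effect.  Inputs must be strictly
    positive (they are logged).
    """
    arrays = list(arrays)
    vals = probes.values[arrays]
    if (vals.to_numpy() <= 0).any():
        raise ValidationError("non-positive intensities: log2 undefined")
    log2v = np.log2(vals.to_numpy())
    tmap = probes.transcripts.to_numpy()
    order = np.argsort(tmap, kind="mergesort")
    sorted_t = tmap[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_t[1:] != sorted_t[:-1], True])
    out_ids = []
    out_rows = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        block = log2v[order[b0:b1], :]
        overall, _row, colfx, _res = median_polish(block, tol=tol, max_iter=max_iter)
        out_ids.append(sorted_t[b0])
        out_rows.append(overall + colfx)
    expr = pd.DataFrame(np.vstack(out_rows), index=out_ids, columns=arrays)
    expr.index.name = "transcript_id"
    return expr.sort_index()


def summarize_median(probes: ProbeMatrix, arrays=None) -> pd.DataFrame:
    """Per-transcript, per-array median of probe intensities (linear scale)."""
    vals = probes.values if arrays is None else probes.values[list(arrays)]
    out = vals.groupby(probes.transcripts).median()
    out.index.name = "transcript_id"
    return out.sort_index()


# ---------------------------------------------------------------------------
# yield scaling


@dataclass
class ConcentrationTable:
    """Yield-scaled steady-state concentrations (AU per mg dry cell weight).

    ``per_array`` is transcript x T0 array; ``mean`` is transcript x strain
    (mean over the strain's T0 arrays).  ``path`` records the
    normalization route that produced the values.
    """

    per_array: pd.DataFrame
    mean: pd.DataFrame
    path: str = "rma_steady_state"


def apply_yield(
    expr_linear: pd.DataFrame, sheet: pd.DataFrame, yields: dict[str, float]
) -> ConcentrationTable:
    """Multiply linear-scale intensities by the strain's total-RNA yield.

    The yield (ug RNA per mg dry cell weight) converts relative
    intensities into an absolute-ish concentration per cell mass, which is
    what makes concentrations comparable between strains with different
    total RNA content.
    """
    meta = sheet.set_index("array_id")
    per_array = {}
    for a in expr_linear.columns:
        strain = meta.loc[a, "strain"]
        if strain not in yields:
            raise ValidationError(f"no extraction yield for strain {strain!r}")
        per_array[a] = expr_linear[a] * yields[strain]
    per_array = pd.DataFrame(per_array, index=expr_linear.index)
    t0 = meta[meta["role"] == "T0"]
    means = {}
    for strain, grp in t0.groupby("strain"):
        cols = [a for a in grp.index if a in per_array.columns]
        if not cols:
            raise ValidationError(f"no T0 arrays for strain {strain!r}")
        means[strain] = per_array[cols].mean(axis=1)
    mean = pd.DataFrame(means, index=expr_linear.index)
    return ConcentrationTable(per_array=per_array, mean=mean)


# ---------------------------------------------------------------------------
# the two normalization paths


def run_decay_path(
    probes: ProbeMatrix,
    sheet: pd.DataFrame,
    background_quantile: float = 0.25,
    rank_spread_max: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Decay-path preprocessing: invariant scaling + median summarization.

    Returns the transcript x array intensity table (linear scale, all
    arrays) and a report with the scale factors and invariant-set size.
    """
    t0 = sheet.loc[sheet["role"] == "T0", "array_id"].tolist()
    invariant = select_invariant_probes(
        probes, t0, background_quantile, rank_spread_max
    )
    conditions = {
        s: g["array_id"].tolist() for s, g in sheet.groupby("strain", sort=False)
    }
    factor_arrays = {
        s: [a for a in arrays if a in t0] for s, arrays in conditions.items()
    }
    scaled, factors = scale_between_conditions(
        probes, invariant, conditions, factor_arrays
    )
    expr = summarize_median(scaled)
    background_level = float(
        np.median(scaled.values.loc[invariant, t0].to_numpy())
    )
    report = {
        "path": "invariant_scaling_median",
        "invariant_probes": int(len(invariant)),
        "scale_factors": factors,
        "background_level": background_level,
    }
    return expr, report


def run_steady_state_path(
    probes: ProbeMatrix,
    sheet: pd.DataFrame,
    yields: dict[str, float],
    background_quantile: float = 0.25,
    rank_spread_max: float = 0.05,
) -> tuple[ConcentrationTable, pd.DataFrame, dict]:
    """Steady-state path: normexp -> quantile -> invariant scaling -> RMA -> yield.

    Operates on the T0 arrays only.  Returns the concentration table, the
    log2 expression matrix (transcript x T0 array, before yield scaling)
    and a report.
    """
    t0_sheet = sheet[sheet["role"] == "T0"]
    t0 = t0_sheet["array_id"].tolist()
    sub = probes.subset_arrays(t0)
    corrected, params = background_correct(sub)
    for strain, grp in t0_sheet.groupby("strain", sort=False):
        corrected = quantile_normalize(corrected, grp["array_id"].tolist())
    invariant = select_invariant_probes(
        corrected, t0, background_quantile, rank_spread_max
    )
    conditions = {
        s: g["array_id"].tolist() for s, g in t0_sheet.groupby("strain", sort=False)
    }
    scaled, factors = scale_between_conditions(corrected, invariant, conditions)
    blocks = [summarize_rma(scaled, arrays) for arrays in conditions.values()]
    log2_expr = pd.concat(blocks, axis=1)[t0]
    conc = apply_yield(np.exp2(log2_expr), sheet, yields)
    report = {
        "path": "rma_steady_state",
        "invariant_probes": int(len(invariant)),
        "scale_factors": factors,
        "normexp": {a: vars(p) for a, p in params.items()},
    }
    return conc, log2_expr, report
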
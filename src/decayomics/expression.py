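"""Differential steady-state expression and ncRNA fold changes.

Between-strain concentration differences are tested with a moderated t
statistic: per-gene sample variances are shrunk toward a prior variance
s0^2 whose weight d0 (prior degrees of freedom) is estimated across all
genes by moment matching on the log variances -- the empirical-Bayes
scheme in which s^2 ~ s0^2 * F(d, d0) marginally.  The moderated t has
d0 + d degrees of freedom, gaining power at small replicate numbers.

Fold changes are taken on the yield-scaled linear concentrations (so the
between-strain comparison is in absolute-ish units); logs appear only
inside the t statistic.  ncRNA fold changes come from library-size
normalized counts with a pseudo-count on zeros.  Category enrichment is a
one-sided hypergeometric over-representation test against user-supplied
gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .simulate import ValidationError
from .stability import adjust_bh


@dataclass
class EBayesPrior:
    """Prior variance s0^2 and prior degrees of freedom d0 (may be inf)."""

    d0: float
    s0_sq: float

    def validate(self) -> "EBayesPrior":
        if not self.d0 > 0:
            raise ValidationError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq must be > 0")
        return self


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return float(x_new)
        x = x_new
    return float(x)


def estimate_eb_prior(s_sq, df: float, winsor: float | None = None) -> EBayesPrior:
    """Moment-matching estimate of (d0, s0^2) from per-gene variances.

    Under the scaled-F model, z = ln s^2 has mean
    ln s0^2 + digamma(d/2) - ln(d/2) and excess variance trigamma(d0/2)
    beyond the sampling term trigamma(d/2).  Matching the sample mean and
    variance of the adjusted z gives d0 (via the trigamma inverse) and
    s0^2.  When the empirical variance does not exceed the sampling term,
    the variances are consistent with a common value and d0 = inf.

    ``winsor`` (e.g. 0.1) clips ln s^2 at its lower/upper quantiles before
    moment matching: a robust variant for variance distributions with
    degenerate tails, such as the atom of (near-)zero replicate variances
    that median-polish summarization over three arrays produces.  The
    resulting d0 is approximate (clipping deflates the spread) but keeps
    the shrinkage target anchored at the bulk of the distribution.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if df < 1:
        raise ValidationError("residual df must be >= 1")
    if np.all(s_sq == 0):
        raise ValidationError("all sample variances are zero")
    pos = s_sq[s_sq > 0]
    if pos.size < 50:
        raise ValidationError("need >= 50 positive variances")
    z = np.log(pos)
    if winsor is not None:
        if not 0.0 < winsor < 0.5:
            raise ValidationError("winsor must lie in (0, 0.5)")
        lo, hi = np.quantile(z, [winsor, 1.0 - winsor])
        z = np.clip(z, lo, hi)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    prior: EBayesPrior,
) -> pd.DataFrame:
    """Moderated two-sample t test on log2 expression replicates.

    ``group_a`` / ``group_b`` are genes x replicates (log2 scale).  The
    pooled per-gene variance s^2 (d = n_a + n_b - 2 df) is shrunk to
    s~^2 = (d0 s0^2 + d s^2) / (d0 + d); with d0 = 0 this is the ordinary
    pooled t, with d0 = inf every gene uses s0^2 and the reference
    distribution approaches the normal.
    """
    index = group_a.index if isinstance(group_a, pd.DataFrame) else None
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("need >= 2 replicates per group")
    d = na + nb - 2
    log2fc = B.mean(axis=1) - A.mean(axis=1)
    s2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / d
    if prior.d0 == 0:
        s2_post = s2
        df_total = float(d)
    elif np.isinf(prior.d0):
        prior.validate()
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        prior.validate()
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = float(prior.d0 + d)
    denom = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / denom
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "p": p,
        }
    )
    if index is not None:
        out.index = index
        out.index.name = "transcript_id"
    return out


def classify_de(
    results: pd.DataFrame,
    p_adj_threshold: float = 0.01,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> pd.DataFrame:
    """Label genes up/down/ns from adjusted p and fold-change bounds."""
    if "p_adj" not in results:
        raise ValidationError("classify_de needs a p_adj column (run adjust_bh first)")
    fc = results["fc"].to_numpy(dtype=float)
    sig = results["p_adj"].to_numpy(dtype=float) < p_adj_threshold
    label = np.where(
        sig & (fc > fc_hi), "up", np.where(sig & (fc < fc_lo), "down", "ns")
    )
    out = results.copy()
    out["de_class"] = label
    return out


def differential_expression(
    conc_per_array: pd.DataFrame,
    sheet: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    p_adj_threshold: float = 0.01,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    winsor: float | None = 0.1,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Moderated-t comparison of strain_b vs strain_a T0 concentrations.

    The prior is estimated with winsorized moment matching by default
    because three-array median-polish summaries leave an atom of zero
    replicate variances that would otherwise degenerate the fit.
    """
    meta = sheet.set_index("array_id")
    t0 = meta[meta["role"] == "T0"]
    cols_a = [a for a in conc_per_array.columns if t0.loc[a, "strain"] == strain_a]
    cols_b = [a for a in conc_per_array.columns if t0.loc[a, "strain"] == strain_b]
    A = np.log2(conc_per_array[cols_a])
    B = np.log2(conc_per_array[cols_b])
    d = len(cols_a) + len(cols_b) - 2
    s2 = (
        (len(cols_a) - 1) * A.var(axis=1, ddof=1)
        + (len(cols_b) - 1) * B.var(axis=1, ddof=1)
    ) / d
    prior = estimate_eb_prior(s2.to_numpy(), df=d, winsor=winsor)
    res = moderated_t(A, B, prior)
    res["p_adj"] = adjust_bh(res["p"].to_numpy())
    res = classify_de(res, p_adj_threshold, fc_hi, fc_lo)
    res.insert(0, "pair", f"{strain_b}_vs_{strain_a}")
    return res, prior


def log2fc_counts(
    counts_a,
    counts_b,
    libsize_a=None,
    libsize_b=None,
    pseudo: float = 0.5,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-feature fold change of condition B over A from count data.

    Counts may be vectors (one sample each) or matrices (features x
    samples); per-group means of library-size normalized counts are
    compared.  Zero counts receive a pseudo-count (default 0.5) before
    normalization so the log2 fold change stays finite.
    """
    idx = counts_a.index if isinstance(counts_a, (pd.Series, pd.DataFrame)) else None
    A = np.atleast_2d(np.asarray(counts_a, dtype=float).T).T
    B = np.atleast_2d(np.asarray(counts_b, dtype=float).T).T
    if np.any(A < 0) or np.any(B < 0):
        raise ValidationError("counts must be non-negative")
    A = np.where(A == 0, pseudo, A)
    B = np.where(B == 0, pseudo, B)
    if normalize:
        la = np.asarray(
            libsize_a if libsize_a is not None else A.sum(axis=0), dtype=float
        )
        lb = np.asarray(
            libsize_b if libsize_b is not None else B.sum(axis=0), dtype=float
        )
        if np.any(la <= 0) or np.any(lb <= 0):
            raise ValidationError("library sizes must be > 0")
        A = A / la
        B = B / lb
    fc = B.mean(axis=1) / A.mean(axis=1)
    out = pd.DataFrame({"fc": fc, "log2fc": np.log2(fc)})
    if idx is not None:
        out.index = idx
        out.index.name = "feature_id"
    return out


def enrichment_test(
    hit_set, universe, category_sets: dict, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per category.

    p is the upper-tail probability of drawing at least the observed
    overlap when |hit_set| genes are sampled from the universe without
    replacement.  Categories are flagged significant at ``alpha``.
    """
    universe = set(universe)
    hits = set(hit_set)
    if not hits <= universe:
        raise ValidationError("hit set contains genes outside the universe")
    n_u = len(universe)
    n_h = len(hits)
    rows = []
    for name, members in category_sets.items():
        members = set(members) & universe
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, n_u, len(members), n_h))
        rows.append(
            {
                "category": name,
                "category_size": len(members),
                "overlap": k,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
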
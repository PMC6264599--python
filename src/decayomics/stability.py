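"""Differential mRNA stability between strains.

The change in degradation rate between a mutant (B) and the control (A)
is the time x strain interaction coefficient in the pooled model

    ln y = b0 + b1 * t + b2 * S + b3 * (t * S),   S = 1{strain B}

fitted on the 24 pooled chase points of the two strains.  b3 is the
difference in slopes (delta k, sign-flipped), tested with a two-sided t
test on n - 4 degrees of freedom.  P-values across transcripts are
adjusted by the Benjamini-Hochberg step-up procedure; changes are
classified from the half-life fold change t1/2(B)/t1/2(A) of the
per-strain log-linear fits, so testing and classification stay decoupled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decay import TimeCourse, fit_loglinear
from .simulate import ValidationError

STABILITY_CLASSES = (
    "sig_destabilized",
    "sig_stabilized",
    "ns_destabilized",
    "ns_stabilized",
)


def interaction_test_matrix(times_a, ln_y_a, times_b, ln_y_b):
    """Time x strain interaction test for many transcripts at once.

    ``ln_y_a`` / ``ln_y_b`` have one row per transcript on the shared time
    vectors of strains A and B.  Returns a DataFrame with delta_slope
    (the interaction coefficient b3), its standard error, t and p.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    Ya = np.atleast_2d(np.asarray(ln_y_a, dtype=float))
    Yb = np.atleast_2d(np.asarray(ln_y_b, dtype=float))
    if Ya.shape[0] != Yb.shape[0]:
        raise ValidationError("strain A and B cover different transcript counts")
    t = np.concatenate([ta, tb])
    s = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    X = np.column_stack([np.ones(t.size), t, s, t * s])
    n = t.size
    if n <= 4:
        raise ValidationError("need more than 4 pooled points")
    try:
        xtx_inv = np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular interaction design: {exc}") from exc
    Y = np.hstack([Ya, Yb])
    B = xtx_inv @ X.T @ Y.T  # 4 x G
    resid = Y - (X @ B).T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / (n - 4)
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B[3] / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 4)
    return pd.DataFrame(
        {"delta_slope": B[3], "se": se, "t": tstat, "p": p}
    )


def interaction_test(tc_a: TimeCourse, tc_b: TimeCourse) -> pd.Series:
    """Interaction test for one transcript pair of time courses.

    Returns one StabilityComparison row including the half-life fold
    change t1/2(B)/t1/2(A) from the per-strain log-linear fits.
    """
    tc_a.validate()
    tc_b.validate()
    if tc_a.transcript_id != tc_b.transcript_id:
        raise ValidationError("time courses belong to different transcripts")
    res = interaction_test_matrix(
        tc_a.times,
        np.log(tc_a.intensities),
        tc_b.times,
        np.log(tc_b.intensities),
    ).iloc[0]
    fit_a = fit_loglinear(tc_a)
    fit_b = fit_loglinear(tc_b)
    fc = (
        fit_b["t_half"] / fit_a["t_half"]
        if fit_a["k"] > 0 and fit_b["k"] > 0
        else np.nan
    )
    return pd.Series(
        {
            "transcript_id": tc_a.transcript_id,
            "pair": f"{tc_b.strain}_vs_{tc_a.strain}",
            "delta_slope": res["delta_slope"],
            "se": res["se"],
            "t": res["t"],
            "p": res["p"],
            "t_half_fc": fc,
        }
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_strains(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
) -> pd.DataFrame:
    """Full per-transcript comparison table for strain_b vs strain_a."""
    meta = sheet.set_index("array_id")
    arrays_a = sheet.loc[sheet["strain"] == strain_a, "array_id"].tolist()
    arrays_b = sheet.loc[sheet["strain"] == strain_b, "array_id"].tolist()
    ta = meta.loc[arrays_a, "time_min"].to_numpy(dtype=float)
    tb = meta.loc[arrays_b, "time_min"].to_numpy(dtype=float)
    va = expr[arrays_a].to_numpy(dtype=float)
    vb = expr[arrays_b].to_numpy(dtype=float)
    floor = min(va[va > 0].min(), vb[vb > 0].min())
    res = interaction_test_matrix(
        ta, np.log(np.maximum(va, floor)), tb, np.log(np.maximum(vb, floor))
    )
    res.insert(0, "transcript_id", expr.index.to_numpy())
    res.insert(1, "pair", f"{strain_b}_vs_{strain_a}")
    th_a = fits_a.set_index("transcript_id")["t_half"].reindex(expr.index)
    th_b = fits_b.set_index("transcript_id")["t_half"].reindex(expr.index)
    res["t_half_fc"] = (th_b / th_a).to_numpy()
    res["p_adj"] = adjust_bh(res["p"].to_numpy())
    return res


def classify_stability(
    comparisons: pd.DataFrame, significance: str = "fdr10"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify half-life changes into the four-class cross-tab.

    ``significance`` is ``fdr10`` (BH-adjusted p < 0.10) or ``raw05``
    (raw p < 0.05).  Destabilized means the half-life fold change is
    below 1.  Returns the classed table and a summary with per-class
    counts and percentages.
    """
    if significance == "fdr10":
        if "p_adj" not in comparisons:
            raise ValidationError("fdr10 classification needs a p_adj column")
        sig = comparisons["p_adj"].to_numpy() < 0.10
    elif significance == "raw05":
        sig = comparisons["p"].to_numpy() < 0.05
    else:
        raise ValidationError(f"unknown significance mode {significance!r}")
    fc = comparisons["t_half_fc"].to_numpy(dtype=float)
    destab = fc < 1.0
    label = np.where(
        sig,
        np.where(destab, "sig_destabilized", "sig_stabilized"),
        np.where(destab, "ns_destabilized", "ns_stabilized"),
    )
    out = comparisons.copy()
    out["class"] = label
    total = len(out)
    counts = out["class"].value_counts().reindex(STABILITY_CLASSES, fill_value=0)
    summary = pd.DataFrame(
        {
            "class": counts.index,
            "n": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total if total else 0.0,
        }
    )
    summary.loc[len(summary)] = ["total", total, 100.0 if total else 0.0]
    return out, summary
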
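"""Degradation rate versus concentration: the three-phase analysis.

Plotting the degradation rate constant k against the steady-state
concentration (both log10) reveals a saturation structure of the in vivo
degradation machinery: a strong negative correlation at low
concentrations (substrate-limited), a weaker one at intermediate
concentrations, and none at the highest concentrations (machinery
saturated).  The three phases are delineated by k-means clustering of the
log-concentration values of all (transcript, strain) points pooled across
strains, then per-phase, per-strain Pearson correlations quantify the
coupling within each phase.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .simulate import ValidationError

PHASES = ("I", "II", "III")


def build_points(
    fits: dict[str, pd.DataFrame],
    conc_mean: pd.DataFrame,
    gene_set,
) -> pd.DataFrame:
    """One (log10 conc, log10 k) point per gene and strain.

    ``fits`` maps strain -> DecayFit table; ``conc_mean`` is transcript x
    strain mean T0 concentration; ``gene_set`` restricts to genes reliably
    fitted in every strain.
    """
    genes = sorted(gene_set)
    rows = []
    for strain, table in fits.items():
        t = table.set_index("transcript_id")
        missing = [g for g in genes if g not in t.index]
        if missing:
            raise ValidationError(
                f"strain {strain!r}: missing decay fit for gene {missing[0]!r}"
            )
        if strain not in conc_mean.columns:
            raise ValidationError(f"no concentrations for strain {strain!r}")
        missing = [g for g in genes if g not in conc_mean.index]
        if missing:
            raise ValidationError(
                f"strain {strain!r}: missing concentration for gene {missing[0]!r}"
            )
        k = t.loc[genes, "k"].to_numpy(dtype=float)
        unreliable = ~t.loc[genes, "reliable"].to_numpy(dtype=bool)
        if unreliable.any():
            bad = np.asarray(genes)[unreliable][0]
            raise ValidationError(
                f"strain {strain!r}: gene {bad!r} is not reliably fitted"
            )
        c = conc_mean.loc[genes, strain].to_numpy(dtype=float)
        rows.append(
            pd.DataFrame(
                {
                    "transcript_id": genes,
                    "strain": strain,
                    "log_conc": np.log10(c),
                    "log_k": np.log10(k),
                }
            )
        )
    points = pd.concat(rows, ignore_index=True)
    if not np.all(np.isfinite(points[["log_conc", "log_k"]].to_numpy())):
        raise ValidationError("non-finite point coordinates")
    return points


def kmeans_1d(values, k: int = 3, seed: int = 0, n_init: int = 20):
    """K-means on a 1-D vector; clusters relabeled in increasing center order.

    Lloyd iterations with k-means++ initialization and ``n_init`` restarts
    (best inertia kept).  Returns (assignments, centers, inertia) with
    assignments in 0..k-1 ordered by center.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if np.unique(x).size < k:
        raise ValidationError(f"need >= {k} distinct values for {k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[km.labels_], centers[order], float(km.inertia_)


def assign_phases(
    points: pd.DataFrame,
    seed: int = 0,
    on: str = "log_conc",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster pooled points into phases I/II/III.

    By default clustering is 1-D on log10 concentration (the phases are
    concentration zones); ``on='both'`` clusters on (log_conc, log_k)
    jointly, with phases still ordered by the concentration coordinate.
    """
    if on == "log_conc":
        labels, centers, _ = kmeans_1d(points["log_conc"].to_numpy(), seed=seed)
    elif on == "both":
        x = points[["log_conc", "log_k"]].to_numpy(dtype=float)
        km = KMeans(n_clusters=3, n_init=20, random_state=seed).fit(x)
        conc_centers = km.cluster_centers_[:, 0]
        order = np.argsort(conc_centers)
        relabel = np.empty(3, dtype=int)
        relabel[order] = np.arange(3)
        labels, centers = relabel[km.labels_], conc_centers[order]
    else:
        raise ValidationError(f"unknown clustering variable {on!r}")
    out = points.copy()
    out["phase"] = np.array(PHASES, dtype=object)[labels]
    return out, centers


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def phase_correlations(points: pd.DataFrame) -> pd.DataFrame:
    """Per-phase, per-strain (and combined) correlation of log k vs log conc."""
    if "phase" not in points:
        raise ValidationError("points have no phase assignment")
    rows = []
    groups = [("combined", points)] + [
        (s, g) for s, g in points.groupby("strain", sort=False)
    ]
    for name, grp in groups:
        for phase in PHASES:
            sub = grp[grp["phase"] == phase]
            n = len(sub)
            if n >= 3 and sub["log_conc"].nunique() > 1 and sub["log_k"].nunique() > 1:
                r, p = pearson_with_p(sub["log_k"], sub["log_conc"])
            else:
                if n > 0:
                    warnings.warn(
                        f"phase {phase} of {name}: fewer than 3 usable points, "
                        "correlation omitted"
                    )
                r, p = np.nan, np.nan
            rows.append({"strain": name, "phase": phase, "n": n, "r": r, "p": p})
    return pd.DataFrame(rows)


def cross_phase_membership(
    points: pd.DataFrame, strain_a: str, strain_b: str
) -> pd.DataFrame:
    """3 x 3 contingency of phase membership between two strains."""
    a = points[points["strain"] == strain_a].set_index("transcript_id")["phase"]
    b = points[points["strain"] == strain_b].set_index("transcript_id")["phase"]
    if set(a.index) != set(b.index):
        raise ValidationError("the two strains cover different gene sets")
    b = b.reindex(a.index)
    table = pd.crosstab(a, b).reindex(index=PHASES, columns=PHASES, fill_value=0)
    table.index.name = f"phase_{strain_a}"
    table.columns.name = f"phase_{strain_b}"
    return table
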
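#!/usr/bin/env python
"""Three-phase analysis of degradation rate versus concentration.

Pools one (log10 concentration, log10 k) point per retained transcript
and strain, splits the concentration axis into phases I/II/III by
k-means, and reports per-phase per-strain Pearson correlations plus
cross-strain phase membership.
"""

from pathlib import Path

from decayomics import (
    build_points,
    common_gene_set,
    cross_phase_membership,
    fit_cohort,
    phase_correlations,
    run_decay_path,
    run_steady_state_path,
)
from decayomics.io import read_probe_matrix, read_table, write_table
from decayomics.saturation import assign_phases
from decayomics.simulate import DEFAULT_YIELDS

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "saturation"


def main() -> None:
    probes = read_probe_matrix(DATA / "probe_matrix.tsv")
    sheet = read_table(DATA / "sample_sheet.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    expr, report = run_decay_path(probes, sheet)
    conc, _, _ = run_steady_state_path(probes, sheet, DEFAULT_YIELDS)
    strains = list(sheet["strain"].unique())
    fits = {
        s: fit_cohort(expr, sheet, s, background_level=report["background_level"])
        for s in strains
    }
    kept = {
        s: set(f.loc[f["reliable"] & f["detected"], "transcript_id"])
        for s, f in fits.items()
    }
    common = common_gene_set(kept)
    points = build_points(fits, conc.mean, common)
    points, centers = assign_phases(points, seed=0)
    stats = phase_correlations(points)
    write_table(points, OUT / "points.tsv")
    write_table(stats, OUT / "correlations.tsv")

    print(f"{len(common)} genes x {len(strains)} strains = {len(points)} points; "
          f"phase centers (log10 conc): {[round(c, 2) for c in centers]}")
    for s in strains:
        row = stats[stats["strain"] == s].set_index("phase")
        print(f"  {s}: " + ", ".join(
            f"phase {p}: n={int(row.loc[p, 'n'])}, r={row.loc[p, 'r']:.2f}"
            for p in ("I", "II", "III")
        ))

    control = strains[0]
    for mutant in strains[1:]:
        member = cross_phase_membership(points, control, mutant)
        write_table(member, OUT / f"membership_{control}_{mutant}.tsv", index=True)
        moved = member.loc[["I", "II"], "III"].sum()
        print(f"  genes in phase III of {mutant} that were in phase I/II of "
              f"{control}: {moved}")


if __name__ == "__main__":
    main()
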
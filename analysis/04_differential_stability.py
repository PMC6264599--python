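#!/usr/bin/env python
"""Test per-transcript half-life changes of each mutant against control.

The time x strain interaction in the pooled 24-point regression gives the
slope difference and its p-value; BH adjustment at 10% flags significant
changes, and each transcript is classed by the direction of its half-life
fold change.  A hypergeometric test then checks that the significantly
destabilized set is enriched for the transcripts whose decay the
generator actually accelerated.
"""

from pathlib import Path

from decayomics import classify_stability, enrichment_test, fit_cohort, run_decay_path
from decayomics.io import read_probe_matrix, read_table, write_table
from decayomics.stability import compare_strains

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "stability"


def main() -> None:
    probes = read_probe_matrix(DATA / "probe_matrix.tsv")
    sheet = read_table(DATA / "sample_sheet.tsv")
    truth = read_table(DATA / "truth_transcripts.tsv").set_index("transcript_id")
    OUT.mkdir(parents=True, exist_ok=True)

    expr, report = run_decay_path(probes, sheet)
    bg = report["background_level"]
    strains = list(sheet["strain"].unique())
    control = strains[0]
    fits = {
        s: fit_cohort(expr, sheet, s, background_level=bg) for s in strains
    }

    for mutant in strains[1:]:
        comp = compare_strains(expr, sheet, control, mutant, fits[control], fits[mutant])
        classed, summary_fdr = classify_stability(comp, "fdr10")
        _, summary_raw = classify_stability(comp, "raw05")
        write_table(classed, OUT / f"{mutant}_vs_{control}.tsv")
        write_table(summary_fdr, OUT / f"summary_fdr10_{mutant}.tsv")
        write_table(summary_raw, OUT / f"summary_raw05_{mutant}.tsv")
        n_sig = (classed["p_adj"] < 0.10).sum()
        n_destab = (classed["class"] == "sig_destabilized").sum()
        n_stab = (classed["class"] == "sig_stabilized").sum()
        print(f"{mutant} vs {control}: {n_sig} significant at BH 10% "
              f"({n_destab} destabilized, {n_stab} stabilized)")

        if mutant == "d_pnp":
            universe = set(classed["transcript_id"])
            hits = set(classed.loc[classed["class"] == "sig_destabilized",
                                   "transcript_id"])
            truly = set(
                truth.index[truth["k_d_pnp"] > 1.5 * truth["k_control"]]
            ) & universe
            enr = enrichment_test(hits, universe, {"truly_destabilized": truly})
            write_table(enr, OUT / "enrichment_destabilized.tsv")
            print(f"    enrichment of truly destabilized transcripts among "
                  f"the calls: p = {enr['p'].iloc[0]:.3g}")


if __name__ == "__main__":
    main()
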
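#!/usr/bin/env python
"""Generate the synthetic rifampicin-chase study used by the analysis.

Three strains (rph-1 control, RNase R and PNPase deletion mutants), each
with twelve arrays: three T0 replicates plus nine chase points on the
0/2/8/15, 0/5/10/18 and 0/3/12/30 minute schedules.  Ground truth
(per-strain k, delay, T0 concentration, DE effects, saturation regime) is
stored alongside so every later step can be checked by recovery.
"""

from pathlib import Path

import numpy as np

from decayomics import SimConfig, generate_arrays, generate_counts, generate_truth
from decayomics.io import write_probe_matrix, write_table, write_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    cfg = SimConfig(n_transcripts=2000, seed=SEED)
    truth = generate_truth(cfg)
    probes, sheet = generate_arrays(truth, cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    write_truth(truth, OUT)
    write_probe_matrix(probes, OUT / "probe_matrix.tsv")
    write_table(sheet, OUT / "sample_sheet.tsv")

    # ncRNA count fixture: 34 features, two conditions x 3 libraries,
    # planted log2 fold changes spanning the range seen for regulatory sRNAs
    rng = np.random.default_rng([SEED, 7])
    log2fc = rng.normal(0.0, 1.5, size=34)
    counts = generate_counts(
        34, [1.0, 1.0, 1.0], [1.0, 1.0, 1.0], log2fc,
        dispersion=0.05, seed=SEED + 7,
    )
    write_table(counts, OUT / "ncrna_counts.tsv", index=True)
    write_table(
        counts.assign(true_log2fc=log2fc)[["true_log2fc"]].reset_index(),
        OUT / "ncrna_truth.tsv",
    )

    n_exp = int(truth.transcripts["expressed"].sum())
    print(f"wrote {len(probes.arrays)} arrays x {probes.values.shape[0]} probes to {OUT}")
    print(f"{cfg.n_transcripts} transcripts, {n_exp} expressed "
          f"({n_exp / cfg.n_transcripts:.0%}); median true half-life "
          f"{np.median(np.log(2) / truth.transcripts['k_control']):.1f} min")


if __name__ == "__main__":
    main()
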
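"""Configuration, validation and end-to-end orchestration.

``run_pipeline`` chains the stages -- simulate (or load), preprocess
(both normalization paths), decay fitting (log-linear and delay models),
differential stability, differential expression (plus optional ncRNA
fold changes and enrichment), and the saturation-phase analysis --
writing every result as TSV plus a JSON run manifest.  Given the same
seed and configuration the output directory is byte-identical between
runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decay import common_gene_set, default_tau_grid, fit_cohort
from .expression import differential_expression, enrichment_test, log2fc_counts
from .io import (
    ProbeMatrix,
    read_probe_matrix,
    read_table,
    write_probe_matrix,
    write_table,
    write_truth,
)
from .preprocess import run_decay_path, run_steady_state_path
from .saturation import assign_phases, build_points, cross_phase_membership, phase_correlations
from .simulate import SimConfig, ValidationError, generate_arrays, generate_counts, generate_truth
from .stability import classify_stability, compare_strains

log = logging.getLogger("decayomics")


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run, with the study's default thresholds."""

    # inputs; when probe_matrix is None the synthetic generator supplies data
    probe_matrix: str | None = None
    sample_sheet: str | None = None
    yields: dict[str, float] | None = None
    counts: str | None = None
    category_sets: str | None = None

    cv_threshold: float = 0.30
    stability_fdr: float = 0.10
    de_fdr: float = 0.01
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    enrichment_alpha: float = 0.05
    background_quantile: float = 0.25
    rank_spread_max: float = 0.05
    tau_max: float = 5.0
    tau_step: float = 0.1
    kmeans_seed: int = 0
    seed: int = 0
    outdir: str = "results/run"

    simulate: SimConfig = field(default_factory=SimConfig)
    simulate_counts: bool = True
    nc_features: int = 34
    nc_log2fc_sd: float = 1.5
    nc_dispersion: float = 0.05

    def validate(self) -> "PipelineConfig":
        for name in ("cv_threshold", "stability_fdr", "de_fdr", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not self.fc_hi > 1.0 > self.fc_lo > 0.0:
            raise ValidationError("fold-change bounds need fc_hi > 1 > fc_lo > 0")
        if self.tau_max < 0 or self.tau_step <= 0:
            raise ValidationError("tau grid parameters must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim:
            if "strains" in sim:
                sim["strains"] = tuple(sim["strains"])
            if "schedules" in sim:
                sim["schedules"] = tuple(tuple(s) for s in sim["schedules"])
            cfg.simulate = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d


def validate_inputs(config: PipelineConfig):
    """Cross-check input files; aggregates all violations before raising.

    Returns (probes, sheet, yields) on success.
    """
    config.validate()
    errors: list[str] = []
    if config.probe_matrix is None:
        config.simulate.validate()
        truth = generate_truth(config.simulate)
        probes, sheet = generate_arrays(truth, config.simulate)
        yields = dict(config.simulate.yields)
        return probes, sheet, yields, truth

    probes = sheet = None
    try:
        probes = read_probe_matrix(config.probe_matrix)
    except (OSError, ValidationError) as exc:
        errors.append(f"probe_matrix: {exc}")
    try:
        sheet = read_table(config.sample_sheet)
    except (OSError, ValidationError, TypeError) as exc:
        errors.append(f"sample_sheet: {exc}")
    yields = dict(config.yields or {})
    if probes is not None and sheet is not None:
        needed = {"array_id", "strain", "replicate", "time_min", "role"}
        missing_cols = needed - set(sheet.columns)
        if missing_cols:
            errors.append(f"sample_sheet: missing columns {sorted(missing_cols)}")
        else:
            sheet_arrays = set(sheet["array_id"])
            for a in probes.arrays:
                if a not in sheet_arrays:
                    errors.append(f"sample_sheet: array {a!r} not described")
            for a in sheet_arrays:
                if a not in probes.arrays:
                    errors.append(f"probe_matrix: array {a!r} missing")
            for s in sorted(set(sheet["strain"])):
                if s not in yields:
                    errors.append(f"yields: missing strain {s!r}")
    if errors:
        raise ValidationError("; ".join(errors))
    return probes, sheet, yields, None


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage and write the results bundle to disk."""
    t_start = time.perf_counter()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "decayomics",
        "version": __version__,
        "seed": config.seed,
        "kmeans_seed": config.kmeans_seed,
        "thresholds": {
            "cv": config.cv_threshold,
            "stability_fdr": config.stability_fdr,
            "de_fdr": config.de_fdr,
            "fc_hi": config.fc_hi,
            "fc_lo": config.fc_lo,
            "enrichment_alpha": config.enrichment_alpha,
        },
    }
    results: dict = {}
    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("inputs")
        probes, sheet, yields, truth = validate_inputs(config)
        if truth is not None:
            write_truth(truth, out)
        write_probe_matrix(probes, out / "probe_matrix.tsv")
        write_table(sheet, out / "sample_sheet.tsv")
        log.info("inputs ready in %.1fs", time.perf_counter() - t0)

        t0 = stage("preprocess")
        decay_expr, decay_report = run_decay_path(
            probes, sheet, config.background_quantile, config.rank_spread_max
        )
        conc, log2_expr, ss_report = run_steady_state_path(
            probes, sheet, yields, config.background_quantile, config.rank_spread_max
        )
        write_table(decay_expr, out / "decay_intensities.tsv", index=True)
        write_table(conc.per_array, out / "concentrations_per_array.tsv", index=True)
        write_table(conc.mean, out / "concentrations_mean.tsv", index=True)
        norm_report = pd.DataFrame(
            [
                {"path": decay_report["path"], "condition": c, "scale_factor": f,
                 "invariant_probes": decay_report["invariant_probes"]}
                for c, f in decay_report["scale_factors"].items()
            ]
            + [
                {"path": ss_report["path"], "condition": c, "scale_factor": f,
                 "invariant_probes": ss_report["invariant_probes"]}
                for c, f in ss_report["scale_factors"].items()
            ]
        )
        write_table(norm_report, out / "normalization_report.tsv")
        manifest["normalization"] = {
            "decay_path": decay_report["scale_factors"],
            "decay_invariant_probes": decay_report["invariant_probes"],
            "steady_state_path": ss_report["scale_factors"],
            "steady_state_invariant_probes": ss_report["invariant_probes"],
        }
        log.info("preprocess done in %.1fs", time.perf_counter() - t0)

        t0 = stage("decay")
        strains = list(dict.fromkeys(sheet["strain"]))
        times_any = sheet.loc[sheet["strain"] == strains[0], "time_min"].to_numpy()
        tau_grid = default_tau_grid(times_any, config.tau_max, config.tau_step)
        bg_level = decay_report.get("background_level")
        fits: dict[str, pd.DataFrame] = {}
        fits_delay: dict[str, pd.DataFrame] = {}
        for strain in strains:
            fits[strain] = fit_cohort(
                decay_expr, sheet, strain, "loglinear", background_level=bg_level
            )
            fits_delay[strain] = fit_cohort(
                decay_expr, sheet, strain, "delay", tau_grid, background_level=bg_level
            )
            write_table(fits[strain], out / f"decay_loglinear_{strain}.tsv")
            write_table(fits_delay[strain], out / f"decay_delay_{strain}.tsv")
        reliable = {
            s: set(f.loc[f["reliable"] & f["detected"], "transcript_id"])
            for s, f in fits.items()
        }
        common = common_gene_set(reliable)
        if not common:
            log.warning("no transcript is reliable in every strain")
        write_table(
            pd.DataFrame({"transcript_id": sorted(common)}),
            out / "common_gene_set.tsv",
        )
        results["fits"] = fits
        results["fits_delay"] = fits_delay
        results["common_genes"] = common
        log.info("decay done in %.1fs (%d common genes)", time.perf_counter() - t0, len(common))

        t0 = stage("stability")
        control = strains[0]
        stab = {}
        for strain in strains[1:]:
            comp = compare_strains(
                decay_expr, sheet, control, strain, fits[control], fits[strain]
            )
            classed, summary = classify_stability(comp, "fdr10")
            _, summary_raw = classify_stability(comp, "raw05")
            write_table(classed, out / f"stability_{strain}_vs_{control}.tsv")
            write_table(summary, out / f"stability_summary_fdr10_{strain}.tsv")
            write_table(summary_raw, out / f"stability_summary_raw05_{strain}.tsv")
            stab[strain] = classed
        results["stability"] = stab
        log.info("stability done in %.1fs", time.perf_counter() - t0)

        t0 = stage("expression")
        detected = {
            s: set(f.loc[f["detected"], "transcript_id"]) for s, f in fits.items()
        }
        de = {}
        for strain in strains[1:]:
            keep = sorted(detected[control] & detected[strain])
            res, prior = differential_expression(
                conc.per_array.loc[keep], sheet, control, strain,
                config.de_fdr, config.fc_hi, config.fc_lo,
            )
            res.insert(0, "transcript_id", res.index)
            write_table(res, out / f"de_{strain}_vs_{control}.tsv")
            de[strain] = res
            manifest.setdefault("ebayes", {})[strain] = {
                "d0": None if np.isinf(prior.d0) else prior.d0,
                "s0_sq": prior.s0_sq,
            }
        results["de"] = de
        if config.counts is not None:
            counts = read_table(config.counts, index_col=0)
            a_cols = [c for c in counts.columns if c.startswith("A_")]
            b_cols = [c for c in counts.columns if c.startswith("B_")]
            nc = log2fc_counts(counts[a_cols], counts[b_cols])
            write_table(nc, out / "ncrna_fold_changes.tsv", index=True)
            results["ncrna"] = nc
        elif config.simulate_counts and config.probe_matrix is None:
            rng = np.random.default_rng([config.seed, 7])
            log2fc = rng.normal(0.0, config.nc_log2fc_sd, size=config.nc_features)
            counts = generate_counts(
                config.nc_features,
                [1.0, 1.0, 1.0],
                [1.0, 1.0, 1.0],
                log2fc,
                config.nc_dispersion,
                seed=int(rng.integers(2**31)),
            )
            write_table(counts, out / "ncrna_counts.tsv", index=True)
            a_cols = [c for c in counts.columns if c.startswith("A_")]
            b_cols = [c for c in counts.columns if c.startswith("B_")]
            nc = log2fc_counts(counts[a_cols], counts[b_cols])
            nc["true_log2fc"] = log2fc
            write_table(nc, out / "ncrna_fold_changes.tsv", index=True)
            results["ncrna"] = nc
        if config.category_sets is not None and strains[1:]:
            with open(config.category_sets) as fh:
                cats = yaml.safe_load(fh)
            strain = strains[-1]
            hits = set(de[strain].loc[de[strain]["de_class"] != "ns", "transcript_id"])
            universe = set(de[strain]["transcript_id"])
            enr = enrichment_test(hits, universe, cats, config.enrichment_alpha)
            write_table(enr, out / f"enrichment_{strain}.tsv")
            results["enrichment"] = enr
        log.info("expression done in %.1fs", time.perf_counter() - t0)

        t0 = stage("saturation")
        if common:
            points = build_points(fits, conc.mean, common)
            points, centers = assign_phases(points, seed=config.kmeans_seed)
            stats_table = phase_correlations(points)
            write_table(points, out / "phase_points.tsv")
            write_table(stats_table, out / "phase_correlations.tsv")
            manifest["kmeans_centers_log10_conc"] = [float(c) for c in centers]
            for strain in strains[1:]:
                member = cross_phase_membership(points, control, strain)
                write_table(member, out / f"phase_membership_{control}_{strain}.tsv", index=True)
            results["points"] = points
            results["phase_stats"] = stats_table
        log.info("saturation done in %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage {current['stage']!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    results["manifest"] = manifest
    return results
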
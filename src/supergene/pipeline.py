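"""End-to-end orchestration: simulate → scan → characterize → report.

A single seeded configuration drives every stage; stage-local seeds are
derived deterministically from the global seed and the stage name, so any
stage rerun in isolation reproduces its output.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import assoc, covscan, enrich, ldscan, pheno, sim
from .io import write_bed_track

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """One config for the full synthetic-data pipeline run."""

    preset: str = "perenne"
    scale: float = 1.0
    seed: int = 0
    out_dir: str = "supergene_run"
    n_perm: int = 100_000
    cov_alpha: float = 0.01
    fdr_alpha: float = 0.05
    ld_window_bp: int = 100_000
    ld_max_pairs: int = 2_000
    repeat_fold: float = 4.0
    extra: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on preset synthetic data and write a report bundle.

    Writes per-stage TSV/BED/JSON outputs under ``cfg.out_dir`` and returns
    the summary dict (also written as report.json).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"preset": cfg.preset, "scale": cfg.scale, "seed": cfg.seed}

    gcfg, ccfg = sim.preset_configs(cfg.preset, cfg.scale, seed=stage_seed(cfg.seed, "simulate"))
    logger.info("simulating preset %s (scale %g)", cfg.preset, cfg.scale)
    gt, sheet = sim.simulate_supergene_population(gcfg)
    sheet.to_tsv(out / "samples.tsv")
    sim.write_vcf(gt, dict(gcfg.contigs), out / "genotypes.vcf")
    depths = sim.simulate_window_depths(ccfg, sheet)
    summary["truth_s_locus"] = list(gcfg.s_locus)

    # Association scan
    acfg = assoc.AssocConfig(fdr_alpha=cfg.fdr_alpha)
    filtered = assoc.filter_for_association(gt, acfg)
    pruned = assoc.ld_prune(filtered, acfg.prune_window_bp, acfg.prune_r2)
    res = assoc.association_scan(pruned, sheet, acfg)
    res.table.to_csv(out / "assoc.tsv", sep="\t", index=False)
    sig = res.significant
    if len(sig):
        bed = sig.rename(columns={"pos": "end"}).assign(start=lambda d: d["end"] - 1)
        write_bed_track(bed.assign(name="assoc_snp"), out / "assoc_hits.bed")
    summary["assoc"] = {
        "n_tested": int(len(res.table)),
        "n_significant": int(len(sig)),
        "hits_per_contig": res.hits_per_contig(),
    }

    # Coverage scan
    scan = covscan.hemizygosity_scan(
        depths, sheet, n_perm=cfg.n_perm, alpha=cfg.cov_alpha,
        seed=stage_seed(cfg.seed, "covscan"),
    )
    scan.windows.to_csv(out / "covscan.tsv", sep="\t", index=False)
    regions = covscan.classify_s_regions(scan)
    if len(regions):
        write_bed_track(regions.rename(columns={"region_class": "name"}), out / "regions.bed")
    summary["covscan"] = {
        "n_tested_windows": scan.n_tested,
        "genome_median_norm_cov": scan.genome_median,
        "regions": regions.to_dict("records"),
    }

    # LD contrast between the supergene contig and the background contig
    target_c, control_c = gcfg.contigs[0][0], gcfg.contigs[1][0]
    ld_seed = stage_seed(cfg.seed, "ldscan")
    m_t = ldscan.window_ld_matrix(gt, target_c, cfg.ld_window_bp, cfg.ld_max_pairs, ld_seed)
    m_c = ldscan.window_ld_matrix(gt, control_c, cfg.ld_window_bp, cfg.ld_max_pairs, ld_seed + 1)
    contrast = ldscan.compare_contig_ld(m_t, m_c)
    summary["ld_contrast"] = {
        "U": contrast.U,
        "p": contrast.p,
        "median_r2_target": contrast.median_target,
        "median_r2_control": contrast.median_control,
    }

    # Repeat enrichment of the recovered (or true) supergene region
    region = enrich.Region(*gcfg.s_locus)
    track = sim.simulate_repeat_track(
        dict(gcfg.contigs), gcfg.s_locus, fold=cfg.repeat_fold,
        seed=stage_seed(cfg.seed, "repeats"),
    )
    enr = enrich.binomial_enrichment_scan(track, region, dict(gcfg.contigs))
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    summary["enrichment_top_class"] = (
        enr.iloc[0][["repeat_class", "log2_fold_enrichment", "p"]].to_dict()
        if len(enr)
        else None
    )

    # Hormone experiment statistics
    meas = sim.simulate_floral_measurements(
        sim.PhenoSimConfig(seed=stage_seed(cfg.seed, "pheno"))
    )
    aov = pheno.two_way_anova(meas)
    aov.table.to_csv(out / "anova.tsv", sep="\t")
    hsd = pheno.tukey_hsd(meas)
    hsd.to_csv(out / "tukey.tsv", sep="\t", index=False)
    summary["anova_interaction_p"] = float(aov["morph:treatment"]["p"])

    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
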
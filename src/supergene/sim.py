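"""Synthetic data with the statistical structure the pipeline assumes.

Every downstream stage is testable without sequencing data: the generators
emulate (a) a dominant-haplotype region present only in S-morph individuals
(≈ zero L-morph read coverage), (b) SNPs perfectly associated with morph
under a dominant model, (c) block-structured background LD, (d) codon
sequence pairs diverged at a target synonymous distance and dN/dS ratio,
(e) repeat annotations with a class enriched in the supergene region, and
(f) morph × hormone-treatment floral measurements.

Background genotypes draw allele frequencies from Beta(0.8, 0.8) truncated
to [0.05, 0.95] and sample genotypes in Hardy–Weinberg proportions,
morph-independently; LD comes from copying genotypes within haplotype-style
blocks rather than from a coalescent — simple, but sufficient to exercise
r² and pruning code.  Coverage counts are negative binomial, with the
hemizygous region at 5% of baseline in L-morph samples (residual
mismapping) rather than exactly zero.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .covscan import WindowDepthTable, tile_windows
from .io import GenotypeTable, SampleSheet
from .molevo import SENSE_CODONS, _S_FRAC, translate_codon

# ---------------------------------------------------------------------------
# Genotypes


@dataclass(frozen=True)
class SupergeneSimConfig:
    """Population-genomic simulation of a hemizygous dominant supergene.

    ``assoc_snp_count`` SNPs inside the supergene region are carried
    heterozygously by every S-morph sample and by no L-morph sample, the
    signature of a dominant hemizygous haplotype.
    """

    n_S: int = 11
    n_L: int = 7
    contigs: tuple[tuple[str, int], ...] = (
        ("contig_S", 10_000_000),
        ("contig_bg", 10_000_000),
    )
    s_locus: tuple[str, int, int] = ("contig_S", 4_000_000, 5_200_000)
    recessive_region: tuple[str, int, int] | None = None
    n_snps: int = 2000
    maf_beta: tuple[float, float] = (0.8, 0.8)
    maf_bounds: tuple[float, float] = (0.05, 0.95)
    ld_block_bp: int = 20_000
    contig_ld_block_bp: dict[str, int] | None = None
    block_copy_prob: float = 0.9
    assoc_snp_count: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_S < 1 or self.n_L < 1:
            raise ValueError("need at least one sample per morph")
        lengths = dict(self.contigs)
        c, s, e = self.s_locus
        if c not in lengths or not (0 <= s < e <= lengths[c]):
            raise ValueError("s_locus must lie inside its contig")
        if self.recessive_region is not None:
            c2, s2, e2 = self.recessive_region
            if c2 not in lengths or not (0 <= s2 < e2 <= lengths[c2]):
                raise ValueError("recessive_region must lie inside its contig")


def _truncated_beta(rng, a, b, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_supergene_population(
    cfg: SupergeneSimConfig,
) -> tuple[GenotypeTable, SampleSheet]:
    """Generate morph-labelled genotypes with a perfectly associated S-locus.

    Background SNPs are morph-independent with block-copy LD; the
    ``assoc_snp_count`` designated SNPs inside the supergene region are
    heterozygous in every S-morph sample and absent from L-morph samples.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_S + cfg.n_L
    sheet = SampleSheet(
        sample_ids=tuple(
            [f"S{i+1:02d}" for i in range(cfg.n_S)]
            + [f"L{i+1:02d}" for i in range(cfg.n_L)]
        ),
        morph=tuple(["S"] * cfg.n_S + ["L"] * cfg.n_L),
        population=tuple(["sim"] * n),
    )
    total_len = sum(l for _, l in cfg.contigs)
    bases = np.array(list("ACGT"))

    var_rows = []
    dosage_cols = []
    for contig, length in cfg.contigs:
        n_here = max(1, round(cfg.n_snps * length / total_len))
        pos = np.unique(rng.integers(1, length + 1, size=2 * n_here + 100))
        while len(pos) < n_here:  # top up after de-duplication (rare)
            pos = np.unique(
                np.concatenate([pos, rng.integers(1, length + 1, size=n_here)])
            )
        pos = np.sort(rng.choice(pos, size=n_here, replace=False))
        block_bp = (cfg.contig_ld_block_bp or {}).get(contig, cfg.ld_block_bp)
        blocks = pos // block_bp
        freqs = _truncated_beta(
            rng, *cfg.maf_beta, *cfg.maf_bounds, size=n_here
        )
        template = {}
        for k, p1 in enumerate(pos):
            blk = blocks[k]
            if blk not in template:
                template[blk] = rng.binomial(2, freqs[k], size=n)
            fresh = rng.binomial(2, freqs[k], size=n)
            copy = rng.random(n) < cfg.block_copy_prob
            g = np.where(copy, template[blk], fresh)
            refalt = rng.choice(4, size=2, replace=False)
            var_rows.append(
                (contig, int(p1), int(p1) - 1, bases[refalt[0]], bases[refalt[1]])
            )
            dosage_cols.append(g)

    # Perfectly associated SNPs inside the supergene region.
    c, s, e = cfg.s_locus
    if cfg.assoc_snp_count:
        existing = {(r[0], r[1]) for r in var_rows}
        apos = []
        while len(apos) < cfg.assoc_snp_count:
            p1 = int(rng.integers(s + 1, e + 1))
            if (c, p1) not in existing:
                existing.add((c, p1))
                apos.append(p1)
        is_s = sheet.is_morph("S")
        for p1 in apos:
            refalt = rng.choice(4, size=2, replace=False)
            var_rows.append((c, p1, p1 - 1, bases[refalt[0]], bases[refalt[1]]))
            dosage_cols.append(np.where(is_s, 1, 0))

    variants = pd.DataFrame(
        var_rows, columns=["contig", "pos", "start", "ref", "alt"]
    )
    dosages = np.array(dosage_cols, dtype=np.int8).T
    order = variants.sort_values(["contig", "pos"], kind="stable").index.to_numpy()
    gt = GenotypeTable(
        variants=variants.iloc[order].reset_index(drop=True),
        dosages=dosages[:, order],
        sample_ids=sheet.sample_ids,
    )
    return gt, sheet


def write_vcf(gt: GenotypeTable, contig_lengths: dict[str, int], path) -> None:
    """Write genotypes as a minimal VCF 4.2 (GT field only)."""
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.sample_ids)
            + "\n"
        )
        for j in range(gt.n_variants):
            v = gt.variants.iloc[j]
            calls = "\t".join(gtmap[int(d)] for d in gt.dosages[:, j])
            fh.write(
                f"{v['contig']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Coverage


@dataclass(frozen=True)
class CoverageSimConfig:
    """Windowed read-count simulation with a hemizygous signal.

    L-morph counts inside the supergene region fall to ``hemi_residual``
    of baseline (residual mismapping); S-morph counts inside an optional
    recessive-specific region fall to half.  Elsewhere both morphs share a
    negative-binomial law with the given dispersion.
    """

    contigs: tuple[tuple[str, int], ...] = (
        ("contig_S", 10_000_000),
        ("contig_bg", 10_000_000),
    )
    s_locus: tuple[str, int, int] | None = ("contig_S", 4_000_000, 5_200_000)
    recessive_region: tuple[str, int, int] | None = None
    window_bp: int = 300_000
    mean_norm_cov: float = 15.0
    base_count: float = 3000.0
    dispersion: float = 30.0
    hemi_residual: float = 0.05
    depth_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.mean_norm_cov <= 0:
            raise ValueError("mean_norm_cov must be positive")
        if self.s_locus and self.recessive_region:
            c1, s1, e1 = self.s_locus
            c2, s2, e2 = self.recessive_region
            if c1 == c2 and s1 < e2 and s2 < e1:
                raise ValueError("s_locus and recessive_region overlap")


def _overlap_frac(start: int, end: int, region: tuple[str, int, int] | None, contig: str) -> float:
    if region is None or region[0] != contig:
        return 0.0
    lo = max(start, region[1])
    hi = min(end, region[2])
    return max(0, hi - lo) / (end - start)


def simulate_window_depths(
    cfg: CoverageSimConfig, samples: SampleSheet
) -> WindowDepthTable:
    """Per-sample negative-binomial window read counts with morph structure."""
    rng = np.random.default_rng(cfg.seed)
    windows = tile_windows(dict(cfg.contigs), cfg.window_bp)
    n = len(samples)
    is_s = samples.is_morph("S")
    depth_factor = np.exp(rng.normal(0.0, cfg.depth_sigma, size=n))

    w = len(windows)
    mean = np.empty((n, w))
    for j, row in windows.iterrows():
        contig, start, end = row["contig"], row["start"], row["end"]
        size_frac = (end - start) / cfg.window_bp
        f_hemi = _overlap_frac(start, end, cfg.s_locus, contig)
        f_rec = _overlap_frac(start, end, cfg.recessive_region, contig)
        # L-morph loses the hemizygous fraction (down to residual mismapping);
        # S-morph carries one copy instead of two in the recessive region.
        factor_l = 1.0 - f_hemi * (1.0 - cfg.hemi_residual)
        factor_s = 1.0 - 0.5 * f_rec
        per_morph = np.where(is_s, factor_s, factor_l)
        mean[:, j] = cfg.base_count * size_frac * per_morph * depth_factor
    k = cfg.dispersion
    counts = rng.negative_binomial(k, k / (k + np.maximum(mean, 1e-9)))
    total = counts.sum(axis=1).astype(float)
    n_full = int((~windows["partial"]).sum())
    scale = cfg.mean_norm_cov * max(n_full, 1)
    return WindowDepthTable(
        windows=windows,
        counts=counts.astype(float),
        total_reads=total,
        sample_ids=samples.sample_ids,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Presets

#: Hemizygous-region sizes typical of small, mid and large distyly
#: supergenes (260 kb, 1.2 Mb, 3.8 Mb).
PRESET_REGION_BP = {"tenue": 260_000, "grandiflorum": 1_200_000, "perenne": 3_800_000}


def preset_configs(
    name: str, scale: float = 1.0, seed: int = 0
) -> tuple[SupergeneSimConfig, CoverageSimConfig]:
    """Genotype and coverage configs for a named supergene-size preset.

    The supergene sits mid-contig on a contig ~8× the region size (minimum
    10 windows), with an equally sized background contig; ``scale``
    multiplies all lengths.
    """
    if name not in PRESET_REGION_BP:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESET_REGION_BP)}")
    region = int(PRESET_REGION_BP[name] * scale)
    contig_len = max(int(8 * region), 3_000_000)
    start = (contig_len - region) // 2
    contigs = (("contig_S", contig_len), ("contig_bg", contig_len))
    s_locus = ("contig_S", start, start + region)
    # Recombination suppression around the supergene: much longer LD blocks
    # on the S-locus contig than on the background contig.
    gcfg = SupergeneSimConfig(
        contigs=contigs,
        s_locus=s_locus,
        contig_ld_block_bp={"contig_S": contig_len},
        seed=seed,
    )
    ccfg = CoverageSimConfig(contigs=contigs, s_locus=s_locus, seed=seed + 1)
    return gcfg, ccfg


# ---------------------------------------------------------------------------
# Codon pairs


@dataclass(frozen=True)
class CodonSimConfig:
    """Codon-pair divergence simulation at a target NG86 dS and omega."""

    n_codons: int = 500
    target_dS: float = 0.3
    omega: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.target_dS < 0:
            raise ValueError("target_dS must be non-negative")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


def _codon_rate_matrix(omega: float) -> tuple[np.ndarray, float, float]:
    """Symmetric sense-codon rate matrix: synonymous single-base changes at
    rate 1, nonsynonymous at rate omega, stop codons excluded.

    Returns (Q, mean synonymous degree, mean NG86 synonymous sites)."""
    m = len(SENSE_CODONS)
    q = np.zeros((m, m))
    syn_degree = np.zeros(m)
    for i, a in enumerate(SENSE_CODONS):
        aa_a = translate_codon(a)
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = sum(x != y for x, y in zip(a, b))
            if diff != 1:
                continue
            if translate_codon(b) == aa_a:
                q[i, j] = 1.0
                syn_degree[i] += 1.0
            else:
                q[i, j] = omega
    np.fill_diagonal(q, -q.sum(axis=1))
    return q, float(syn_degree.mean()), float(_S_FRAC.mean())


def simulate_codon_pair(cfg: CodonSimConfig) -> tuple[str, str]:
    """Two coding sequences diverged from a common ancestor.

    Each codon evolves independently under a continuous-time Markov process
    on the 61 sense codons (uniform ancestral codons — the stationary
    distribution of the symmetric rate matrix), with the total branch length
    scaled so the expected number of synonymous substitutions per NG86
    synonymous site equals ``target_dS``.  Stop codons are never created.
    """
    rng = np.random.default_rng(cfg.seed)
    anc = rng.integers(0, len(SENSE_CODONS), size=cfg.n_codons)
    if cfg.target_dS == 0:
        seq = "".join(SENSE_CODONS[i] for i in anc)
        return seq, seq
    q, mean_syn_degree, mean_syn_sites = _codon_rate_matrix(cfg.omega)
    t_total = cfg.target_dS * mean_syn_sites / mean_syn_degree
    p_half = expm(q * (t_total / 2.0))
    p_half = np.clip(p_half, 0.0, None)
    p_half /= p_half.sum(axis=1, keepdims=True)

    def _evolve(states: np.ndarray) -> np.ndarray:
        u = rng.random(len(states))
        cdf = np.cumsum(p_half[states], axis=1)
        return (u[:, None] > cdf).sum(axis=1)

    d1, d2 = _evolve(anc), _evolve(anc)
    seq1 = "".join(SENSE_CODONS[i] for i in d1)
    seq2 = "".join(SENSE_CODONS[i] for i in d2)
    return seq1, seq2


# ---------------------------------------------------------------------------
# Repeat tracks

DEFAULT_CLASS_DENSITY = {
    "LTR/Ty3": 0.08,
    "LTR/Ty1": 0.05,
    "DNA/Helitron": 0.03,
    "DNA/hAT": 0.02,
}


def simulate_repeat_track(
    genome_lengths: dict[str, int],
    s_locus: tuple[str, int, int],
    enriched_class: str = "LTR/Ty3",
    fold: float = 4.0,
    class_density: dict[str, float] | None = None,
    element_bp: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """BED-style repeat annotations with one class enriched in the supergene.

    Elements of length ``element_bp`` occupy non-overlapping slots, so the
    per-class covered proportion is ≈ its density (× ``fold`` for the
    enriched class inside the region) without union shrinkage.
    """
    if fold < 0:
        raise ValueError("fold must be non-negative")
    density = dict(class_density or DEFAULT_CLASS_DENSITY)
    if enriched_class not in density:
        density[enriched_class] = 0.05
    if fold * density[enriched_class] > 1 or sum(density.values()) > 1:
        raise ValueError("repeat proportions exceed 1")
    rng = np.random.default_rng(seed)
    c_reg, reg_s, reg_e = s_locus
    rows = []
    for contig, length in genome_lengths.items():
        spans = []
        if contig == c_reg:
            spans = [(0, reg_s, False), (reg_s, reg_e, True), (reg_e, length, False)]
        else:
            spans = [(0, length, False)]
        for span_s, span_e, in_region in spans:
            n_slots = (span_e - span_s) // element_bp
            if n_slots <= 0:
                continue
            for klass, dens in density.items():
                d = dens * (fold if (in_region and klass == enriched_class) else 1.0)
                k = int(round(d * n_slots))
                if k == 0:
                    continue
                slots = rng.choice(n_slots, size=min(k, n_slots), replace=False)
                for sl in np.sort(slots):
                    start = span_s + int(sl) * element_bp
                    rows.append((contig, start, start + element_bp, klass))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Floral measurements


@dataclass(frozen=True)
class PhenoSimConfig:
    """Morph × treatment style-length experiment.

    Defaults: S-morph styles at 4.0 mm vs L-morph 7.0 mm, a hormone effect
    of 0.82 mm confined to the S-morph, residual SD 0.5 mm and 12
    flowers per design cell — a study-sized floral experiment.
    """

    baseline_S: float = 4.0
    baseline_L: float = 7.0
    effect_S: float = 0.82
    effect_L: float = 0.0
    sd: float = 0.5
    n_per_cell: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("residual sd must be positive")
        if self.n_per_cell < 2:
            raise ValueError("need at least 2 observations per cell")


def simulate_floral_measurements(
    cfg: PhenoSimConfig, organ: str = "style"
) -> pd.DataFrame:
    """Tidy measurement rows: length = baseline(morph) + effect(morph)·I[eBL] + noise."""
    rng = np.random.default_rng(cfg.seed)
    baselines = {"S": cfg.baseline_S, "L": cfg.baseline_L}
    effects = {"S": cfg.effect_S, "L": cfg.effect_L}
    rows = []
    for morph in ("S", "L"):
        for treatment in ("control", "eBL"):
            mu = baselines[morph] + effects[morph] * (treatment == "eBL")
            vals = mu + rng.normal(0.0, cfg.sd, size=cfg.n_per_cell)
            for i, v in enumerate(vals):
                rows.append(
                    (f"{morph}{i+1:02d}", morph, treatment, organ, "NA", float(v))
                )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "morph", "treatment", "organ", "section", "length"],
    )


@dataclass(frozen=True)
class CellLengthSimConfig:
    """Style epidermal cell-length experiment (μm), by style section.

    The hormone effect on mean cell length (default 12.6 μm, S-morph only)
    acts additively on the flower-section mean; replicate cells within a
    section scatter around that mean.
    """

    baseline_S: float = 90.0
    baseline_L: float = 105.0
    section_factors: tuple[tuple[str, float], ...] = (
        ("bottom", 1.15),
        ("middle", 1.0),
        ("top", 0.85),
    )
    effect_S: float = 12.6
    effect_L: float = 0.0
    flower_sd: float = 8.0
    cell_sd: float = 12.0
    n_flowers_per_cell: int = 7
    n_cells_per_section: int = 10
    seed: int = 0


def simulate_cell_measurements(cfg: CellLengthSimConfig) -> pd.DataFrame:
    """Raw per-cell length rows (organ='cell'), 10 cells per flower section."""
    rng = np.random.default_rng(cfg.seed)
    baselines = {"S": cfg.baseline_S, "L": cfg.baseline_L}
    effects = {"S": cfg.effect_S, "L": cfg.effect_L}
    rows = []
    for morph in ("S", "L"):
        for treatment in ("control", "eBL"):
            for f in range(cfg.n_flowers_per_cell):
                fid = f"{morph}_{treatment}_{f+1:02d}"
                for section, sf in cfg.section_factors:
                    mu = (
                        baselines[morph] * sf
                        + effects[morph] * (treatment == "eBL")
                        + rng.normal(0.0, cfg.flower_sd)
                    )
                    cells = np.maximum(
                        mu + rng.normal(0.0, cfg.cell_sd, size=cfg.n_cells_per_section),
                        1.0,
                    )
                    for v in cells:
                        rows.append(
                            (fid, morph, treatment, "cell", section, float(v))
                        )
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "morph", "treatment", "organ", "section", "length"],
    )
    return df
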
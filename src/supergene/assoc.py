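"""Morph–genotype association scan.

GWAS stage for a dominant supergene: sites with missing calls or low minor
allele frequency are removed, variants in strong local LD are pruned, and
each remaining SNP is tested for association between floral morph and
carrier status of the minor allele (dominance coding) with a two-sided
Fisher exact test, followed by Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeTable, SampleSheet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssocConfig:
    """Filters and thresholds for the association scan.

    max_missing defaults to 0: any site with missing data is dropped before
    testing, so the 2×2 tables have complete margins.
    """

    maf_min: float = 0.05
    max_missing: float = 0.0
    prune_window_bp: int = 50_000
    prune_r2: float = 0.2
    fdr_alpha: float = 0.05

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0 < self.prune_r2 < 1):
            raise ValueError("prune_r2 must lie in (0, 1)")


def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-site minor allele frequency computed on called alleles only."""
    d = np.asarray(dosages, dtype=float)
    called = d != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_alleles > 0, np.where(called, d, 0).sum(axis=0) / n_alleles, np.nan)
    return np.minimum(alt_freq, 1.0 - alt_freq)


def filter_for_association(gt: GenotypeTable, cfg: AssocConfig = AssocConfig()) -> GenotypeTable:
    """Drop sites with missing data beyond ``max_missing`` and MAF below
    ``maf_min`` (monomorphic sites go with them)."""
    if gt.n_variants == 0:
        return gt
    missing_frac = (gt.dosages == MISSING).mean(axis=0)
    maf = minor_allele_frequency(gt.dosages)
    keep = (missing_frac <= cfg.max_missing) & (maf >= cfg.maf_min) & (maf > 0)
    if not keep.any():
        warnings.warn("all sites removed by association filters", stacklevel=2)
    return gt.take_variants(np.flatnonzero(keep))


def _dosage_r2_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """r² between all column pairs of two dosage matrices (no missing)."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    sa = np.sqrt((az**2).sum(axis=0))
    sb = np.sqrt((bz**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az.T @ bz) / np.outer(sa, sb)
    return r**2


def ld_prune(
    gt: GenotypeTable, window_bp: int = 50_000, r2_max: float = 0.2
) -> GenotypeTable:
    """Prune variants so no pair closer than ``window_bp`` has dosage-r² > ``r2_max``.

    Conflicting pairs are resolved greedily from the highest r² down,
    dropping the member with lower MAF (ties: the downstream variant).  The
    guarantee is on the output — every pair of surviving variants within
    ``window_bp`` of each other has r² ≤ ``r2_max`` — independent of how the
    contig is chunked.
    """
    if gt.n_variants == 0:
        return gt
    maf = minor_allele_frequency(gt.dosages)
    keep = np.ones(gt.n_variants, dtype=bool)
    d = gt.dosages.astype(float)
    d[gt.dosages == MISSING] = np.nan

    for contig, sub in gt.variants.groupby("contig", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        pairs = []  # (r2, global_i, global_j)
        for k in range(len(idx)):
            # variants within window_bp downstream of variant k
            hi = np.searchsorted(pos, pos[k] + window_bp, side="left")
            for m in range(k + 1, hi):
                x, y = d[:, idx[k]], d[:, idx[m]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                    continue
                r2 = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
                if r2 > r2_max:
                    pairs.append((r2, idx[k], idx[m]))
        # highest-r² first; deterministic tie-break on positions
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        for _, i, j in pairs:
            if not (keep[i] and keep[j]):
                continue
            if maf[i] < maf[j]:
                keep[i] = False
            elif maf[j] < maf[i]:
                keep[j] = False
            else:  # equal MAF: drop the larger position
                keep[max(i, j)] = False
    return gt.take_variants(np.flatnonzero(keep))


def dominant_fisher_test(
    dosages_at_snp: np.ndarray, morphs: np.ndarray
) -> tuple[np.ndarray, float]:
    """Two-sided Fisher exact test of carrier status × morph at one SNP.

    Samples are dichotomized as carriers of the minor allele (dosage ≥ 1
    copy); minor is defined on the analyzed cohort, ties at frequency 0.5
    treating the alt allele as minor.  Returns the 2×2 table
    [[carrier_S, carrier_L], [noncarrier_S, noncarrier_L]] and the p-value
    under the classical sum-of-extreme-tables rule.
    """
    d = np.asarray(dosages_at_snp)
    morphs = np.asarray(morphs)
    if (d == MISSING).any():
        raise ValueError("missing dosages not allowed in the dominance test")
    levels = set(morphs.tolist())
    if levels != {"S", "L"}:
        raise ValueError(f"need both morphs present; got {sorted(levels)}")
    alt_freq = d.sum() / (2.0 * len(d))
    carrier = (d >= 1) if alt_freq <= 0.5 else (d <= 1)
    s = morphs == "S"
    table = np.array(
        [
            [int((carrier & s).sum()), int((carrier & ~s).sum())],
            [int((~carrier & s).sum()), int((~carrier & ~s).sum())],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(min(p, 1.0))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class AssocResult:
    """Per-SNP association scan output."""

    table: pd.DataFrame  # contig,pos,carrier_S,carrier_L,noncarrier_S,noncarrier_L,p_raw,q_fdr,significant
    fdr_alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def hits_per_contig(self) -> dict[str, int]:
        sig = self.significant
        return sig.groupby("contig").size().to_dict()


def association_scan(
    gt: GenotypeTable, samples: SampleSheet, cfg: AssocConfig = AssocConfig()
) -> AssocResult:
    """Dominance-model Fisher exact scan with BH-FDR.

    ``gt`` is expected to be filtered (no missing calls) and LD-pruned.
    """
    if tuple(samples.sample_ids) != tuple(gt.sample_ids):
        raise ValueError("sample sheet does not match genotype table")
    morphs = samples.morph_array
    rows = []
    for j in range(gt.n_variants):
        t2, p = dominant_fisher_test(gt.dosages[:, j], morphs)
        rows.append(
            (
                gt.variants["contig"].iat[j],
                gt.variants["pos"].iat[j],
                t2[0, 0],
                t2[0, 1],
                t2[1, 0],
                t2[1, 1],
                p,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "carrier_S",
            "carrier_L",
            "noncarrier_S",
            "noncarrier_L",
            "p_raw",
        ],
    )
    if len(df):
        df["q_fdr"] = bh_fdr(df["p_raw"].to_numpy())
        df["significant"] = df["q_fdr"] < cfg.fdr_alpha
    else:
        df["q_fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return AssocResult(table=df, fdr_alpha=cfg.fdr_alpha)


def contig_hit_summary(
    hits: AssocResult | dict[str, int], contig_to_chrom: dict[str, str]
) -> pd.DataFrame:
    """Aggregate significant-SNP counts to chromosomes.

    Returns one row per chromosome with the hit count and the percentage of
    all hits (1 decimal).  Contigs absent from the map are pooled as
    "unplaced" and stay in the denominator.
    """
    counts = hits.hits_per_contig() if isinstance(hits, AssocResult) else dict(hits)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no significant SNPs to summarize")
    per_chrom: dict[str, int] = {}
    for contig, n in counts.items():
        chrom = contig_to_chrom.get(contig, "unplaced")
        per_chrom[chrom] = per_chrom.get(chrom, 0) + n
    out = pd.DataFrame(
        {
            "chromosome": list(per_chrom),
            "n_hits": list(per_chrom.values()),
        }
    ).sort_values("n_hits", ascending=False, ignore_index=True)
    out["pct_of_hits"] = (100.0 * out["n_hits"] / total).round(1)
    return out
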
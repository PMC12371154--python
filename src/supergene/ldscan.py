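"""Linkage-disequilibrium structure: window-pair median r² and contrasts.

Recombination suppression around a supergene shows up as elevated LD over
megabase scales.  r² here is the squared Pearson correlation of genotype
dosages (composite LD) — the data are unphased, so this is the practical
choice, and it can differ slightly from haplotype-based r².  For a contig,
SNPs are grouped into fixed windows (default 100 kb) and each cell (i, j)
of the LD matrix is the median r² over SNP pairs drawn one from window i
and one from window j; the target-vs-control contrast pools the non-empty
cell medians of two such matrices into a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeTable

#: Above this product of group sizes the Wilcoxon switches to the normal
#: approximation with tie and continuity corrections.
WILCOXON_EXACT_LIMIT = 10_000


def dosage_r2(snp_a, snp_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls are dropped pairwise; returns NaN (undefined) when fewer
    than two complete pairs remain or either vector is constant.
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


@dataclass
class LDMatrix:
    """Symmetric matrix of median window-pair r² on one contig."""

    contig: str
    windows: pd.DataFrame  # start, end
    med_r2: np.ndarray  # windows × windows, NaN where no SNP pair
    snp_counts: np.ndarray

    def pooled_cell_medians(self) -> np.ndarray:
        """Non-empty cell medians from the upper triangle (incl. diagonal)."""
        iu = np.triu_indices(len(self.windows))
        vals = self.med_r2[iu]
        return vals[~np.isnan(vals)]


def window_ld_matrix(
    gt: GenotypeTable,
    contig: str,
    window_bp: int = 100_000,
    max_pairs_per_cell: int = 10_000,
    seed: int | None = None,
) -> LDMatrix:
    """Median r² between all pairs of fixed windows along one contig.

    Cells with more than ``max_pairs_per_cell`` SNP pairs are estimated from
    a seeded random subsample (medians are robust to this); cells with no
    SNP pair are NaN ("empty", the white areas of an LD heatmap).
    """
    on = gt.variants["contig"] == contig
    if not on.any():
        raise ValueError(f"contig {contig!r} not present in genotype table")
    sub = gt.variants[on]
    pos = sub["start"].to_numpy()
    dos = gt.dosages[:, on.to_numpy()].astype(float)
    dos[dos == MISSING] = np.nan

    n_win = int(pos.max() // window_bp) + 1
    windows = pd.DataFrame(
        {
            "start": np.arange(n_win) * window_bp,
            "end": (np.arange(n_win) + 1) * window_bp,
        }
    )
    win_of = (pos // window_bp).astype(int)
    members = [np.flatnonzero(win_of == w) for w in range(n_win)]
    snp_counts = np.array([len(m) for m in members])

    rng = np.random.default_rng(seed)
    has_missing = bool(np.isnan(dos).any())
    if not has_missing:
        # Standardize columns once so pair r is a dot product; constant
        # columns become NaN and drop out of the medians.
        z = dos - dos.mean(axis=0)
        norm = np.sqrt((z**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(norm > 0, z / norm, np.nan)

    med = np.full((n_win, n_win), np.nan)
    for i in range(n_win):
        if not len(members[i]):
            continue
        for j in range(i, n_win):
            if not len(members[j]):
                continue
            ai, aj = members[i], members[j]
            if i == j:
                if len(ai) < 2:
                    continue
                pairs = np.array(np.triu_indices(len(ai), k=1)).T
            else:
                pairs = np.array(
                    np.meshgrid(np.arange(len(ai)), np.arange(len(aj)))
                ).reshape(2, -1).T
            if len(pairs) > max_pairs_per_cell:
                take = rng.choice(len(pairs), size=max_pairs_per_cell, replace=False)
                pairs = pairs[take]
            if has_missing:
                vals = np.array(
                    [dosage_r2(dos[:, ai[a]], dos[:, aj[b]]) for a, b in pairs]
                )
            else:
                r = np.einsum(
                    "sp,sp->p", z[:, ai[pairs[:, 0]]], z[:, aj[pairs[:, 1]]]
                )
                vals = np.minimum(r * r, 1.0)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                med[i, j] = med[j, i] = float(np.median(vals))
    return LDMatrix(contig=contig, windows=windows, med_r2=med, snp_counts=snp_counts)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test (two-sided) for two samples.

    Returns the U statistic for the first sample and its p-value; exact
    null when n1·n2 ≤ 10 000 with no ties, otherwise the normal
    approximation with midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values not allowed")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (x.size * y.size <= WILCOXON_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class LDContrast:
    """Target-vs-control contig LD comparison."""

    U: float
    p: float
    median_target: float
    median_control: float
    n_target_cells: int
    n_control_cells: int


def compare_contig_ld(target: LDMatrix, control: LDMatrix) -> LDContrast:
    """Compare pooled window-pair median r² between two contigs.

    Both matrices must be computed with the same window size; the test is a
    two-sided Wilcoxon rank-sum on the pooled non-empty cell medians.
    """
    tv = target.pooled_cell_medians()
    cv = control.pooled_cell_medians()
    if tv.size == 0 or cv.size == 0:
        raise ValueError("an LD matrix has no non-empty cells")
    u, p = wilcoxon_rank_sum(tv, cv)
    return LDContrast(
        U=u,
        p=p,
        median_target=float(np.median(tv)),
        median_control=float(np.median(cv)),
        n_target_cells=int(tv.size),
        n_control_cells=int(cv.size),
    )
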
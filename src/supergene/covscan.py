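"""Windowed normalized-coverage presence–absence scan between floral morphs.

A hemizygous dominant haplotype shows up as a genomic segment with ~zero
short-read coverage in every L-morph individual but normal coverage in
S-morph individuals.  The scan tiles each contig into fixed windows
(default 300 kb), normalizes per-sample read counts by total sample read
count, and tests each window for a coverage difference between morphs with
a two-sample Fisher–Pitman permutation test (statistic: absolute difference
of group means, labels permuted).  Window p-values are Bonferroni-corrected
genome-wide and significant windows are classified as S-hemizygous
(L-morph coverage ≈ 0), recessive-specific (S-morph at about half the
L-morph level) or other, then merged into contiguous regions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleSheet

logger = logging.getLogger(__name__)

#: Exact label enumeration is used instead of Monte Carlo below this count.
EXACT_ENUMERATION_LIMIT = 100_000


def tile_windows(
    contig_lengths: dict[str, int], window_bp: int = 300_000
) -> pd.DataFrame:
    """Tile contigs into half-open windows [0,w), [w,2w), ...

    A terminal partial window shorter than half the nominal size is kept but
    flagged (``partial=True``) and excluded from testing, to avoid
    length-confounded coverage.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for contig {contig}")
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            rows.append((contig, start, end, (end - start) < 0.5 * window_bp))
            start = end
    return pd.DataFrame(rows, columns=["contig", "start", "end", "partial"])


def normalize_depths(
    counts: np.ndarray, total_reads: np.ndarray, scale: float = 1e6
) -> np.ndarray:
    """Per-sample library-size normalization: counts / total_reads × scale."""
    counts = np.asarray(counts, dtype=float)
    total = np.asarray(total_reads, dtype=float)
    if np.any(total <= 0):
        bad = np.flatnonzero(total <= 0)
        raise ValueError(f"non-positive total read count for sample index {bad.tolist()}")
    return counts / total[:, None] * scale


@dataclass
class WindowDepthTable:
    """Per-sample raw and normalized read counts over genomic tiles."""

    windows: pd.DataFrame  # contig, start, end, partial
    counts: np.ndarray  # samples × windows
    total_reads: np.ndarray  # per sample
    sample_ids: tuple[str, ...]
    scale: float = 1e6
    norm: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.windows)):
            raise ValueError("counts matrix must be samples × windows")
        self.norm = normalize_depths(self.counts, self.total_reads, self.scale)

    @classmethod
    def from_long_table(cls, df: pd.DataFrame, scale: float = 1e6) -> "WindowDepthTable":
        """Build from a long table with columns contig,start,end,sample,count."""
        wide = df.pivot_table(
            index="sample", columns=["contig", "start", "end"], values="count"
        )
        windows = pd.DataFrame(
            [(c, s, e) for c, s, e in wide.columns], columns=["contig", "start", "end"]
        )
        span = windows["end"] - windows["start"]
        windows["partial"] = span < 0.5 * span.max()
        counts = wide.to_numpy(dtype=float)
        return cls(
            windows=windows,
            counts=counts,
            total_reads=counts.sum(axis=1),
            sample_ids=tuple(wide.index),
            scale=scale,
        )


def _perm_stat_null(
    data: np.ndarray, n_x: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo null |mean_x − mean_y| for one vector under label permutation."""
    n = len(data)
    total = data.sum()
    out = np.empty(n_perm)
    chunk = 200_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        take = np.argpartition(keys, n_x - 1, axis=1)[:, :n_x]
        sx = data[take].sum(axis=1)
        out[done : done + m] = np.abs(sx / n_x - (total - sx) / (n - n_x))
        done += m
    return out


def fisher_pitman_p(
    x_group,
    y_group,
    n_perm: int = 1_000_000,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Two-sample Fisher–Pitman permutation p-value (two-sided).

    Statistic is |mean(x) − mean(y)|.  When the number of label assignments
    C(n, n_x) is at most 100 000 the null is enumerated exactly; otherwise
    the Monte-Carlo add-one estimator (1 + #{|T*| ≥ |T|}) / (1 + n_perm)
    is used, which can never report zero.  ``method`` forces one path
    ("exact" / "monte-carlo") instead of the automatic choice.
    """
    x = np.asarray(x_group, dtype=float)
    y = np.asarray(y_group, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if method not in ("auto", "exact", "monte-carlo"):
        raise ValueError("method must be 'auto', 'exact' or 'monte-carlo'")
    data = np.concatenate([x, y])
    n, n_x = len(data), len(x)
    obs = abs(x.mean() - y.mean())
    tol = 1e-12 * max(1.0, obs)

    use_exact = (
        method == "exact"
        or (method == "auto" and math.comb(n, n_x) <= EXACT_ENUMERATION_LIMIT)
    )
    if use_exact:
        total = data.sum()
        hits = 0
        count = 0
        for combo in itertools.combinations(range(n), n_x):
            sx = data[list(combo)].sum()
            t = abs(sx / n_x - (total - sx) / (n - n_x))
            hits += t >= obs - tol
            count += 1
        return hits / count
    rng = np.random.default_rng(seed)
    null = _perm_stat_null(data, n_x, n_perm, rng)
    return (1 + int((null >= obs - tol).sum())) / (1 + n_perm)


@dataclass
class CovScanResult:
    """Per-window permutation scan output with Bonferroni correction."""

    windows: pd.DataFrame  # contig,start,end,partial,median_S,median_L,p_raw,p_bonf,significant
    n_tested: int
    genome_median: float
    alpha: float


def hemizygosity_scan(
    depths: WindowDepthTable,
    samples: SampleSheet,
    n_perm: int = 1_000_000,
    alpha: float = 0.01,
    seed: int | None = None,
) -> CovScanResult:
    """Scan windows for morph-differential normalized coverage.

    Per window, a Fisher–Pitman permutation test compares normalized
    coverage between S- and L-morph samples; partial terminal windows are
    excluded from testing; Bonferroni correction runs across all tested
    windows genome-wide and a window is significant iff the corrected
    p ≤ ``alpha``.  In the Monte-Carlo regime one label-permutation matrix
    is shared by all windows of the scan, which leaves each window's
    p-value marginally valid and makes the scan fast.
    """
    if tuple(samples.sample_ids) != tuple(depths.sample_ids):
        raise ValueError("sample sheet does not match depth table")
    is_s = samples.is_morph("S")
    is_l = samples.is_morph("L")
    n_s, n_l = int(is_s.sum()), int(is_l.sum())
    if n_s < 2 or n_l < 2:
        raise ValueError("need at least 2 samples per morph")

    norm = depths.norm
    tested = ~depths.windows["partial"].to_numpy()
    n_tested = int(tested.sum())
    n = n_s + n_l
    exact = math.comb(n, n_s) <= EXACT_ENUMERATION_LIMIT
    floor = (2.0 / math.comb(n, n_s)) if exact else 1.0 / (1 + n_perm)
    if n_tested and floor > alpha / n_tested:
        logger.warning(
            "permutation p floor %.3g exceeds Bonferroni threshold %.3g: "
            "no window can reach significance at this sample size",
            floor,
            alpha / n_tested,
        )

    # Reorder samples as [S..., L...] so group sums come from index blocks.
    order = np.concatenate([np.flatnonzero(is_s), np.flatnonzero(is_l)])
    dat = norm[order][:, tested]  # n × W
    obs = np.abs(dat[:n_s].mean(axis=0) - dat[n_s:].mean(axis=0))
    tol = 1e-12 * np.maximum(1.0, obs)

    totals = dat.sum(axis=0)  # per window
    ge = np.zeros(dat.shape[1], dtype=np.int64)

    def _accumulate(sel: np.ndarray) -> None:
        sx = sel @ dat  # P × W group-S sums under permutation
        t_null = np.abs(sx / n_s - (totals[None, :] - sx) / n_l)
        np.add(ge, (t_null >= obs[None, :] - tol[None, :]).sum(axis=0), out=ge)

    if exact:
        combos = np.array(
            list(itertools.combinations(range(n), n_s)), dtype=np.intp
        )  # C × n_s
        sel = np.zeros((len(combos), n), dtype=float)
        sel[np.arange(len(combos))[:, None], combos] = 1.0
        _accumulate(sel)
        p_raw_tested = ge / len(combos)
    else:
        rng = np.random.default_rng(seed)
        chunk = 100_000
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            keys = rng.random((m, n))
            take = np.argpartition(keys, n_s - 1, axis=1)[:, :n_s]
            sel = np.zeros((m, n), dtype=float)
            sel[np.arange(m)[:, None], take] = 1.0
            _accumulate(sel)
            done += m
        p_raw_tested = (1 + ge) / (1 + n_perm)

    p_raw = np.full(len(depths.windows), np.nan)
    p_raw[tested] = p_raw_tested
    p_bonf = np.minimum(1.0, p_raw * max(n_tested, 1))

    win = depths.windows.copy()
    win["median_S"] = np.median(norm[is_s], axis=0)
    win["median_L"] = np.median(norm[is_l], axis=0)
    win["p_raw"] = p_raw
    win["p_bonf"] = p_bonf
    win["significant"] = tested & (p_bonf <= alpha)
    genome_median = float(np.median(norm[:, tested])) if n_tested else float("nan")
    return CovScanResult(
        windows=win, n_tested=n_tested, genome_median=genome_median, alpha=alpha
    )


REGION_CLASSES = ("S_hemizygous", "recessive_specific", "other")


def classify_s_regions(
    result: CovScanResult,
    eps_frac: float = 0.1,
    half_lo: float = 0.35,
    half_hi: float = 0.65,
) -> pd.DataFrame:
    """Classify significant windows and merge adjacent same-class windows.

    A significant window is S_hemizygous when the L-morph median coverage is
    below ``eps_frac`` of the genome-wide median while the S-morph median is
    at least half of it; recessive_specific when the S/L median ratio falls
    in [half_lo, half_hi] (one S copy vs two L copies); otherwise other.
    Returns merged regions (contig, start, end, region_class, n_windows).
    """
    if not np.isfinite(result.genome_median) or result.genome_median == 0:
        raise ValueError("genome-wide median coverage is zero or undefined")
    gm = result.genome_median
    sig = result.windows[result.windows["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["contig", "start", "end", "region_class", "n_windows"]
        )

    def _klass(row):
        med_s, med_l = row["median_S"], row["median_L"]
        if med_l < eps_frac * gm and med_s >= 0.5 * gm:
            return "S_hemizygous"
        if med_l > 0 and half_lo <= med_s / med_l <= half_hi:
            return "recessive_specific"
        return "other"

    sig["region_class"] = sig.apply(_klass, axis=1)
    sig = sig.sort_values(["contig", "start"])
    regions = []
    cur = None
    for _, row in sig.iterrows():
        if (
            cur is not None
            and row["contig"] == cur["contig"]
            and row["region_class"] == cur["region_class"]
            and row["start"] == cur["end"]
        ):
            cur["end"] = row["end"]
            cur["n_windows"] += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "contig": row["contig"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "region_class": row["region_class"],
                "n_windows": 1,
            }
    regions.append(cur)
    return pd.DataFrame(regions)
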
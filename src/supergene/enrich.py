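"""Repeat-class enrichment of a genomic region against the genome background.

Non-recombining supergene regions accumulate transposable elements.  For
each repeat class, the covered base pairs inside the region of interest are
compared with the genome-wide class fraction (the region itself excluded
from the background) using an exact two-sided binomial test; enrichment is
summarized as log2((x/n) / p0).  Treating base pairs as Bernoulli trials
ignores spatial autocorrelation of repeats — an optional element-count mode
(elements as trials) is exposed as a cruder but less autocorrelated
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Region:
    contig: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty or inverted region")

    @property
    def length(self) -> int:
        return self.end - self.start


def _merged_coverage(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp covered by the union of intervals."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return int(total)


def _class_bp_in_span(
    track: pd.DataFrame, contig: str | None, start: int, end: int, invert: bool = False
) -> dict[str, int]:
    """Per-class union bp inside (or, with invert, outside) one span.

    ``track`` has columns contig, start, end, name (name = repeat class).
    """
    out: dict[str, int] = {}
    for klass, sub in track.groupby("name"):
        bp = 0
        for c, csub in sub.groupby("contig"):
            s = csub["start"].to_numpy().astype(np.int64)
            e = csub["end"].to_numpy().astype(np.int64)
            if c == contig:
                cs = np.clip(s, start, end)
                ce = np.clip(e, start, end)
                inside = _merged_coverage(cs[cs < ce], ce[cs < ce])
                if invert:
                    bp += _merged_coverage(s, e) - inside
                else:
                    bp += inside
            elif invert:
                bp += _merged_coverage(s, e)
        out[klass] = bp
    return out


def class_composition(track: pd.DataFrame, region: Region) -> pd.DataFrame:
    """Per-class covered bp and fraction of the region.

    Overlapping intervals within a class are merged (union semantics);
    classes may overlap each other, so fractions need not sum to 1.
    Elements straddling the region boundary contribute their clipped part.
    """
    bp = _class_bp_in_span(track, region.contig, region.start, region.end)
    df = pd.DataFrame(
        {"repeat_class": list(bp), "bp": list(bp.values())}
    ).sort_values("repeat_class", ignore_index=True)
    df["fraction"] = df["bp"] / region.length
    return df


def binomial_enrichment_scan(
    track: pd.DataFrame,
    region: Region,
    genome_lengths: dict[str, int],
    mode: str = "bp",
) -> pd.DataFrame:
    """Per-class enrichment of the region vs the rest of the genome.

    In ``bp`` mode each base pair of the region is a Bernoulli trial with
    null success probability p0 = class fraction of the background (genome
    minus the region).  In ``elements`` mode each annotated element of a
    class is a trial, success = element midpoint inside the region, with
    p0 = region length / genome length.  p-values are exact two-sided
    binomial (sum of point probabilities ≤ observed); log2 fold enrichment
    is log2(observed rate / p0) and is +/-inf at zero rates.
    """
    if region.contig not in genome_lengths:
        raise ValueError(f"region contig {region.contig!r} not in genome lengths")
    if region.end > genome_lengths[region.contig]:
        raise ValueError("region extends past its contig")
    genome_len = int(sum(genome_lengths.values()))
    rows = []
    if mode == "bp":
        in_bp = _class_bp_in_span(track, region.contig, region.start, region.end)
        out_bp = _class_bp_in_span(
            track, region.contig, region.start, region.end, invert=True
        )
        n = region.length
        bg_len = genome_len - n
        for klass in sorted(in_bp):
            x = in_bp[klass]
            p0 = out_bp[klass] / bg_len
            if x == 0 and p0 == 0:
                continue
            rows.append((klass, x, n, x / n, p0))
    elif mode == "elements":
        p0 = region.length / genome_len
        mid = (track["start"] + track["end"]) // 2
        in_region = (
            (track["contig"] == region.contig)
            & (mid >= region.start)
            & (mid < region.end)
        )
        for klass, sub in track.groupby("name"):
            n = len(sub)
            x = int(in_region[sub.index].sum())
            rows.append((klass, x, n, x / n, p0))
    else:
        raise ValueError("mode must be 'bp' or 'elements'")

    recs = []
    for klass, x, n, rate, p0 in rows:
        if p0 == 0:
            log2fe = np.inf
            p = 0.0 if x > 0 else 1.0
        elif rate == 0:
            log2fe = -np.inf
            p = stats.binomtest(int(x), int(n), p0).pvalue
        else:
            log2fe = float(np.log2(rate / p0))
            p = stats.binomtest(int(x), int(n), p0).pvalue
        recs.append((klass, int(x), int(n), rate, p0, log2fe, float(p)))
    df = pd.DataFrame(
        recs,
        columns=["repeat_class", "x", "n", "rate", "p0", "log2_fold_enrichment", "p"],
    )
    if len(df):
        df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
    else:
        df["p_bonferroni"] = pd.Series(dtype=float)
    return df.sort_values("log2_fold_enrichment", ascending=False, ignore_index=True)
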
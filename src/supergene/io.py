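"""Readers, writers and variant-level filters.

The pipeline's genomic inputs travel as the field's standard text formats:
VCF for genotypes, BED for intervals (windows, repeats, masks), FASTA for
coding sequences, and a headered TSV sample sheet mapping each individual to
its floral morph (S or L) and source population.

Internally all interval arithmetic is 0-based half-open; VCF positions are
converted on ingest and kept alongside the original 1-based coordinate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype dosage.
MISSING = -1

MORPHS = ("S", "L")


class SampleSheetError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSheet:
    """Sample → floral morph (S/L) and population assignment.

    Sample ids must be unique and every sample used in a scan must carry a
    non-missing morph label.
    """

    sample_ids: tuple[str, ...]
    morph: tuple[str, ...]
    population: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SampleSheetError("duplicate sample ids in sample sheet")
        if len(self.morph) != len(self.sample_ids) or len(self.population) != len(
            self.sample_ids
        ):
            raise SampleSheetError("sample sheet columns have unequal lengths")
        bad = [m for m in self.morph if m not in MORPHS]
        if bad:
            raise SampleSheetError(f"morph labels must be one of {MORPHS}; got {bad}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def morph_array(self) -> np.ndarray:
        return np.asarray(self.morph)

    def is_morph(self, morph: str) -> np.ndarray:
        return self.morph_array == morph

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise SampleSheetError(f"samples not in sheet: {missing}")
        idx = [index[s] for s in wanted]
        return SampleSheet(
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.morph[i] for i in idx),
            tuple(self.population[i] for i in idx),
        )

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "morph", "population"}
        if not required.issubset(df.columns):
            raise SampleSheetError(
                f"sample sheet must have columns {sorted(required)}; got {list(df.columns)}"
            )
        return cls(
            tuple(df["sample_id"]), tuple(df["morph"]), tuple(df["population"])
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "morph": self.morph,
                "population": self.population,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeTable:
    """Samples × biallelic variants with dosage coding 0/1/2/missing.

    ``dosages`` is an int8 matrix (samples × variants); missing calls are
    :data:`MISSING`.  ``variants`` has columns contig, pos (1-based), start
    (0-based), ref, alt.  Optional per-call depth, per-site quality and
    ref/alt allele-depth pairs support the site and allele-balance filters.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: tuple[str, ...]
    call_depth: np.ndarray | None = None
    site_quality: np.ndarray | None = None
    allele_depths: np.ndarray | None = None  # samples × variants × 2 (ref, alt)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        v = self.variants
        if len(v) and not (
            v.groupby("contig", sort=False)["pos"].apply(
                lambda s: bool(s.is_monotonic_increasing)
            )
        ).all():
            raise ValueError("variant positions must be increasing within contig")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, idx) -> "GenotypeTable":
        """Subset to variant indices ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeTable(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
            sample_ids=self.sample_ids,
            call_depth=None if self.call_depth is None else self.call_depth[:, idx],
            site_quality=None
            if self.site_quality is None
            else np.asarray(self.site_quality)[idx],
            allele_depths=None
            if self.allele_depths is None
            else self.allele_depths[:, idx],
        )


@dataclass(frozen=True)
class FilterConfig:
    """Variant-call hard filters: depth, site quality, missingness, allele balance.

    ``min_called_frac`` keeps a site only when at least that fraction of
    genotypes is called; allele-balance bounds are a closed interval on the
    alt-read fraction of heterozygous calls.
    """

    min_depth: int = 5
    max_depth: int = 200
    min_called_frac: float = 0.9
    min_quality: float = 20.0
    ab_low: float = 0.2
    ab_high: float = 0.8

    def __post_init__(self):
        if not (0 <= self.ab_low < self.ab_high <= 1):
            raise ValueError("require 0 <= ab_low < ab_high <= 1")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if not (0 <= self.min_called_frac <= 1):
            raise ValueError("min_called_frac must lie in [0, 1]")


def read_vcf_genotypes(path, samples: SampleSheet) -> GenotypeTable:
    """Read biallelic SNP genotypes for ``samples`` from a VCF.

    Multiallelic records, indels and records with malformed genotypes are
    dropped (skipped records are counted in the log).  Dosage is the alt
    allele count; uncalled genotypes become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True, samples=list(samples.sample_ids))
    header_samples = list(vcf.samples)
    absent = [s for s in samples.sample_ids if s not in header_samples]
    if absent:
        raise SampleSheetError(f"samples missing from VCF header: {absent}")
    # cyvcf2 returns columns in VCF header order; map back to sheet order.
    order = [header_samples.index(s) for s in samples.sample_ids]

    rows, dos, depths, quals, ads = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
            continue
        try:
            gt = np.asarray(rec.gt_types)[order]
        except Exception:  # malformed GT
            n_skipped += 1
            continue
        d = np.where(gt == 3, MISSING, gt).astype(np.int8)
        rows.append((rec.CHROM, rec.POS, rec.POS - 1, ref, alt))
        dos.append(d)
        try:
            fmt_dp = rec.format("DP")
        except KeyError:
            fmt_dp = None
        depths.append(
            fmt_dp[order, 0].astype(float) if fmt_dp is not None else np.full(len(order), np.nan)
        )
        quals.append(rec.QUAL if rec.QUAL is not None else np.nan)
        try:
            fmt_ad = rec.format("AD")
        except KeyError:
            fmt_ad = None
        ads.append(
            fmt_ad[order, :2].astype(float)
            if fmt_ad is not None
            else np.full((len(order), 2), np.nan)
        )
    if n_skipped:
        logger.warning("skipped %d records with malformed genotypes", n_skipped)

    variants = pd.DataFrame(rows, columns=["contig", "pos", "start", "ref", "alt"])
    n = len(samples)
    return GenotypeTable(
        variants=variants,
        dosages=np.asarray(dos, dtype=np.int8).reshape(len(rows), n).T
        if rows
        else np.empty((n, 0), dtype=np.int8),
        sample_ids=samples.sample_ids,
        call_depth=np.asarray(depths).T if rows else np.empty((n, 0)),
        site_quality=np.asarray(quals, dtype=float),
        allele_depths=np.transpose(np.asarray(ads), (1, 0, 2))
        if rows
        else np.empty((n, 0, 2)),
    )


def apply_site_filters(
    gt: GenotypeTable,
    per_call_depth: np.ndarray | None = None,
    per_site_quality: np.ndarray | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> GenotypeTable:
    """Depth / quality / missingness hard filters.

    Calls with depth outside [min_depth, max_depth] are set missing; sites
    with quality below min_quality, or with a called fraction below
    ``min_called_frac`` after the depth step, are removed.  Surviving sites
    keep their order.
    """
    depth = per_call_depth if per_call_depth is not None else gt.call_depth
    qual = per_site_quality if per_site_quality is not None else gt.site_quality
    dosages = gt.dosages.copy()

    if depth is not None:
        depth = np.asarray(depth, dtype=float)
        if depth.shape != dosages.shape:
            raise ValueError("depth matrix shape does not match genotypes")
        with np.errstate(invalid="ignore"):
            bad_depth = (depth < cfg.min_depth) | (depth > cfg.max_depth)
        dosages[bad_depth & (dosages != MISSING)] = MISSING

    keep = np.ones(gt.n_variants, dtype=bool)
    if qual is not None:
        qual = np.asarray(qual, dtype=float)
        if qual.shape != (gt.n_variants,):
            raise ValueError("site quality length does not match variants")
        keep &= ~(qual < cfg.min_quality)  # NaN quality passes

    if gt.n_samples:
        called_frac = (dosages != MISSING).mean(axis=0)
        keep &= called_frac >= cfg.min_called_frac

    out = GenotypeTable(
        variants=gt.variants,
        dosages=dosages,
        sample_ids=gt.sample_ids,
        call_depth=gt.call_depth,
        site_quality=gt.site_quality,
        allele_depths=gt.allele_depths,
    )
    return out.take_variants(np.flatnonzero(keep))


def apply_allele_balance_filter(
    gt: GenotypeTable,
    allele_depths: np.ndarray | None = None,
    ab_low: float = 0.2,
    ab_high: float = 0.8,
) -> GenotypeTable:
    """Set heterozygous calls with alt-read fraction outside [ab_low, ab_high] missing.

    The fraction is alt_depth / (ref_depth + alt_depth); the bounds are a
    closed interval, so a fraction exactly at a bound passes.  Homozygous
    calls are untouched.
    """
    ad = allele_depths if allele_depths is not None else gt.allele_depths
    if ad is None:
        raise ValueError("allele depths required for the allele-balance filter")
    ad = np.asarray(ad, dtype=float)
    if ad.shape != (gt.n_samples, gt.n_variants, 2):
        raise ValueError("allele depth array must be samples × variants × 2")
    if np.nanmin(ad) < 0:
        raise ValueError("negative allele depths")

    dosages = gt.dosages.copy()
    het = dosages == 1
    total = ad[..., 0] + ad[..., 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, ad[..., 1] / total, np.nan)
    fail = het & ~np.isnan(frac) & ((frac < ab_low) | (frac > ab_high))
    dosages[fail] = MISSING
    return GenotypeTable(
        variants=gt.variants,
        dosages=dosages,
        sample_ids=gt.sample_ids,
        call_depth=gt.call_depth,
        site_quality=gt.site_quality,
        allele_depths=gt.allele_depths,
    )


def exclude_variants_in_bed(gt: GenotypeTable, bed: pd.DataFrame) -> GenotypeTable:
    """Drop variants falling inside any interval of a BED exclusion track
    (e.g. a repeat mask supplied upstream)."""
    keep = np.ones(gt.n_variants, dtype=bool)
    starts = gt.variants["start"].to_numpy()
    contigs = gt.variants["contig"].to_numpy()
    for contig, sub in bed.groupby("contig"):
        on = contigs == contig
        if not on.any():
            continue
        pos = starts[on]
        inside = np.zeros(pos.shape, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            inside |= (pos >= s) & (pos < e)
        keep[np.flatnonzero(on)[inside]] = False
    return gt.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# BED tracks

BED_COLUMNS = ["contig", "start", "end", "name"]


def read_bed_track(path) -> pd.DataFrame:
    """Read a BED3/BED4 track into a DataFrame (0-based half-open intervals)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 tab-separated columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=".")
    df.columns = BED_COLUMNS
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, vals.astype(np.int64)):
            raise ValueError(f"non-integer coordinates in BED column '{col}'")
        df[col] = vals.astype(np.int64)
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"empty or inverted interval {bad['contig']}:{bad['start']}-{bad['end']}"
        )
    df["name"] = df["name"].astype(str)
    return df.reset_index(drop=True)


def write_bed_track(df: pd.DataFrame, path) -> None:
    """Write (contig, start, end[, name]) intervals as BED; inverse of
    :func:`read_bed_track`."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA coding sequences


def read_fasta_cds(path) -> dict[str, str]:
    """Read coding sequences from FASTA as {id: uppercase sequence}.

    Gaps '-' and ambiguity codes are preserved; duplicate ids are an error;
    an empty file returns an empty dict with a warning.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
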
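"""Molecular evolution: Nei–Gojobori dN/dS, clock dating, LRT arithmetic.

The NG86 method counts, for every codon, the fraction of single-base changes
that are synonymous ("synonymous sites"), and, for every differing codon
pair, the synonymous/nonsynonymous split of the differences averaged over
all mutational pathways between the two codons.  Proportions of differences
per site are then corrected for multiple hits with the Jukes–Cantor formula

    d = -(3/4) * ln(1 - (4/3) * p).

Single-base changes that create a stop codon are excluded from site
denominators, and multi-step pathways passing through a stop codon are
excluded from the difference counts (codon pairs connected only through
stops are skipped entirely).  This matches the common MEGA-style NG86
convention and is the main source of possible small discrepancies with other
implementations.

Divergence times use the strict molecular clock t = dS / (2 mu) with mu in
substitutions per site per year.  Likelihood-ratio arithmetic for nested
branch models (statistic 2*dlnL against chi-square) is provided; the ML
fitting itself is out of scope — this module consumes log-likelihoods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

BASES = "TCAG"
#: All 64 codons in TCAG order.
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_STANDARD_CODE = {}


def _build_code() -> dict[str, str]:
    from Bio.Seq import Seq

    return {c: str(Seq(c).translate()) for c in CODONS}


_STANDARD_CODE = _build_code()
STOP_CODONS = tuple(c for c in CODONS if _STANDARD_CODE[c] == "*")
SENSE_CODONS = tuple(c for c in CODONS if _STANDARD_CODE[c] != "*")
_SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)


def translate_codon(codon: str) -> str:
    return _STANDARD_CODE[codon]


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts (s, n) of one codon.

    Per position, the synonymous fraction is (# synonymous single-base
    changes) / (# single-base changes not creating a stop); s is the sum
    over the three positions and n = 3 - s.
    """
    codon = codon.upper()
    if codon not in _SENSE_INDEX:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = _STANDARD_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            maa = _STANDARD_CODE[mutant]
            if maa == "*":
                continue
            valid += 1
            if maa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathway_counts(a: str, b: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) difference counts over all stop-free pathways
    from codon ``a`` to codon ``b``; None if every pathway crosses a stop."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff_pos):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _STANDARD_CODE[nxt] == "*":
                ok = False
                break
            if _STANDARD_CODE[nxt] == _STANDARD_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = float(np.mean([t[0] for t in totals]))
    nd = float(np.mean([t[1] for t in totals]))
    return sd, nd


def _build_tables():
    s_frac = np.array([ng86_site_counts(c)[0] for c in SENSE_CODONS])
    sd = np.zeros((N_SENSE, N_SENSE))
    nd = np.zeros((N_SENSE, N_SENSE))
    valid = np.ones((N_SENSE, N_SENSE), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if j < i:
                continue
            res = _pathway_counts(a, b)
            if res is None:
                valid[i, j] = valid[j, i] = False
            else:
                sd[i, j] = sd[j, i] = res[0]
                nd[i, j] = nd[j, i] = res[1]
    return s_frac, sd, nd, valid


_S_FRAC, _PAIR_SD, _PAIR_ND, _PAIR_VALID = _build_tables()


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN when saturated (p >= 3/4)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


@dataclass
class NGResult:
    """Pairwise NG86 estimates: fractional site/difference counts,
    proportions, JC-corrected distances and their ratio."""

    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # NaN when dS == 0 or either distance is saturated
    se_dS: float | None = None
    se_dN: float | None = None


def codon_indices(seq: str) -> np.ndarray:
    """Sense-codon index per codon of ``seq``; -1 for codons containing a
    gap or ambiguity, or that are stops."""
    if len(seq) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    seq = seq.upper()
    return np.array(
        [_SENSE_INDEX.get(seq[i : i + 3], -1) for i in range(0, len(seq), 3)],
        dtype=np.int64,
    )


def _pair_codon_indices(seq1: str, seq2: str) -> tuple[np.ndarray, np.ndarray]:
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be codon-aligned to equal length")
    ia, ib = codon_indices(seq1), codon_indices(seq2)
    # Pairwise deletion: drop codon columns unusable in either sequence, or
    # connected only through stop-codon intermediates.
    keep = (ia >= 0) & (ib >= 0)
    keep[keep] = _PAIR_VALID[ia[keep], ib[keep]]
    return ia[keep], ib[keep]


def _ng86_from_indices(ia: np.ndarray, ib: np.ndarray) -> NGResult:
    n_codons = len(ia)
    if n_codons == 0:
        raise ValueError("no analyzable codon columns")
    S = float((_S_FRAC[ia].sum() + _S_FRAC[ib].sum()) / 2.0)
    N = 3.0 * n_codons - S
    Sd = float(_PAIR_SD[ia, ib].sum())
    Nd = float(_PAIR_ND[ia, ib].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = dN / dS if dS and not np.isnan(dS) and not np.isnan(dN) else float("nan")
    return NGResult(n_codons, S, N, Sd, Nd, pS, pN, dS, dN, omega)


def ng86_pairwise(seq1: str, seq2: str) -> NGResult:
    """NG86 estimates for one codon-aligned sequence pair.

    Codon columns with a gap, ambiguity code or stop codon in either
    sequence are dropped pairwise; sites are averaged over the two
    sequences; multi-base codon differences average their pathway counts.
    """
    ia, ib = _pair_codon_indices(seq1, seq2)
    return _ng86_from_indices(ia, ib)


def ng86_bootstrap_se(
    seq1: str, seq2: str, B: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Bootstrap standard errors of (dS, dN) by resampling codon columns.

    Replicates in which a distance saturates are dropped and counted; if
    more than half saturate the SE is undefined (NaN) with a warning.
    """
    ia, ib = _pair_codon_indices(seq1, seq2)
    n = len(ia)
    if n < 10:
        raise ValueError("need at least 10 analyzable codons for the bootstrap")
    rng = np.random.default_rng(seed)
    ds_reps, dn_reps = [], []
    n_sat = 0
    for _ in range(B):
        take = rng.integers(0, n, size=n)
        r = _ng86_from_indices(ia[take], ib[take])
        if np.isnan(r.dS) or np.isnan(r.dN):
            n_sat += 1
            continue
        ds_reps.append(r.dS)
        dn_reps.append(r.dN)
    if n_sat > B / 2:
        warnings.warn(
            f"{n_sat}/{B} bootstrap replicates saturated; SE undefined", stacklevel=2
        )
        return float("nan"), float("nan")
    return float(np.std(ds_reps, ddof=1)), float(np.std(dn_reps, ddof=1))


# ---------------------------------------------------------------------------
# Molecular clock


@dataclass(frozen=True)
class ClockEstimate:
    """Strict-clock divergence time t = dS / (2 mu)."""

    dS: float
    mu: float
    t_years: float
    se_t_years: float | None = None

    @property
    def t_ma(self) -> float:
        """Time in millions of years, rounded to 1 decimal."""
        return round(self.t_years / 1e6, 1)

    @property
    def se_t_ma(self) -> float | None:
        return None if self.se_t_years is None else round(self.se_t_years / 1e6, 1)


def clock_time(dS: float, mu: float = 7e-9, se_dS: float | None = None) -> ClockEstimate:
    """Date a divergence from synonymous distance under a strict clock.

    ``mu`` is the per-site per-year mutation rate (default 7e-9, a standard
    plant spontaneous rate); the factor 2 accounts for the two diverging
    lineages.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if dS < 0:
        raise ValueError("dS must be non-negative")
    t = dS / (2.0 * mu)
    se = None if se_dS is None else se_dS / (2.0 * mu)
    return ClockEstimate(dS=dS, mu=mu, t_years=t, se_t_years=se)


# ---------------------------------------------------------------------------
# Likelihood-ratio arithmetic


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability (regularized incomplete gamma)."""
    if x < 0:
        raise ValueError("statistic must be non-negative")
    if int(df) != df or df < 1:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(x, df))


@dataclass(frozen=True)
class LRTInput:
    """Nested-model comparison: log-likelihoods (or a direct statistic) and
    the difference in free parameters."""

    df: int
    lnL_null: float | None = None
    lnL_alt: float | None = None
    statistic: float | None = None


def lrt_pvalue(inp: LRTInput) -> tuple[float, float]:
    """Likelihood-ratio test: statistic 2(lnL_alt - lnL_null) against
    chi-square with ``df`` degrees of freedom."""
    if inp.statistic is not None:
        stat = float(inp.statistic)
    else:
        if inp.lnL_null is None or inp.lnL_alt is None:
            raise ValueError("provide either both log-likelihoods or a statistic")
        if inp.lnL_alt < inp.lnL_null - 1e-8:
            raise ValueError(
                "alternative log-likelihood below null: models not nested or fit failed"
            )
        stat = 2.0 * (inp.lnL_alt - inp.lnL_null)
        stat = max(stat, 0.0)
    return stat, chisq_sf(stat, inp.df)


# ---------------------------------------------------------------------------
# Closest paralog by minimum synonymous divergence


def closest_paralog(
    focal_cds: str, candidate_cds: dict[str, str]
) -> tuple[str, NGResult]:
    """Pick the candidate with minimum pairwise NG86 dS to the focal CDS.

    Each candidate must be codon-aligned to the focal sequence pairwise.
    Ties on dS break by lower dN, then lexicographic id.  Candidates whose
    synonymous distance saturates are excluded; if all saturate, an error
    lists them.
    """
    if not candidate_cds:
        raise ValueError("empty candidate set")
    results = []
    saturated = []
    for name in sorted(candidate_cds):
        r = ng86_pairwise(focal_cds, candidate_cds[name])
        if np.isnan(r.dS):
            saturated.append(name)
            continue
        dn_key = r.dN if not np.isnan(r.dN) else np.inf
        results.append((r.dS, dn_key, name, r))
    if not results:
        raise ValueError(f"all candidate pairs saturated: {saturated}")
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    best = results[0]
    return best[2], best[3]
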
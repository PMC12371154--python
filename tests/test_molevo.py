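"""NG86 dN/dS, clock dating and LRT arithmetic, against code-table oracles."""

import itertools
import math

import numpy as np
import pytest

import supergene as sg
from supergene import molevo

# ---------------------------------------------------------------------------
# Independent oracle: recompute NG86 per codon pair by direct enumeration
# over the genetic code (no shared tables with the implementation).

GENETIC_CODE = {}
for b1 in "TCAG":
    for b2 in "TCAG":
        for b3 in "TCAG":
            GENETIC_CODE[b1 + b2 + b3] = None
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for codon, aa in zip(GENETIC_CODE, _AA):
    GENETIC_CODE[codon] = aa


def oracle_site_counts(codon):
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "TCAG":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] == "*":
                continue
            valid += 1
            syn += GENETIC_CODE[mut] == aa
        if valid:
            s += syn / valid
    return s


def oracle_path_counts(a, b):
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return (0.0, 0.0)
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            sd += GENETIC_CODE[nxt] == GENETIC_CODE[cur]
            nd += GENETIC_CODE[nxt] != GENETIC_CODE[cur]
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_pairwise(seq1, seq2):
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if GENETIC_CODE.get(c1, "*") == "*" or GENETIC_CODE.get(c2, "*") == "*":
            continue
        path = oracle_path_counts(c1, c2)
        if path is None:
            continue
        n_codons += 1
        S += (oracle_site_counts(c1) + oracle_site_counts(c2)) / 2
        Sd += path[0]
        Nd += path[1]
    N = 3.0 * n_codons - S
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(pS), jc(pN)


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,expected",
        [("TTT", 1 / 3), ("TGG", 0.0), ("CTC", 1.0)],
    )
    def test_known_codons(self, codon, expected):
        s, n = sg.ng86_site_counts(codon)
        assert s == pytest.approx(expected)
        assert s + n == pytest.approx(3.0)

    def test_all_sense_codons_match_oracle(self):
        for codon in molevo.SENSE_CODONS:
            s, n = sg.ng86_site_counts(codon)
            assert s == pytest.approx(oracle_site_counts(codon), abs=1e-12)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            sg.ng86_site_counts("TAA")


class TestPairwise:
    def test_identical_sequences(self):
        s = "ATGGCTAAA"
        r = sg.ng86_pairwise(s, s)
        assert r.Sd == r.Nd == 0.0
        assert r.dS == r.dN == 0.0

    def test_single_synonymous_difference(self):
        s1, s2 = "TTT" * 9, "TTC" + "TTT" * 8
        r = sg.ng86_pairwise(s1, s2)
        assert (r.S_sites, r.N_sites) == (3.0, 24.0)
        assert r.pS == pytest.approx(1 / 3)
        assert r.dS == pytest.approx(-0.75 * math.log(5 / 9))
        assert r.dN == 0.0

    def test_single_nonsynonymous_difference(self):
        s1, s2 = "AAA" * 9, "AAC" + "AAA" * 8
        r = sg.ng86_pairwise(s1, s2)
        assert r.pN == pytest.approx(1 / 24)
        assert r.dN == pytest.approx(0.0429, abs=5e-5)
        assert r.dS == 0.0
        assert np.isnan(r.omega)

    def test_symmetry_and_site_conservation(self):
        rng = np.random.default_rng(1)
        for rep in range(20):
            pair = sg.simulate_codon_pair(
                sg.CodonSimConfig(n_codons=50, target_dS=0.4, omega=0.8, seed=rep)
            )
            a = sg.ng86_pairwise(*pair)
            b = sg.ng86_pairwise(pair[1], pair[0])
            for f in ("S_sites", "N_sites", "Sd", "Nd", "pS", "pN"):
                assert getattr(a, f) == pytest.approx(getattr(b, f))
            assert a.S_sites + a.N_sites == pytest.approx(3 * a.n_codons)

    def test_gapped_columns_dropped_pairwise(self):
        r = sg.ng86_pairwise("TTT---TTT", "TTTAAATTC")
        assert r.n_codons == 2
        assert r.Sd == 1.0

    def test_matches_oracle_on_random_pairs(self):
        for rep in range(100):
            s1, s2 = sg.simulate_codon_pair(
                sg.CodonSimConfig(n_codons=30, target_dS=0.5, omega=0.7, seed=rep)
            )
            S, N, Sd, Nd, dS, dN = oracle_pairwise(s1, s2)
            r = sg.ng86_pairwise(s1, s2)
            assert r.S_sites == pytest.approx(S, abs=1e-9)
            assert r.N_sites == pytest.approx(N, abs=1e-9)
            assert r.Sd == pytest.approx(Sd, abs=1e-9)
            assert r.Nd == pytest.approx(Nd, abs=1e-9)
            assert r.dS == pytest.approx(dS, abs=1e-9)
            assert r.dN == pytest.approx(dN, abs=1e-9)

    def test_jc_correction_limit(self):
        # d → p as p → 0 (relative error ≤ 0.1% at p ≤ 1e-3)
        p = 1e-3
        d = molevo.jukes_cantor(p)
        assert abs(d - p) / p <= 1e-3


class TestBootstrap:
    def test_zero_difference_zero_se(self):
        s = "ATGGCTAAATTTCCCGGGTTACGTACGAAA"
        se_ds, se_dn = sg.ng86_bootstrap_se(s, s, B=50, seed=0)
        assert se_ds == 0.0 and se_dn == 0.0

    def test_deterministic_under_seed(self):
        s1, s2 = sg.simulate_codon_pair(
            sg.CodonSimConfig(n_codons=200, target_dS=0.3, omega=0.5, seed=4)
        )
        a = sg.ng86_bootstrap_se(s1, s2, B=200, seed=9)
        b = sg.ng86_bootstrap_se(s1, s2, B=200, seed=9)
        assert a == b

    def test_bootstrap_se_tracks_replicate_sd(self):
        # SE from one bootstrap should approximate the SD of dS over
        # independent simulation replicates
        ds = []
        for rep in range(60):
            s1, s2 = sg.simulate_codon_pair(
                sg.CodonSimConfig(n_codons=500, target_dS=0.3, omega=0.3, seed=300 + rep)
            )
            ds.append(sg.ng86_pairwise(s1, s2).dS)
        true_sd = np.std(ds, ddof=1)
        s1, s2 = sg.simulate_codon_pair(
            sg.CodonSimConfig(n_codons=500, target_dS=0.3, omega=0.3, seed=999)
        )
        se, _ = sg.ng86_bootstrap_se(s1, s2, B=400, seed=1)
        assert se == pytest.approx(true_sd, rel=0.35)


class TestClock:
    @pytest.mark.parametrize("ds,expected_ma", [(0.513, 36.6), (0.438, 31.3), (0.0, 0.0)])
    def test_divergence_times(self, ds, expected_ma):
        assert sg.clock_time(ds, 7e-9).t_ma == expected_ma

    def test_se_propagation(self):
        est = sg.clock_time(0.513, 7e-9, se_dS=0.10)
        assert est.se_t_ma == pytest.approx(7.1, abs=0.05)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            sg.clock_time(0.5, 0.0)


class TestChisq:
    def test_published_lrt_pvalues(self):
        assert round(sg.chisq_sf(9.08, 2), 4) == 0.0107
        assert round(sg.chisq_sf(0.11, 1), 2) == 0.74

    def test_zero_statistic(self):
        assert sg.chisq_sf(0.0, 3) == 1.0

    def test_closed_form_df2(self):
        for x in (0.1, 1.0, 4.54, 9.08, 20.0):
            assert sg.chisq_sf(x, 2) == pytest.approx(math.exp(-x / 2), abs=1e-12)

    def test_high_precision_gamma_oracle(self):
        import sympy

        for df in range(1, 11):
            for x in (0.5, 2.3, 7.7):
                expected = float(
                    sympy.uppergamma(sympy.Rational(df, 2), sympy.Float(x) / 2)
                    / sympy.gamma(sympy.Rational(df, 2))
                )
                assert sg.chisq_sf(x, df) == pytest.approx(expected, rel=1e-10)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            sg.chisq_sf(1.0, 0)


class TestLrt:
    def test_from_log_likelihoods(self):
        stat, p = sg.lrt_pvalue(sg.LRTInput(df=2, lnL_null=-100.0, lnL_alt=-95.46))
        assert stat == pytest.approx(9.08)
        assert round(p, 4) == 0.0107

    def test_identical_likelihoods(self):
        stat, p = sg.lrt_pvalue(sg.LRTInput(df=1, lnL_null=-50.0, lnL_alt=-50.0))
        assert stat == 0.0 and p == 1.0

    def test_chi2_critical_value(self):
        _, p = sg.lrt_pvalue(sg.LRTInput(df=1, statistic=3.841458820694124))
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            sg.lrt_pvalue(sg.LRTInput(df=1, lnL_null=-50.0, lnL_alt=-51.0))


class TestClosestParalog:
    def test_identical_candidate_wins(self):
        focal = "ATGGCTAAATTTCCCGGGTTACGTACGAAA"
        best, r = sg.closest_paralog(focal, {"far": "ATGGCGAAGTTCCCAGGCTTGCGAACGAAG", "same": focal})
        assert best == "same" and r.dS == 0.0

    def test_lower_ds_candidate_selected(self):
        chosen = 0
        for rep in range(40):
            near = sg.simulate_codon_pair(
                sg.CodonSimConfig(n_codons=500, target_dS=0.1, omega=0.3, seed=rep)
            )
            far = sg.simulate_codon_pair(
                sg.CodonSimConfig(n_codons=500, target_dS=0.5, omega=0.3, seed=1000 + rep)
            )
            best, _ = sg.closest_paralog(
                near[0], {"near": near[1], "far": far[1]}
            )
            chosen += best == "near"
        assert chosen >= 39

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            sg.closest_paralog("ATG", {})


class TestEstimatorRecovery:
    @pytest.mark.parametrize("target_ds,omega", [(0.1, 0.3), (0.3, 0.3), (0.3, 1.0)])
    def test_mean_recovery_over_grid(self, target_ds, omega):
        ds_l, om_l = [], []
        for rep in range(60):
            pair = sg.simulate_codon_pair(
                sg.CodonSimConfig(
                    n_codons=2000, target_dS=target_ds, omega=omega,
                    seed=rep + int(1000 * target_ds) + int(100 * omega),
                )
            )
            r = sg.ng86_pairwise(*pair)
            ds_l.append(r.dS)
            om_l.append(r.omega)
        assert np.mean(ds_l) == pytest.approx(target_ds, rel=0.10)
        assert np.mean(om_l) == pytest.approx(omega, rel=0.15)


class TestCodonSimulator:
    def test_zero_divergence_identical(self):
        s1, s2 = sg.simulate_codon_pair(sg.CodonSimConfig(n_codons=80, target_dS=0.0, seed=1))
        assert s1 == s2

    def test_omega_zero_no_nonsynonymous(self):
        s1, s2 = sg.simulate_codon_pair(
            sg.CodonSimConfig(n_codons=800, target_dS=0.2, omega=0.0, seed=2)
        )
        r = sg.ng86_pairwise(s1, s2)
        assert r.Nd == 0.0 and r.dN == 0.0
        assert r.dS > 0.1

    def test_no_stop_codons(self):
        s1, s2 = sg.simulate_codon_pair(
            sg.CodonSimConfig(n_codons=300, target_dS=1.0, omega=1.0, seed=3)
        )
        for seq in (s1, s2):
            for i in range(0, len(seq), 3):
                assert molevo.translate_codon(seq[i : i + 3]) != "*"

    def test_deterministic(self):
        cfg = sg.CodonSimConfig(n_codons=100, target_dS=0.3, omega=0.5, seed=11)
        assert sg.simulate_codon_pair(cfg) == sg.simulate_codon_pair(cfg)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            sg.CodonSimConfig(omega=-0.1)
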
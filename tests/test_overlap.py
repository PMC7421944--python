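"""Harmonization, inflation control, conditional Q-Q and cFDR/conjFDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pleiokit as pk
from pleiokit.containers import ValidationError
from tests.conftest import toy_sumstats

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _with_alleles(ss, a1, a2, negate=False):
    t = ss.table.copy()
    t["a1"], t["a2"] = a1, a2
    if negate:
        t["z"] = -t["z"]
    return pk.SummaryStats(t)


class TestHarmonize:
    def test_swapped_alleles_restore_z_exactly(self):
        ss1 = toy_sumstats(np.random.default_rng(0).uniform(0.01, 1, 50))
        ss2 = _with_alleles(ss1, "G", "A", negate=True)
        pair = pk.harmonize_pair(ss1, ss2)
        assert np.array_equal(pair.z1, pair.z2)

    def test_strand_ambiguous_dropped(self):
        ss1 = toy_sumstats([0.5, 0.5])
        t = ss1.table.copy()
        t.loc[0, ["a1", "a2"]] = ["A", "T"]
        ss1 = pk.SummaryStats(t)
        pair = pk.harmonize_pair(ss1, ss1)
        assert len(pair) == 1
        assert pair.drop_log["strand_ambiguous"] == 1

    def test_sign_corrections_match_truth_table(self):
        """All 16 allele-pair matchings against an exhaustive oracle."""
        bases = "ACGT"
        rng = np.random.default_rng(1)
        cases = []
        for a1, a2 in itertools.permutations(bases, 2):
            for b1, b2 in itertools.permutations(bases, 2):
                cases.append((a1, a2, b1, b2))

        def oracle(a1, a2, b1, b2):
            if {a1, a2} in ({"A", "T"}, {"C", "G"}):
                return None
            if {b1, b2} in ({"A", "T"}, {"C", "G"}):
                return None
            if (b1, b2) == (a1, a2):
                return +1
            if (b1, b2) == (a2, a1):
                return -1
            rb1, rb2 = COMP[b1], COMP[b2]
            if (rb1, rb2) == (a1, a2):
                return +1
            if (rb1, rb2) == (a2, a1):
                return -1
            return None

        for a1, a2, b1, b2 in cases:
            z = float(rng.uniform(0.5, 2.0))
            ss1 = toy_sumstats([0.04], z=[z])
            ss1 = _with_alleles(ss1, a1, a2)
            ss2 = toy_sumstats([0.04], z=[z])
            ss2 = _with_alleles(ss2, b1, b2)
            want = oracle(a1, a2, b1, b2)
            pair = pk.harmonize_pair(ss1, ss2)
            if want is None:
                assert len(pair) == 0, (a1, a2, b1, b2)
            else:
                assert len(pair) == 1, (a1, a2, b1, b2)
                assert pair.z2[0] == pytest.approx(want * z)

    def test_empty_intersection_raises(self):
        ss1 = toy_sumstats([0.5], pos=[100])
        ss2 = toy_sumstats([0.5], pos=[200])
        with pytest.raises(ValidationError):
            pk.harmonize_pair(ss1, ss2)


class TestInflation:
    def test_null_lambda_near_one(self):
        z = np.random.default_rng(2).standard_normal(100_000)
        ss = toy_sumstats(2 * stats.norm.sf(np.abs(z)), z=z,
                          pos=np.arange(100_000) + 1)
        _, lam = pk.genomic_inflation_correct(ss)
        assert 0.97 < lam < 1.03

    def test_inflated_scores_are_corrected(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(100_000) * np.sqrt(1.2)
        ss = toy_sumstats(2 * stats.norm.sf(np.abs(z)), z=z,
                          pos=np.arange(100_000) + 1)
        corrected, lam = pk.genomic_inflation_correct(ss)
        assert lam == pytest.approx(1.2, abs=0.03)
        _, lam2 = pk.genomic_inflation_correct(corrected)
        assert lam2 == pytest.approx(1.0, abs=0.03)

    def test_no_deflation_when_lambda_below_one(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(50_000) * 0.8
        ss = toy_sumstats(2 * stats.norm.sf(np.abs(z)), z=z,
                          pos=np.arange(50_000) + 1)
        out, lam = pk.genomic_inflation_correct(ss)
        assert lam < 1
        assert np.allclose(out.p, ss.p, atol=1e-12)


class TestExcludeRegions:
    @pytest.mark.parametrize("chrom,pos,removed", [
        (6, 30_000_000, True),         # inside MHC
        (6, 25_119_106, True),         # inclusive start
        (6, 25_119_105, False),        # one below start
        (6, 33_854_733, True),         # inclusive end
        (6, 33_854_734, False),
        (8, 7_242_715, True),          # inclusive start of 8p23.1
        (8, 12_483_983, False),
        (1, 30_000_000, False),        # wrong chromosome
    ])
    def test_printed_boundaries_are_inclusive(self, chrom, pos, removed):
        ss = toy_sumstats([0.5], chrom=[chrom], pos=[pos])
        out, n = pk.exclude_regions(ss, [pk.MHC, pk.REGION_8P23])
        assert n == (1 if removed else 0)
        assert len(out) == (0 if removed else 1)


class TestConditionalQq:
    def test_self_conditioning_at_cutoff_one_is_ordinary_qq(self, small_pair):
        ss1, _, _ = small_pair
        pair = pk.harmonize_pair(ss1, ss1)
        qq = pk.conditional_qq(pair, cutoffs=[1.0])
        crv = qq.curves[1.0]
        p_sorted = np.sort(pair.p1)
        for t, e in zip(crv["nominal_nlp"], crv["ecdf"]):
            want = np.searchsorted(p_sorted, 10.0 ** (-t), side="right") \
                / p_sorted.size
            assert e == pytest.approx(want, abs=1e-12)

    def test_null_curves_stay_near_diagonal(self):
        """Independent traits: all strata match the null ECDF band."""
        cfg = pk.SimulationConfig(m_snps=20_000, block_size=1, pi_shared=0,
                                  seed=50)
        panel = pk.simulate_ld_genotypes(cfg, n_samples=200)
        ss1, ss2, _ = pk.simulate_sumstats_pair(cfg, panel)
        pair = pk.harmonize_pair(ss1, ss2)
        qq = pk.conditional_qq(pair)
        for c, crv in qq.curves.items():
            stratum_n = int(np.sum(pair.p2 <= c))
            sub = crv[crv["nominal_nlp"] <= 2.0]   # well-populated region
            nominal = 10.0 ** (-sub["nominal_nlp"])
            band = 4 * np.sqrt(nominal * (1 - nominal) / stratum_n) \
                + 2.0 / stratum_n
            assert np.all(np.abs(sub["ecdf"] - nominal) <= band)

    def test_shared_signal_deflects_monotonically(self):
        cfg = pk.SimulationConfig(m_snps=20_000, n1=50_000, n2=50_000,
                                  block_size=20, pi_shared=0.05,
                                  sign_concordance=1.0, h2_a=0.6, h2_b=0.6,
                                  seed=51)
        panel = pk.simulate_ld_genotypes(cfg, n_samples=300)
        ss1, ss2, _ = pk.simulate_sumstats_pair(cfg, panel)
        pair = pk.harmonize_pair(ss1, ss2)
        qq = pk.conditional_qq(pair)
        nominal = qq.curves[1.0]["nominal_nlp"]
        window = (nominal >= 1.0) & (nominal <= 3.0)
        prev = None
        for c in [1.0, 0.1, 0.01, 0.001]:
            cur = qq.curves[c]["ecdf"].to_numpy()[window]
            if prev is not None:
                assert np.all(cur >= prev - 1e-12)
                assert cur.mean() > prev.mean()
            prev = cur


class TestCondFdr:
    def test_twelve_variant_toy_matches_hand_count(self):
        """Exact per-variant equality with p1 |S(p2)| / #{p1<=., in S}."""
        p1 = np.array([1e-6, 2e-4, 5e-4, 0.001, 0.004, 0.01,
                       0.03, 0.08, 0.2, 0.4, 0.7, 0.95])
        rng = np.random.default_rng(6)
        p2 = rng.permutation(np.array([2e-5, 1e-4, 3e-4, 0.002, 0.005,
                                       0.02, 0.05, 0.1, 0.3, 0.5, 0.8, 0.99]))
        ss1 = toy_sumstats(p1)
        ss2 = toy_sumstats(p2)
        pair = pk.harmonize_pair(ss1, ss2)
        got = pk.cond_fdr(pair, which=1).fdr
        for i in range(12):
            stratum = np.flatnonzero(pair.p2 <= pair.p2[i])
            count = np.sum(pair.p1[stratum] <= pair.p1[i])
            want = min(1.0, max(pair.p1[i],
                                pair.p1[i] * stratum.size / count))
            assert got[i] == want, i

    def test_conditioning_on_constant_reduces_to_empirical_fdr(self):
        rng = np.random.default_rng(7)
        p1 = rng.uniform(size=10)
        ss1 = toy_sumstats(p1)
        ss2 = toy_sumstats(np.ones(10))
        pair = pk.harmonize_pair(ss1, ss2)
        got = pk.cond_fdr(pair, which=1).fdr
        ranks = stats.rankdata(p1, method="max")
        want = np.clip(p1 * 10 / ranks, p1, 1.0)
        assert np.allclose(got, want, atol=1e-12)

    def test_perfectly_informative_conditioning_dominates(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        pair = pk.harmonize_pair(toy_sumstats(p), toy_sumstats(p))
        cfdr = pk.cond_fdr(pair, which=1).fdr
        uncond = pk.cond_fdr(
            pk.harmonize_pair(toy_sumstats(p), toy_sumstats(np.ones(200))),
            which=1).fdr
        assert np.all(cfdr <= uncond + 1e-12)

    def test_values_bounded_by_p1_and_one(self, small_pair, small_panel):
        ss1, ss2, _ = small_pair
        pair = pk.harmonize_pair(ss1, ss2, panel=small_panel)
        for res in (pk.cond_fdr(pair, 1),
                    pk.cond_fdr(pair, 1, n_prune=5, seed=0)):
            assert np.all(res.fdr >= pair.p1 - 1e-15)
            assert np.all(res.fdr <= 1.0 + 1e-15)

    def test_grid_table_is_monotone(self, small_pair, small_panel):
        ss1, ss2, _ = small_pair
        pair = pk.harmonize_pair(ss1, ss2, panel=small_panel)
        table = pk.cond_fdr(pair, 1, n_prune=10, seed=1).table
        assert np.all(np.diff(table.values, axis=1) <= 1e-12)
        assert np.all(np.diff(table.values, axis=0) <= 1e-12)
        assert table.values.min() >= 0 and table.values.max() <= 1

    def test_permuted_conditioning_approaches_unconditional(self):
        rng = np.random.default_rng(9)
        m = 20_000
        p1 = rng.uniform(size=m)
        p2 = rng.permutation(p1)
        pair = pk.harmonize_pair(toy_sumstats(p1, pos=np.arange(m) + 1),
                                 toy_sumstats(p2, pos=np.arange(m) + 1))
        cfdr = pk.cond_fdr(pair, 1).fdr
        ranks = stats.rankdata(pair.p1, method="max")
        uncond = np.clip(pair.p1 * m / ranks, pair.p1, 1.0)
        assert np.mean(np.abs(cfdr - uncond)) < 0.02


class TestConjFdr:
    def test_is_maximum_of_the_two_directions(self, small_pair, small_panel):
        ss1, ss2, _ = small_pair
        pair = pk.harmonize_pair(ss1, ss2, panel=small_panel)
        f1 = pk.cond_fdr(pair, 1, n_prune=5, seed=2).fdr
        f2 = pk.cond_fdr(pair, 2, n_prune=5, seed=2).fdr
        cj = pk.conj_fdr(pair, n_prune=5, seed=2)
        assert np.array_equal(cj, np.maximum(f1, f2))

    def test_symmetric_in_trait_order(self, small_pair, small_panel):
        ss1, ss2, _ = small_pair
        a = pk.harmonize_pair(ss1, ss2, panel=small_panel)
        b = a.swapped()
        assert np.array_equal(pk.conj_fdr(a, n_prune=7, seed=3),
                              pk.conj_fdr(b, n_prune=7, seed=3))

    def test_pruning_requires_blocks(self, small_pair):
        ss1, ss2, _ = small_pair
        pair = pk.harmonize_pair(ss1, ss2)
        with pytest.raises(ValidationError, match="block"):
            pk.cond_fdr(pair, 1, n_prune=5)


class TestSharedLoci:
    def _sim(self, sign_concordance, seed=60, m=3000):
        cfg = pk.SimulationConfig(m_snps=m, n1=40_000, n2=40_000,
                                  block_size=20, pi_shared=0.05,
                                  sign_concordance=sign_concordance,
                                  h2_a=0.6, h2_b=0.6, seed=seed)
        panel = pk.simulate_ld_genotypes(cfg, n_samples=400)
        ss1, ss2, truth = pk.simulate_sumstats_pair(cfg, panel)
        pair = pk.harmonize_pair(ss1, ss2, panel=panel)
        cj = pk.conj_fdr(pair, n_prune=10, seed=seed)
        report = pk.shared_loci(pair, cj, panel, 0.05)
        # restrict to loci led by a variant near a true shared causal whose
        # effect is strong enough that the z signs are noise-free
        strong = truth.shared_index[
            np.sqrt(cfg.n1) * np.abs(truth.beta_a[truth.shared_index]) > 5.0]
        shared_pos = panel.variants["pos"].iloc[strong].to_numpy()
        shared_chrom = panel.variants["chrom"].iloc[strong].to_numpy()
        pos = panel.variants.set_index("snp")["pos"]
        chrom = panel.variants.set_index("snp")["chrom"]
        true_mask = np.array([
            bool(np.any((shared_chrom == chrom[lead])
                        & (np.abs(shared_pos - pos[lead]) <= 20_000)))
            for lead in report.table["lead"]
        ])
        signs_at_true = report.table["sign"].to_numpy()[true_mask]
        return report, signs_at_true

    def test_full_concordance_gives_all_same_direction(self):
        report, signs = self._sim(1.0)
        assert signs.size > 0
        assert np.all(signs > 0)

    def test_zero_concordance_gives_all_opposite(self):
        report, signs = self._sim(0.0)
        assert signs.size > 0
        assert np.all(signs < 0)

    def test_no_calls_is_empty_report_not_error(self):
        rng = np.random.default_rng(61)
        p = rng.uniform(0.2, 1.0, 50)
        cfg = pk.SimulationConfig(m_snps=50, block_size=5, pi_shared=0,
                                  seed=62)
        panel = pk.simulate_ld_genotypes(cfg, n_samples=200)
        ss1 = toy_sumstats(p, chrom=panel.variants["chrom"],
                           pos=panel.variants["pos"])
        t = ss1.table.assign(snp=panel.variants["snp"])
        ss1 = pk.SummaryStats(t)
        pair = pk.harmonize_pair(ss1, ss1, panel=panel)
        cj = pk.conj_fdr(pair)
        report = pk.shared_loci(pair, cj, panel, 1e-6)
        assert report.n_loci == 0
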
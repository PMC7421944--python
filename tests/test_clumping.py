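"""Clumping hierarchy against brute-force oracles on toy panels."""

import numpy as np
import pandas as pd
import pytest

import pleiokit as pk
from tests.conftest import toy_sumstats


def make_panel(r_target, pos, n=4000, chrom=None, seed=0):
    """Panel whose dosage correlations approximate a target matrix.

    Latent multivariate normal thresholded at 0.5 frequency; the
    dosage-scale correlation is close to (slightly below) the latent one.
    """
    m = len(pos)
    rng = np.random.default_rng(seed)
    r = np.asarray(r_target, dtype=float)
    chol = np.linalg.cholesky(r + 1e-9 * np.eye(m))
    d = 0
    for _ in range(2):
        lat = rng.standard_normal((n, m)) @ chol.T
        d = d + (lat > 0)
    freq = np.clip(d.mean(axis=0) / 2, 0.01, 0.99)
    v = pd.DataFrame({"snp": [f"v{i}" for i in range(m)],
                      "chrom": 1 if chrom is None else chrom,
                      "pos": pos, "a1": "A", "a2": "G", "freq": freq})
    return pk.GenotypePanel(d.astype(float), v)


def greedy_oracle(p, pos, r2, threshold, r2_thr, window):
    """Independent double-loop greedy clump (brute force)."""
    order = sorted(range(len(p)), key=lambda i: (p[i], pos[i]))
    accepted = []
    for i in order:
        if p[i] >= threshold:
            continue
        ok = True
        for j in accepted:
            if abs(pos[i] - pos[j]) <= window and r2[i][j] >= r2_thr:
                ok = False
        if ok:
            accepted.append(i)
    return accepted


class TestLdR2:
    def test_identical_columns_give_one(self):
        panel = make_panel(np.eye(3), [100, 200, 300])
        panel.dosages[:, 1] = panel.dosages[:, 0]
        assert pk.ld_r2(panel, 0, 1) == pytest.approx(1.0)
        assert pk.ld_r2(panel, 0, 0) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        panel = make_panel(np.eye(2), [100, 200], n=5000)
        assert pk.ld_r2(panel, 0, 1) < 0.01

    def test_matrix_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.4, (200, 8)).astype(float)
        v = pd.DataFrame({"snp": [f"v{i}" for i in range(8)], "chrom": 1,
                          "pos": np.arange(8) * 100 + 1, "a1": "A",
                          "a2": "G", "freq": 0.4})
        panel = pk.GenotypePanel(d, v)
        for i in range(8):
            for j in range(8):
                num = np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2
                assert pk.ld_r2(panel, i, j) == pytest.approx(num, abs=1e-12)

    def test_symmetry(self):
        panel = make_panel([[1, .5], [.5, 1]], [100, 200])
        assert pk.ld_r2(panel, 0, 1) == pytest.approx(pk.ld_r2(panel, 1, 0))


class TestClumpIndependent:
    def test_no_significant_variants_gives_empty(self, small_panel):
        ss = toy_sumstats(np.full(5, 0.5),
                          pos=np.arange(5) * 1000 + 1)
        assert pk.clump_independent(ss, small_panel) == []

    def test_high_ld_pair_keeps_smaller_p(self):
        """r^2 = 0.8 >= 0.6 within 50 kb: dependent, smaller p wins."""
        panel = make_panel([[1, .97], [.97, 1]], [100_000, 150_000], n=20000)
        assert pk.ld_r2(panel, 0, 1) >= 0.6
        ss = toy_sumstats([1e-9, 1e-12], pos=[100_000, 150_000])
        out = pk.clump_independent(ss, panel)
        assert out == ["v1"]

    def test_matches_exhaustive_oracle_on_random_toys(self):
        """100 random <=12-SNP instances: greedy output equals brute force."""
        rng = np.random.default_rng(7)
        for rep in range(100):
            m = int(rng.integers(2, 13))
            pos = np.sort(rng.choice(np.arange(1, 3_000_000, 1000), m,
                                     replace=False))
            # random correlation via random factor structure
            f = rng.standard_normal((m, 2))
            r = f @ f.T + np.diag(rng.uniform(0.1, 2.0, m))
            dd = np.sqrt(np.diag(r))
            r = r / np.outer(dd, dd)
            panel = make_panel(r, pos, n=3000, seed=100 + rep)
            p = 10.0 ** rng.uniform(-12, 0, m)
            p[rng.random(m) < 0.3] /= 1e6
            ss = toy_sumstats(p, pos=pos)
            params = pk.ClumpParams()
            got = pk.clump_independent(ss, panel, params)
            # oracle uses the same empirical r2 (computed independently)
            d = panel.dosages
            r2 = [[np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2 for j in range(m)]
                  for i in range(m)]
            want = greedy_oracle(p, pos, r2, params.p_threshold,
                                 params.r2_independent, params.window_bp)
            assert got == [f"v{i}" for i in want], f"instance {rep}"

    def test_output_invariant_to_input_row_order(self):
        rng = np.random.default_rng(8)
        pos = np.arange(10) * 50_000 + 1
        panel = make_panel(np.eye(10) * 0.5 + 0.5, pos, n=3000)
        p = 10.0 ** rng.uniform(-12, -6, 10)
        ss = toy_sumstats(p, pos=pos)
        shuffled = pk.SummaryStats(
            ss.table.sample(frac=1, random_state=1).reset_index(drop=True))
        assert pk.clump_independent(ss, panel) == \
            pk.clump_independent(shuffled, panel)


class TestDefineLoci:
    def _two_lead_setup(self, gap):
        pos = [1_000_000, 1_000_000 + gap]
        panel = make_panel(np.eye(2), pos, n=3000)
        ss = toy_sumstats([1e-10, 1e-11], pos=pos)
        params = pk.ClumpParams()
        indep = pk.clump_independent(ss, panel, params)
        return pk.define_loci(indep, ss, panel, params)

    def test_leads_within_merge_distance_form_one_locus(self):
        assert len(self._two_lead_setup(200_000)) == 1

    def test_leads_beyond_merge_distance_stay_separate(self):
        assert len(self._two_lead_setup(300_000)) == 2

    def test_toy_blocks_match_hand_enumeration(self):
        """Three LD blocks; rules applied in sequence by hand.

        Block A: v0..v4 tightly linked around 1.0 Mb, v0 most significant
        -> one lead, others dependent.  Block B: v5..v9 at 1.2 Mb, lead v6
        201 kb from lead v0 (< 250 kb) -> merges with A.  Block C: v10..v19
        at 9 Mb, only v12 significant -> separate locus.
        """
        m = 20
        pos = np.concatenate([1_000_000 + np.arange(5) * 1000,
                              1_200_000 + np.arange(5) * 1000,
                              9_000_000 + np.arange(10) * 1000])
        blocks = np.zeros((m, m))
        for sl in (slice(0, 5), slice(5, 10), slice(10, 20)):
            blocks[sl, sl] = 0.95
        np.fill_diagonal(blocks, 1.0)
        panel = make_panel(blocks, pos, n=20000)
        p = np.ones(m)
        p[0], p[1], p[6], p[12] = 1e-12, 1e-10, 1e-9, 1e-9
        ss = toy_sumstats(p, pos=pos)
        params = pk.ClumpParams()
        indep = pk.clump_independent(ss, panel, params)
        assert indep == ["v0", "v6", "v12"]    # one per significant block
        loci = pk.define_loci(indep, ss, panel, params)
        assert len(loci) == 2                  # A+B merged (<250 kb), C apart
        first = loci[0]
        assert first.start == 1_000_000 and first.end >= 1_204_000
        assert set(first.lead_ids) == {"v0", "v6"}
        second = loci[1]
        assert second.lead_ids == ["v12"]
        assert second.start == 9_000_000 and second.end == 9_009_000
        # candidates: everything in r^2 >= 0.6 with an independent SNP
        assert set(second.candidate_ids) == {f"v{i}" for i in range(10, 20)}

    def test_threshold_monotonicity(self, small_pair, small_panel):
        """Relaxing 1e-8 -> 5e-8 never decreases the locus count."""
        ss1, _, _ = small_pair
        counts = {}
        for thr in (1e-8, 5e-8):
            params = pk.ClumpParams(p_threshold=thr)
            indep = pk.clump_independent(ss1, small_panel, params)
            counts[thr] = len(pk.define_loci(indep, ss1, small_panel, params))
        assert counts[5e-8] >= counts[1e-8]

    def test_postconditions_on_simulated_data(self, small_pair, small_panel):
        """Independent SNPs pairwise r^2<0.6, leads pairwise r^2<0.1 (1 Mb),
        every significant SNP covered by an independent one at r^2>=0.6."""
        ss1, _, _ = small_pair
        params = pk.ClumpParams()
        indep = pk.clump_independent(ss1, small_panel, params)
        loci = pk.define_loci(indep, ss1, small_panel, params)
        idx = {s: j for j, s in enumerate(small_panel.variants["snp"])}
        pos = small_panel.variants.set_index("snp")["pos"]
        chrom = small_panel.variants.set_index("snp")["chrom"]

        def r2(a, b):
            return pk.ld_r2(small_panel, idx[a], idx[b])

        for i, a in enumerate(indep):
            for b in indep[i + 1:]:
                if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= params.window_bp:
                    assert r2(a, b) < params.r2_independent
        leads = [lid for loc in loci for lid in loc.lead_ids]
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                if chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= params.window_bp:
                    assert r2(a, b) < params.r2_lead
        sig = ss1.table.loc[ss1.p < params.p_threshold, "snp"]
        for s in sig:
            assert any(chrom[s] == chrom[a]
                       and abs(pos[s] - pos[a]) <= params.window_bp
                       and r2(s, a) >= params.r2_candidate
                       for a in indep) or s in indep
        # loci of one trait are pairwise non-overlapping
        for i, la in enumerate(loci):
            for lb in loci[i + 1:]:
                assert not la.overlaps(lb)


class TestCrossTrait:
    def test_single_trait_is_identity(self):
        loci = [pk.Locus(1, 100, 200, ["a"], ["a"], ["a"], 1e-9)]
        regions = pk.cross_trait_unique_loci({"t1": loci})
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 200)
        assert regions[0].traits == ["t1"]

    def test_identical_locus_in_two_traits_merges(self):
        locus = pk.Locus(2, 500, 900, ["a"], ["a"], ["a"], 1e-9)
        regions = pk.cross_trait_unique_loci({"t1": [locus], "t2": [locus]})
        assert len(regions) == 1
        assert set(regions[0].traits) == {"t1", "t2"}

    def test_counts_match_sweep_line_oracle(self):
        rng = np.random.default_rng(11)
        for rep in range(50):
            per_trait = {}
            intervals = []
            for t in range(int(rng.integers(1, 5))):
                starts = np.sort(rng.choice(np.arange(1, 10_000, 10),
                                            rng.integers(1, 8), replace=False))
                loci = []
                prev_end = 0
                for s in starts:
                    if s <= prev_end:      # keep per-trait lists disjoint
                        continue
                    e = s + int(rng.integers(5, 400))
                    loci.append(pk.Locus(1, int(s), e, ["x"], ["x"], ["x"],
                                         1e-9))
                    prev_end = e
                per_trait[f"t{t}"] = loci
                intervals += [(l.start, l.end) for l in loci]
            got = len(pk.cross_trait_unique_loci(per_trait))
            # oracle: classic sweep over sorted endpoints
            events = sorted(intervals)
            count, cur_end = 0, -1
            for s, e in events:
                if s > cur_end:
                    count += 1
                    cur_end = e
                else:
                    cur_end = max(cur_end, e)
            assert got == count, f"instance {rep}"
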
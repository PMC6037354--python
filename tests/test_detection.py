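import math

import numpy as np
import pandas as pd
import pytest

from rohscape import (GenotypeMatrix, MarkerMap, ROHSet, build_incidence,
                      classify_length, compute_allowances,
                      compute_min_snp_count, detect_category, detect_roh,
                      maximal_runs, merge_and_classify)


class TestMinSnpCount:
    @pytest.mark.parametrize("alpha,ns,ni,het,expected", [
        (0.5, 1, 1, 0.5, 1),            # ln(0.5)/ln(0.5) = 1
        (0.05, 10_000, 20, 0.30, 43),   # 42.62 -> ceil
        (0.05, 624_737, 54, 0.25, 71),  # 70.67 -> ceil
    ])
    def test_closed_form(self, alpha, ns, ni, het, expected):
        assert compute_min_snp_count(alpha, ns, ni, het) == expected
        raw = math.log(alpha / (ns * ni)) / math.log(1 - het)
        assert expected == math.ceil(raw)

    @pytest.mark.parametrize("het", [0.0, 1.0])
    def test_degenerate_heterozygosity_rejected(self, het):
        with pytest.raises(ValueError):
            compute_min_snp_count(0.05, 100, 10, het)


class TestAllowances:
    def test_zero_error_rate_allows_no_hets(self):
        for mL, dS in [(1e6, 1000.0), (16e6, 37.5)]:
            assert compute_allowances(mL, dS, 0.0, 0.0) == (0, 0)

    def test_direct_evaluation(self):
        assert compute_allowances(8e6, 4000, 0.0025, 0.0)[0] == 5
        assert compute_allowances(2e6, 4000, 0.0, 0.01)[1] == 5

    def test_rounding_modes(self):
        # (mL/dS)*eG = 4.4
        assert compute_allowances(4.4e6, 1000, 0.001, 0.0)[0] == 4
        assert compute_allowances(4.4e6, 1000, 0.001, 0.0, "ceil")[0] == 5
        assert compute_allowances(4.6e6, 1000, 0.001, 0.0, "floor")[0] == 4
        assert compute_allowances(4.6e6, 1000, 0.001, 0.0)[0] == 5


class TestMaximalRuns:
    def _mb_panel(self):
        pos = np.arange(12) * 1_000_000 + 1
        g = np.zeros(12, np.int8)
        g[6] = 1
        return g, pos

    def test_all_heterozygous_yields_nothing(self):
        g = np.ones(20, np.int8)
        assert maximal_runs(g, np.arange(20) * 1000 + 1, 2, 1, 5, 5) == []

    def test_het_splits_run_when_not_allowed(self):
        g, pos = self._mb_panel()
        assert maximal_runs(g, pos, 5, 4e6, 0, 0) == [(0, 5), (7, 11)]

    def test_het_allowance_bridges_run(self):
        g, pos = self._mb_panel()
        assert maximal_runs(g, pos, 5, 4e6, 1, 0) == [(0, 11)]

    def test_endpoints_trimmed_to_homozygous(self):
        g = np.array([1, 0, 0, 0, 0, -1], np.int8)
        pos = np.arange(6) * 1000 + 1
        assert maximal_runs(g, pos, 3, 1, 1, 1) == [(1, 4)]

    def test_oracle_equivalence_small_panels(self, brute_maximal_runs,
                                             random_panel_factory):
        rng = np.random.default_rng(42)
        for _ in range(60):
            g, pos, p = random_panel_factory(rng)
            assert maximal_runs(g, pos, **p) == brute_maximal_runs(g, pos, **p)

    def test_relaxing_allowances_never_shrinks_coverage(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(1, 10 ** 6), 50, replace=False))
        for _ in range(30):
            g = rng.choice([-1, 0, 1, 2], 50, p=[0.1, 0.4, 0.2, 0.3]).astype(np.int8)

            def covered(nH, nM):
                runs = maximal_runs(g, pos, 3, 1, nH, nM)
                cov = set()
                for i, j in runs:
                    cov.update(range(i, j + 1))
                return cov

            base = covered(0, 0)
            assert base <= covered(1, 0) <= covered(2, 1)


class TestMergeAndClassify:
    def _map(self, n=40, spacing=500_000):
        return MarkerMap(pd.DataFrame({
            "chrom": "1", "marker_id": [f"m{j}" for j in range(n)],
            "pos": np.arange(n) * spacing + 1}))

    def _cands(self, intervals):
        return pd.DataFrame([{"individual": "i", "chrom": "1",
                              "start_bp": s, "end_bp": e}
                             for s, e in intervals])

    def test_disjoint_segments_unchanged(self):
        roh = merge_and_classify(
            self._cands([(1_000_000, 3_000_000), (5_000_000, 7_000_000)]),
            self._map())
        assert len(roh) == 2
        assert set(roh.frame["category"]) == {"2-4 Mb"}

    def test_overlap_union_reclassified(self):
        roh = merge_and_classify(
            self._cands([(1_000_000, 3_000_000), (2_000_000, 6_000_000)]),
            self._map())
        assert len(roh) == 1
        seg = roh.frame.iloc[0]
        assert (seg["start_bp"], seg["end_bp"]) == (1_000_000, 6_000_000)
        assert seg["category"] == "4-8 Mb"

    def test_cross_round_merge_makes_long_category(self):
        roh = merge_and_classify(
            self._cands([(1_000_000, 10_000_000), (9_000_000, 18_000_000)]),
            self._map(60))
        assert len(roh) == 1
        assert roh.frame.iloc[0]["category"] == ">16 Mb"

    def test_sub_megabase_fragments_dropped(self):
        roh = merge_and_classify(self._cands([(1_000_000, 1_500_000)]),
                                 self._map())
        assert len(roh) == 0

    def test_bookended_merge_but_gapped_stay_separate(self):
        merged = merge_and_classify(
            self._cands([(1_000_000, 2_000_000), (2_000_001, 3_500_000)]),
            self._map())
        assert len(merged) == 1
        apart = merge_and_classify(
            self._cands([(1_000_000, 2_000_000), (2_000_002, 3_500_000)]),
            self._map())
        assert len(apart) == 2

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(3)
        intervals = [(int(s), int(s + l)) for s, l in zip(
            rng.integers(1, 15_000_000, 20), rng.integers(500_000, 4_000_000, 20))]
        M = self._map(80)
        a = merge_and_classify(self._cands(intervals), M)
        b = merge_and_classify(self._cands(intervals[::-1]), M)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        again = merge_and_classify(
            a.frame[["individual", "chrom", "start_bp", "end_bp"]], M)
        pd.testing.assert_frame_equal(again.frame, a.frame)

    def test_category_boundaries(self):
        assert classify_length(999_999) is None
        assert classify_length(1_000_000) == "1-2 Mb"
        assert classify_length(16_000_000) == ">16 Mb"
        assert classify_length(15_999_999) == "8-16 Mb"


class TestIncidence:
    def _setup(self):
        M = MarkerMap(pd.DataFrame({
            "chrom": "1", "marker_id": [f"m{j}" for j in range(10)],
            "pos": np.arange(10) * 1_000_000 + 1}))
        return M

    def test_empty_set_all_zero(self):
        M = self._setup()
        roh = ROHSet(pd.DataFrame(columns=["individual", "chrom", "start_bp",
                                           "end_bp", "n_snps", "length_bp",
                                           "category"]))
        assert build_incidence(roh, M, 5).counts.sum() == 0

    def test_single_segment_track(self):
        M = self._setup()
        frame = pd.DataFrame([{"individual": "i", "chrom": "1",
                               "start_bp": 3_000_001, "end_bp": 7_000_001,
                               "n_snps": 5, "length_bp": 4_000_001,
                               "category": "4-8 Mb"}])
        track = build_incidence(ROHSet(frame), M, 1)
        np.testing.assert_array_equal(track.counts,
                                      [0, 0, 0, 1, 1, 1, 1, 1, 0, 0])

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(12)
        M = self._setup()
        rows = []
        for ind in range(20):
            s = int(rng.integers(1, 8_000_000))
            e = s + int(rng.integers(1_000_000, 3_000_000))
            rows.append({"individual": f"i{ind}", "chrom": "1",
                         "start_bp": s, "end_bp": e, "n_snps": 0,
                         "length_bp": e - s + 1,
                         "category": classify_length(e - s + 1)})
        roh = ROHSet(pd.DataFrame(rows))
        track = build_incidence(roh, M, 20)
        pos = M.frame["pos"].to_numpy()
        brute = [sum(1 for r in rows if r["start_bp"] <= p <= r["end_bp"])
                 for p in pos]
        np.testing.assert_array_equal(track.counts, brute)

    def test_incidence_conserves_snp_count(self):
        rng = np.random.default_rng(1)
        M = self._setup()
        rows = []
        for ind in range(10):
            s = int(rng.integers(1, 6_000_000))
            e = s + int(rng.integers(1_000_000, 4_000_000))
            rows.append({"individual": f"i{ind}", "chrom": "1",
                         "start_bp": s, "end_bp": e, "n_snps": 0,
                         "length_bp": e - s + 1,
                         "category": classify_length(e - s + 1)})
        roh = ROHSet(pd.DataFrame(rows))
        track = build_incidence(roh, M, 10)
        pos = M.frame["pos"].to_numpy()
        n_snps = sum(int(np.searchsorted(pos, r["end_bp"], "right")
                         - np.searchsorted(pos, r["start_bp"], "left"))
                     for r in rows)
        assert track.counts.sum() == n_snps


class TestDetectRoh:
    def test_full_pipeline_on_constructed_panel(self):
        # one individual homozygous everywhere except a het island
        n = 300
        pos = np.arange(n) * 50_000 + 1
        M = MarkerMap(pd.DataFrame({"chrom": "1",
                                    "marker_id": [f"m{j}" for j in range(n)],
                                    "pos": pos}))
        rng = np.random.default_rng(0)
        het_ind = rng.choice([0, 1, 2], n, p=[0.55 / 2, 0.45, 0.55 / 2])
        calls = np.vstack([np.zeros(n), het_ind]).astype(np.int8)
        G = GenotypeMatrix(["hom", "het"], calls)
        roh = detect_roh(G, M)
        assert set(roh.frame["individual"]) == {"hom"}
        total = roh.frame["length_bp"].sum()
        assert total >= 0.9 * (pos[-1] - pos[0])

    def test_detect_category_unknown_chromosome_errors(self, tiny_panel):
        G, M = tiny_panel
        with pytest.raises(KeyError, match="chromosome '7'"):
            detect_category(G, M, "a", "7", 2, 1.0, 0, 0)
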
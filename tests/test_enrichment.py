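import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rohscape import (Genome, MarkerMap, ROHSet, call_enriched_intervals,
                      classify_length, empirical_pvalues, permute_segments,
                      read_bed, write_bed)
from rohscape.enrichment import EnrichedInterval


def _roh(rows):
    recs = [{"individual": ind, "chrom": chrom, "start_bp": s, "end_bp": e,
             "n_snps": 0, "length_bp": e - s + 1,
             "category": classify_length(e - s + 1)}
            for ind, chrom, s, e in rows]
    return ROHSet(pd.DataFrame(recs, columns=["individual", "chrom",
                                              "start_bp", "end_bp", "n_snps",
                                              "length_bp", "category"]))


GENOME = Genome.from_lengths({"1": 100_000_000})


class TestPermuteSegments:
    def test_lengths_chrom_individual_preserved(self):
        roh = _roh([("a", "1", 1_000_000, 4_000_000),
                    ("b", "1", 50_000_000, 52_500_000)])
        out = permute_segments(roh, GENOME, np.random.default_rng(0))
        pd.testing.assert_series_equal(out.frame["length_bp"],
                                       roh.frame["length_bp"])
        assert list(out.frame["individual"]) == ["a", "b"]
        assert (out.frame["end_bp"] <= 100_000_000).all()
        assert (out.frame["start_bp"] >= 1).all()

    def test_chromosome_sized_segment_forced_placement(self):
        roh = _roh([("a", "1", 1, 100_000_000)])
        out = permute_segments(roh, GENOME, np.random.default_rng(1))
        assert out.frame.iloc[0]["start_bp"] == 1

    def test_oversized_segment_rejected(self):
        roh = _roh([("a", "1", 1, 100_000_001)])
        roh.frame.loc[0, "length_bp"] = 100_000_001
        with pytest.raises(ValueError, match="longer than chromosome"):
            permute_segments(roh, GENOME, np.random.default_rng(2))

    def test_start_positions_uniform(self):
        # 3 Mb segment on 100 Mb: valid starts U{1, 97e6+1}
        roh = _roh([("a", "1", 1_000_000, 3_999_999)])
        rng = np.random.default_rng(3)
        starts = np.array([permute_segments(roh, GENOME, rng)
                           .frame.iloc[0]["start_bp"]
                           for _ in range(10_000)], dtype=float)
        u = (starts - 1) / 97_000_000
        assert sps.kstest(u, "uniform").pvalue > 0.01

    def test_empty_set_passes_through(self):
        out = permute_segments(_roh([]), GENOME, np.random.default_rng(4))
        assert len(out) == 0


class TestEmpiricalPvalues:
    def _toy(self):
        M = MarkerMap(pd.DataFrame({
            "chrom": "1", "marker_id": [f"m{j}" for j in range(10)],
            "pos": (np.arange(10) + 1) * 9_000_000}))
        roh = _roh([("a", "1", 27_000_000, 45_000_000)])  # covers SNPs 3..5
        return M, roh

    def test_zero_observed_count_gives_p_one(self):
        M, roh = self._toy()
        res = empirical_pvalues(roh, M, GENOME, 200, seed=5)
        assert (res.frame.loc[res.frame["observed"] == 0, "p"] == 1.0).all()

    def test_bit_exact_reproducibility(self):
        M, roh = self._toy()
        a = empirical_pvalues(roh, M, GENOME, 500, seed=9)
        b = empirical_pvalues(roh, M, GENOME, 500, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_duplicated_individual_symmetry(self):
        M, roh = self._toy()
        dup = _roh([("a", "1", 27_000_000, 45_000_000),
                    ("b", "1", 27_000_000, 45_000_000)])
        pa = empirical_pvalues(roh, M, GENOME, 300, seed=11).frame
        pb = empirical_pvalues(dup, M, GENOME, 300, seed=11).frame
        # same covered positions are the significant ones in both
        assert (pa["observed"] * 2 == pb["observed"]).all()

    def test_matches_exact_placement_enumeration(self):
        M, roh = self._toy()
        N = 20_000
        res = empirical_pvalues(roh, M, GENOME, N, seed=13)
        length = 18_000_001
        max_start = 100_000_000 - length + 1
        for _, row in res.frame.iterrows():
            p_ = row["pos"]
            n_cover = max(0, min(p_, max_start) - max(1, p_ - length + 1) + 1)
            exact = n_cover / max_start if row["observed"] >= 1 else 1.0
            se = np.sqrt(max(exact * (1 - exact), 1e-12) / N)
            assert abs(row["p"] - exact) <= 3 * se + 2 / N

    def test_null_pvalues_superuniform(self):
        # observed set is itself a random placement: p ~ superuniform
        rng = np.random.default_rng(21)
        M = MarkerMap(pd.DataFrame({
            "chrom": "1", "marker_id": [f"m{j}" for j in range(50)],
            "pos": np.sort(rng.choice(np.arange(1, 100_000_000), 50,
                                      replace=False))}))
        base = _roh([(f"i{k}", "1", 1, 5_000_000) for k in range(8)])
        placed = permute_segments(base, GENOME, rng)
        res = empirical_pvalues(placed, M, GENOME, 2000, seed=22)
        p = res.frame.loc[res.frame["observed"] > 0, "p"].to_numpy()
        # P(p <= x) <= x for a valid p-value; check at a few thresholds
        for x in (0.05, 0.1, 0.25):
            frac = (p <= x).mean()
            se = np.sqrt(x * (1 - x) / len(p))
            assert frac <= x + 3 * se

    def test_multi_segment_individual_counts_once(self):
        # one individual whose two segments span the whole chromosome:
        # every randomization covers any marker at most once for them
        M = MarkerMap(pd.DataFrame({
            "chrom": "1", "marker_id": ["m0", "m1"],
            "pos": [25_000_000, 75_000_000]}))
        roh = _roh([("a", "1", 1, 60_000_000),
                    ("a", "1", 60_000_002, 100_000_000)])
        res = empirical_pvalues(roh, M, GENOME, 300, seed=30)
        # observed counts are 1 (individual-level), and exceedance equals N
        assert (res.frame["observed"] == 1).all()
        assert (res.frame["exceedance"] <= 300).all()


class TestEnrichedIntervals:
    def _result(self, sig_pos_mb, all_pos_mb=None):
        pos = np.array(all_pos_mb if all_pos_mb is not None else sig_pos_mb)
        p = np.where(np.isin(pos, sig_pos_mb), 0.01, 0.5)
        frame = pd.DataFrame({"chrom": "1", "pos": (pos * 1e6).astype(int),
                              "observed": 5, "exceedance": 1, "p": p})
        from rohscape.enrichment import PermutationResult
        return PermutationResult(frame, 100, 0)

    def test_gap_rule(self):
        res = self._result([1.0, 1.5, 2.4, 4.0])
        ivs = call_enriched_intervals(res, 0.05)
        assert [(iv.start_bp, iv.end_bp) for iv in ivs] == \
            [(1_000_000, 2_400_000), (4_000_000, 4_000_000)]

    def test_no_significant_snps(self):
        res = self._result([], all_pos_mb=[1.0, 2.0])
        assert call_enriched_intervals(res, 0.05) == []

    def test_all_significant_single_interval(self):
        res = self._result([1.0, 1.5, 2.0, 2.5])
        assert len(call_enriched_intervals(res, 0.05)) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(1, 50_000_000), 100, replace=False))
        frame = pd.DataFrame({"chrom": "1", "pos": pos, "observed": 1,
                              "exceedance": 0, "p": rng.random(100)})
        from rohscape.enrichment import PermutationResult
        res = PermutationResult(frame, 100, 0)
        prev_n, prev_span = 0, 0
        for thr in (0.01, 0.05, 0.2, 0.5, 0.9):
            ivs = call_enriched_intervals(res, thr)
            n_sig = sum(iv.n_snps for iv in ivs)
            assert n_sig >= prev_n
            prev_n = n_sig


class TestBedRoundTrip:
    def test_coordinate_convention(self, tmp_path):
        iv = EnrichedInterval("2", 1_000_000, 2_400_000, 3, 1e-3)
        path = str(tmp_path / "x.bed")
        write_bed([iv], path)
        line = [l for l in open(path) if not l.startswith("#")][0]
        chrom, start, end, name, score = line.split("\t")
        assert (chrom, int(start), int(end)) == ("2", 999_999, 2_400_000)
        assert int(score) == 300  # -100*log10(1e-3)

    def test_round_trip(self, tmp_path):
        ivs = [EnrichedInterval("1", 500_000, 900_000, 2, 0.01),
               EnrichedInterval("3", 1, 10_000_000, 40, 1e-5)]
        path = str(tmp_path / "y.bed")
        write_bed(ivs, path)
        back = read_bed(path)
        assert [(b.chrom, b.start_bp, b.end_bp) for b in back] == \
            [(i.chrom, i.start_bp, i.end_bp) for i in ivs]

    def test_empty_list_header_only(self, tmp_path):
        path = str(tmp_path / "z.bed")
        write_bed([], path)
        assert read_bed(path) == []
        assert open(path).read().startswith("#")
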
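"""ROH caller vs brute-force oracle, F_ROH, incidence and conserved regions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sweeproh as sp
from conftest import brute_force_roh, make_matrix
from sweeproh.roh import RohParams, segment_summary


def segs_as_tuples(segments):
    return [(s.start, s.end, s.n_snps) for s in segments]


class TestCaller:
    def test_all_heterozygous_sample_has_no_segments(self):
        g = np.ones((120, 2), dtype=np.int8)
        m = make_matrix(np.arange(1, 121) * 5_000, g, chrom_length=1_000_000)
        assert sp.call_roh(m, "s0") == []

    def test_sixty_homozygous_snps_form_one_segment(self):
        positions = np.arange(1, 61) * 10_000          # 10 kb .. 600 kb
        g = np.zeros((60, 1), dtype=np.int8)
        m = make_matrix(positions, g, samples=["a"], chrom_length=1_000_000)
        segments = sp.call_roh(m, "a")
        assert segs_as_tuples(segments) == [(10_000, 600_000, 60)]
        assert segments[0].length_kb == pytest.approx(590.001)

    def test_large_internal_gap_splits_and_drops_short_parts(self):
        first = np.arange(1, 31) * 10_000              # spans 290 kb
        second = first[-1] + 1_500_000 + np.arange(1, 31) * 10_000
        positions = np.concatenate([first, second])
        g = np.zeros((60, 1), dtype=np.int8)
        m = make_matrix(positions, g, samples=["a"], chrom_length=5_000_000)
        assert sp.call_roh(m, "a") == []

    def test_min_snp_threshold_rejects_sparse_run(self):
        # 49 homozygous SNPs spanning > 600 kb pass length but fail min_snps
        positions = np.arange(1, 50) * 13_000
        g = np.zeros((49, 1), dtype=np.int8)
        m = make_matrix(positions, g, samples=["a"], chrom_length=1_000_000)
        params = RohParams(window_snps=20, min_snps=50)
        assert sp.call_roh(m, "a", params) == []

    def test_chromosome_shorter_than_window_is_skipped(self):
        g = np.zeros((10, 1), dtype=np.int8)
        m = make_matrix(np.arange(1, 11) * 10_000, g, samples=["a"])
        assert sp.call_roh(m, "a") == []

    def test_het_and_missing_tolerances_respected(self):
        # within-tolerance interruptions do not break the run
        g = np.zeros((80, 1), dtype=np.int8)
        g[20] = 1
        g[40] = -1
        positions = np.arange(1, 81) * 8_000
        m = make_matrix(positions, g, samples=["a"], chrom_length=1_000_000)
        params = RohParams(window_snps=20, window_het_max=2, window_missing_max=2,
                           min_snps=50, min_length_kb=500)
        got = segs_as_tuples(sp.call_roh(m, "a", params))
        expect = brute_force_roh(positions, g[:, 0], params)
        assert got == expect
        assert len(got) == 1

    @given(st.data())
    def test_oracle_equivalence_on_random_instances(self, data):
        s = data.draw(st.integers(20, 120))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        positions = np.sort(
            rng.choice(np.arange(1, 3_000_000, 100), size=s, replace=False)
        )
        col = rng.choice(
            np.array([0, 1, 2, -1], dtype=np.int8), size=(s, 1),
            p=[0.55, 0.2, 0.2, 0.05],
        )
        params = RohParams(
            window_snps=int(data.draw(st.integers(2, 15))),
            window_het_max=int(data.draw(st.integers(0, 3))),
            window_missing_max=int(data.draw(st.integers(0, 3))),
            hit_proportion_min=float(data.draw(st.sampled_from([0.025, 0.05, 0.5, 1.0]))),
            min_length_kb=float(data.draw(st.sampled_from([10, 100, 500]))),
            min_snps=int(data.draw(st.integers(2, 30))),
            max_gap_kb=float(data.draw(st.sampled_from([50, 200, 1000]))),
            density_kb_per_snp_max=float(data.draw(st.sampled_from([20, 100, 500]))),
        )
        m = make_matrix(positions, col, samples=["a"], chrom_length=3_100_000)
        got = segs_as_tuples(sp.call_roh(m, "a", params))
        assert got == brute_force_roh(positions, col[:, 0], params)

    def test_segments_sorted_and_non_overlapping(self, planted_bundle):
        for sample, segs in sp.call_roh_all(planted_bundle["matrix"]).items():
            by_chrom: dict = {}
            for s in segs:
                by_chrom.setdefault(s.chromosome, []).append(s)
            for chrom_segs in by_chrom.values():
                for a, b in zip(chrom_segs, chrom_segs[1:]):
                    assert a.end < b.start


class TestFroh:
    def test_no_segments_gives_zero(self):
        assert sp.froh([], 1000.0).froh == 0.0

    def test_total_length_equal_to_genome_gives_one(self):
        seg = sp.RohSegment("a", "1", 1, 1_000_000, 100)
        assert sp.froh([seg], 1000.0).froh == pytest.approx(1.0)

    def test_long_division_example(self):
        seg = sp.RohSegment("a", "1", 1, int(124_469.28895 * 1000), 100)
        result = sp.froh([seg], 2_489_385.779)
        assert result.froh == pytest.approx(0.05, rel=1e-6)

    def test_default_l_auto_constant(self):
        assert sp.DEFAULT_L_AUTO_KB == pytest.approx(2_489_385.779)


class TestConcordance:
    def test_identical_vectors(self):
        assert sp.froh_concordance([1, 2, 3], [1, 2, 3]) == pytest.approx((1.0, 1.0))

    def test_reversed_vectors(self):
        rho, r = sp.froh_concordance([1, 2, 3], [3, 2, 1])
        assert (rho, r) == (pytest.approx(-1.0), pytest.approx(-1.0))

    def test_hand_computed_example(self):
        rho, r = sp.froh_concordance([1, 2, 3, 4], [1, 2, 4, 3])
        assert rho == pytest.approx(0.8)
        assert r == pytest.approx(0.8)

    def test_zero_variance_reported_undefined(self):
        rho, r = sp.froh_concordance([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(r)

    def test_dict_inputs_matched_by_sample(self):
        a = {"x": 0.1, "y": 0.2, "z": 0.3}
        b = {"z": 0.3, "x": 0.1, "y": 0.2}
        assert sp.froh_concordance(a, b) == pytest.approx((1.0, 1.0))

    def test_wgs_vs_array_parameters_agree_on_synthetic_data(self):
        # per-individual tracts of graded length, long enough for both the
        # WGS-tuned and the array-era parameter sets to detect
        specs = tuple(
            sp.AutozygositySpec("1", 200_000, 200_000 + 1_200_000 + 200_000 * i,
                                (f"ind{i:03d}",))
            for i in range(6)
        )
        cfg = sp.SimConfig(
            seed=8, n_individuals=6, chromosomes=(("1", 6_000_000),),
            snp_density=5e-4, autozygosity_specs=specs, missing_rate=0.01,
        )
        matrix, _ = sp.simulate_population(cfg)
        span = sum(
            int(c.positions[-1] - c.positions[0] + 1) / 1000
            for c in matrix.chroms.values()
        )
        a = {s: sp.froh(v, span, s).froh
             for s, v in sp.call_roh_all(matrix, sp.RohParams()).items()}
        b = {s: sp.froh(v, span, s).froh
             for s, v in sp.call_roh_all(matrix, sp.ARRAY_DEFAULT_PARAMS).items()}
        rho, r = sp.froh_concordance(a, b)
        assert rho > 0.5 and r > 0.5


class TestIncidenceAndConserved:
    def three_sample_track(self):
        positions = np.arange(1, 11) * 100
        g = np.zeros((10, 3), dtype=np.int8)
        m = make_matrix(positions, g, chrom_length=2_000)
        segments = {
            "s0": [sp.RohSegment("s0", "1", 100, 500, 5)],
            "s1": [sp.RohSegment("s1", "1", 300, 800, 6)],
            "s2": [],
        }
        return m, segments

    def test_no_segments_gives_all_zero(self):
        m, _ = self.three_sample_track()
        track = sp.snp_incidence({"s0": [], "s1": [], "s2": []}, m)
        assert track.chroms["1"][1].tolist() == [0] * 10

    def test_incidence_counts_individuals_once(self):
        m, segments = self.three_sample_track()
        # duplicate overlapping segments for one sample must not double-count
        segments["s0"].append(sp.RohSegment("s0", "1", 200, 400, 3))
        track = sp.snp_incidence(segments, m)
        assert track.chroms["1"][1].tolist() == [1, 1, 2, 2, 2, 1, 1, 1, 0, 0]

    def test_cutoff_uses_ceiling(self):
        import math
        assert math.ceil(0.6 * 19) == 12  # breed-style threshold example

    def test_regions_from_high_incidence_runs(self):
        m, segments = self.three_sample_track()
        track = sp.snp_incidence(segments, m)
        regions = sp.conserved_regions(track, 3, 2 / 3, segments)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_snps, r.min_incidence) == (300, 500, 3, 2)
        assert {s.sample for s in r.contributing_segments} == {"s0", "s1"}

    def test_disjoint_roh_with_full_threshold_gives_nothing(self):
        m, segments = self.three_sample_track()
        track = sp.snp_incidence(segments, m)
        assert sp.conserved_regions(track, 3, 1.0) == []

    def test_threshold_monotonicity(self, planted_bundle):
        matrix = planted_bundle["matrix"]
        segments = sp.call_roh_all(matrix)
        track = sp.snp_incidence(segments, matrix)
        n = len(matrix.samples)
        previous = None
        for prop in (0.3, 0.5, 0.7, 0.9):
            spans = {
                (r.chromosome, r.start, r.end)
                for r in sp.conserved_regions(track, n, prop)
            }
            if previous is not None:
                for chrom, start, end in spans:
                    assert any(
                        c == chrom and s <= start and end <= e
                        for c, s, e in previous
                    )
            previous = spans

    def test_planted_tract_recovered_with_carrier_count(self):
        carriers = tuple(f"ind{i:03d}" for i in range(6))
        cfg = sp.SimConfig(
            seed=3, n_individuals=10, chromosomes=(("1", 1_000_000),),
            snp_density=1e-3,
            autozygosity_specs=(sp.AutozygositySpec("1", 100_000, 700_000, carriers),),
            missing_rate=0.01,
        )
        matrix, _ = sp.simulate_population(cfg)
        segments = sp.call_roh_all(matrix)
        track = sp.snp_incidence(segments, matrix)
        regions = sp.conserved_regions(track, 10, 0.5, segments)
        assert len(regions) == 1
        assert len(regions[0].contributing_segments) == 6
        assert regions[0].start <= 150_000 and regions[0].end >= 650_000

    def test_summary_statistics_over_contributing_segments(self):
        segs = [
            sp.RohSegment("a", "1", 1, 100_000, 50),
            sp.RohSegment("b", "1", 1, 300_000, 50),
        ]
        summary = segment_summary(segs)
        assert summary["count"] == 2
        assert summary["mean_kb"] == pytest.approx(200.0, rel=1e-3)
        assert summary["sd_kb"] == pytest.approx(
            float(np.std([100.0, 300.0], ddof=1)), rel=1e-3
        )
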
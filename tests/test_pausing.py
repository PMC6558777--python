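import numpy as np
import pandas as pd
import pytest

from startseq.core_io import AlignedRead
from startseq.coverage import THREE_PRIME, build_end_coverage
from startseq.pausing import (
    assign_reads_to_genes,
    compute_fpkm,
    initiation_class_profiles,
    length_by_initiation,
    pausing_index,
    three_prime_metaprofile,
    top_quartile_anchors,
)


class TestFpkm:
    def test_closed_form(self):
        assert compute_fpkm([100], [1000], 1e6)[0] == pytest.approx(100.0)

    def test_zero_count(self):
        assert compute_fpkm([0], [1000], 1e6)[0] == 0.0

    def test_zero_length_is_hard_error(self):
        with pytest.raises(ValueError):
            compute_fpkm([10], [0], 1e6)

    def test_matches_per_row_recomputation(self, rng):
        counts = rng.integers(0, 10_000, 100)
        lengths = rng.integers(200, 50_000, 100)
        total = 3.7e7
        got = compute_fpkm(counts, lengths, total)
        for i in range(100):
            assert got[i] == pytest.approx(counts[i] * 1e9 / (total * lengths[i]))


class TestPausingIndex:
    def test_simple_ratio(self):
        assert pausing_index([500], [10.0])[0] == pytest.approx(50.0)

    def test_zero_fpkm_is_missing(self):
        assert np.isnan(pausing_index([500], [0.0])[0])

    def test_scale_equivariance(self, rng):
        counts = rng.integers(10, 5_000, 200).astype(float)
        fpkm = rng.lognormal(1, 1, 200)
        pi = pausing_index(counts, fpkm)
        np.testing.assert_allclose(pausing_index(2 * counts, fpkm), 2 * pi)
        # doubling the RNA-seq library total halves FPKM and doubles PI
        lengths = rng.integers(1000, 5000, 200)
        raw = rng.integers(1, 10_000, 200)
        f1 = compute_fpkm(raw, lengths, 1e7)
        f2 = compute_fpkm(raw, lengths, 2e7)
        np.testing.assert_allclose(pausing_index(counts, f2), 2 * pausing_index(counts, f1))


def sense_read(p5, length, strand="+", chrom="chr1"):
    if strand == "+":
        return AlignedRead(chrom, p5, p5 + length, "+")
    return AlignedRead(chrom, p5 - length + 1, p5 + 1, "-")


ANCHOR = [("chr1", 10_000, "+", "gA.0")]


class TestThreePrimeProfile:
    def test_fixed_length_reads_peak_at_34(self):
        reads = [sense_read(10_000, 35) for _ in range(20)]
        cov3 = build_end_coverage(reads, THREE_PRIME)
        profile, peak = three_prime_metaprofile(cov3, ANCHOR)
        assert peak == 34
        assert profile.sum() == 20  # conservation

    def test_planted_normal_lengths_peak_in_band(self, rng):
        lengths = np.clip(np.rint(rng.normal(35, 5, 30_000)), 18, 47).astype(int)
        reads = [sense_read(10_000, int(L)) for L in lengths]
        _, peak = three_prime_metaprofile(build_end_coverage(reads, THREE_PRIME), ANCHOR)
        assert 33 <= peak <= 36

    def test_uniform_ends_have_no_dominant_peak(self, rng):
        positions = rng.integers(9_850, 10_151, 5000)
        reads = [sense_read(int(p) - 30, 31) for p in positions]
        profile, _ = three_prime_metaprofile(build_end_coverage(reads, THREE_PRIME), ANCHOR)
        interior = profile[30:-1]  # offsets fully covered by the uniform draw
        assert interior.max() <= 2 * np.median(interior)

    def test_top_quartile_selection(self):
        anchors = [("chr1", i, "+", f"g{i}") for i in range(8)]
        fpkm = np.array([1, 9, 3, 7, 5, 8, 2, 6], dtype=float)
        top = top_quartile_anchors(anchors, fpkm)
        assert [a[1] for a in top] == [1, 5]


class TestAssignment:
    def test_nearest_tss_wins_and_tie_goes_upstream(self):
        anchors = [("chr1", 1_000, "+", "up"), ("chr1", 1_200, "+", "down")]
        r_near = sense_read(1_050, 30)
        r_tie = sense_read(1_100, 30)
        df = assign_reads_to_genes([r_near, r_tie], anchors)
        assert list(df.gene_id) == ["up", "up"]
        assert list(df.offset5) == [50, 100]

    def test_wrong_strand_or_out_of_window_unassigned(self):
        anchors = [("chr1", 1_000, "+", "g")]
        reads = [
            AlignedRead("chr1", 1_010, 1_040, "-"),
            sense_read(1_151, 30),  # offset +151, outside the 150 nt flank
        ]
        assert len(assign_reads_to_genes(reads, anchors)) == 0

    def test_minus_strand_offsets(self):
        anchors = [("chr1", 1_000, "-", "g")]
        df = assign_reads_to_genes([sense_read(1_007, 35, "-")], anchors)
        assert list(df.offset5) == [-7]
        assert list(df.offset3) == [-7 + 34]


class TestLengthByInitiation:
    def test_mean_and_sem(self):
        df = pd.DataFrame(
            {"gene_id": ["g"] * 2, "offset5": [-7, -7], "length": [36, 38], "offset3": [0, 0]}
        )
        out = length_by_initiation(df)
        assert out.n_reads[0] == 2
        assert out.mean_length[0] == pytest.approx(37.0)
        assert out.sem_length[0] == pytest.approx(1.0)

    def test_reads_longer_than_47_excluded(self):
        df = pd.DataFrame(
            {"gene_id": ["g"] * 3, "offset5": [0, 0, 0], "length": [35, 48, 47], "offset3": [0] * 3}
        )
        out = length_by_initiation(df)
        assert out.n_reads[0] == 2 and out.mean_length[0] == pytest.approx(41.0)

    def test_flat_under_distance_anchored_no_bonus(self):
        """Mean length has no trend in initiation offset when lengths ignore starts."""
        from startseq.synth import GeneratorConfig, generate_genome_and_genes, simulate_startseq
        from startseq.coverage import FIVE_PRIME
        from startseq.tss import TssConfig, passing_tss_anchors, reannotate_tss

        cfg = GeneratorConfig(
            seed=77, n_genes=60, n_elements=0, chrom_length=300_000,
            upstream_length_bonus=0.0, tss_purity=0.5, offtss_geom_p=0.08,
            reads_lognorm_mu=float(np.log(800)),
        )
        bundle = generate_genome_and_genes(cfg)
        reads = simulate_startseq(cfg, bundle)
        covs = [build_end_coverage(r, FIVE_PRIME) for r in reads]
        df = reannotate_tss(bundle.genes, covs, TssConfig(primary_replicate=0))
        anchors = passing_tss_anchors(df)
        assigned = assign_reads_to_genes(reads[0], anchors)
        lbp = length_by_initiation(assigned)
        well = lbp[lbp.n_reads >= 50]
        slope = np.polyfit(well.offset5, well.mean_length, 1)[0]
        assert abs(slope) < 0.1


class TestInitiationClasses:
    def _reads(self, n_up, n_down, mode, rng):
        """Planted reads: upstream band at -8, downstream band at +20."""
        reads = []
        for _ in range(n_up):
            L = 35 + 8 if mode == "sequence" else int(np.clip(rng.normal(35, 2), 18, 47))
            reads.append(sense_read(10_000 - 8, L))
        for _ in range(n_down):
            L = 35 - 20 if mode == "sequence" else int(np.clip(rng.normal(35, 2), 18, 47))
            reads.append(sense_read(10_000 + 20, L))
        return reads

    def test_distance_anchored_shift_tracks_centroid_gap(self, rng):
        assigned = assign_reads_to_genes(self._reads(300, 300, "distance", rng), ANCHOR)
        res = initiation_class_profiles(assigned)
        assert res.centroid_gap == pytest.approx(28.0)
        assert abs(res.shift_statistic - res.centroid_gap) <= 2

    def test_sequence_anchored_shift_is_zero(self, rng):
        assigned = assign_reads_to_genes(self._reads(300, 300, "sequence", rng), ANCHOR)
        res = initiation_class_profiles(assigned)
        assert abs(res.shift_statistic) <= 2

    def test_empty_class_is_underpowered(self, rng):
        assigned = assign_reads_to_genes(self._reads(0, 300, "distance", rng), ANCHOR)
        res = initiation_class_profiles(assigned)
        assert res.upstream.underpowered
        assert np.isnan(res.shift_statistic)
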
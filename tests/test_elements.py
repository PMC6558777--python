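import itertools

import pytest

from startseq.coverage import FIVE_PRIME, StrandedEndCoverage
from startseq.elements import (
    Peak,
    call_strand_peaks,
    filter_promoter_proximal,
    merge_bidirectional,
    select_novel_transcripts,
)


def make_cov(entries):
    cov = StrandedEndCoverage(FIVE_PRIME)
    for (chrom, strand, pos), n in entries.items():
        cov.add(chrom, strand, pos, n)
    return cov


class TestPeakCaller:
    def test_single_position(self):
        peaks = call_strand_peaks(make_cov({("chr1", "+", 500): 12}))
        assert len(peaks) == 1 and peaks[0].summit == 500 and peaks[0].summit_count == 12

    def test_nearby_weaker_summit_suppressed(self):
        cov = make_cov({("chr1", "+", 500): 12, ("chr1", "+", 600): 11})
        peaks = call_strand_peaks(cov, min_separation=150)
        assert len(peaks) == 1 and peaks[0].summit == 500

    def test_below_min_count_ignored(self):
        assert call_strand_peaks(make_cov({("chr1", "+", 500): 9})) == []

    def test_opposite_strands_independent(self):
        cov = make_cov({("chr1", "+", 500): 12, ("chr1", "-", 520): 12})
        assert len(call_strand_peaks(cov)) == 2

    def test_matches_greedy_oracle(self, rng):
        for _ in range(300):
            entries = {}
            for _ in range(int(rng.integers(1, 30))):
                pos = int(rng.integers(0, 3_000))
                entries[pos] = entries.get(pos, 0) + int(rng.integers(1, 20))
            cov = make_cov({("chr1", "+", p): v for p, v in entries.items()})
            got = [(p.summit, p.summit_count) for p in call_strand_peaks(cov, 10, 150)]
            # oracle: independent greedy over count-sorted positions
            accepted = []
            for pos, v in sorted(entries.items(), key=lambda t: (-t[1], t[0])):
                if v >= 10 and all(abs(pos - a) >= 150 for a, _ in accepted):
                    accepted.append((pos, v))
            assert sorted(got) == sorted(accepted)


class TestPromoterFilter:
    def _peak(self, summit, strand="+"):
        return Peak("chr1", strand, summit, 20, summit - 5, summit + 5)

    @pytest.mark.parametrize("dist,kept", [(3000, False), (3001, True)])
    def test_boundary_inclusive(self, dist, kept):
        peaks = filter_promoter_proximal([self._peak(10_000 + dist)], [("chr1", 10_000)])
        assert bool(peaks) == kept

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            peaks = [self._peak(int(rng.integers(0, 100_000))) for _ in range(40)]
            tss = [("chr1", int(rng.integers(0, 100_000))) for _ in range(20)]
            got = filter_promoter_proximal(peaks, tss, 3000)
            expected = [
                p for p in peaks
                if all(abs(p.summit - t) > 3000 for _, t in tss)
            ]
            assert [p.summit for p in got] == [p.summit for p in expected]


def chain_oracle(peaks, max_gap):
    """Independent region enumeration: walk summit-sorted peaks, cut at gaps,
    keep maximal runs of >=2 with an adjacent opposite-strand pair."""
    regions = []
    by_chrom = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.summit, p.strand)):
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        run = [ps[0]]
        for p in ps[1:]:
            if p.summit - run[-1].summit <= max_gap:
                run.append(p)
            else:
                regions.append(run)
                run = [p]
        regions.append(run)
    return [
        tuple(p.summit for p in run)
        for run in regions
        if len(run) >= 2 and any(a.strand != b.strand for a, b in itertools.pairwise(run))
    ]


class TestMergeBidirectional:
    def _peak(self, summit, strand, chrom="chr1"):
        return Peak(chrom, strand, summit, 15, summit - 10, summit + 10)

    def test_opposite_pair_within_gap_merges(self):
        regions = merge_bidirectional([self._peak(1_000, "+"), self._peak(2_500, "-")])
        assert len(regions) == 1
        assert regions[0].start == 990 and regions[0].end == 2_510

    def test_same_strand_pair_gives_no_region(self):
        assert merge_bidirectional([self._peak(1_000, "+"), self._peak(1_500, "+")]) == []

    def test_far_apart_opposite_pair_gives_no_region(self):
        assert merge_bidirectional([self._peak(1_000, "+"), self._peak(4_100, "-")]) == []

    def test_matches_chain_enumeration_on_small_sets(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 9))
            peaks = [
                self._peak(int(rng.integers(0, 10_000)), "+" if rng.random() < 0.5 else "-")
                for _ in range(n)
            ]
            got = merge_bidirectional(peaks, 2_000)
            got_summits = [tuple(p.summit for p in r.member_peaks) for r in got]
            assert sorted(got_summits) == sorted(chain_oracle(peaks, 2_000)) if peaks else got == []

    def test_regions_non_overlapping_and_partition_members(self, rng):
        peaks = [
            self._peak(int(rng.integers(0, 200_000)), "+" if rng.random() < 0.5 else "-")
            for _ in range(300)
        ]
        regions = merge_bidirectional(peaks, 1_000)
        spans = sorted((r.start, r.end) for r in regions)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        member_ids = [id(p) for r in regions for p in r.member_peaks]
        assert len(member_ids) == len(set(member_ids))


GTF_LINE = '{chrom}\tsrc\t{feat}\t{start}\t{end}\t.\t{strand}\t.\tgene_id "{gid}"; transcript_id "{tid}";\n'


def write_gtf(path, rows):
    path.write_text("".join(GTF_LINE.format(**r) for r in rows))


class TestNovelTranscripts:
    def _known(self, tmp_path):
        p = tmp_path / "known.gtf"
        write_gtf(p, [dict(chrom="chr1", feat="gene", start=1_001, end=5_000,
                           strand="+", gid="known1", tid="known1.t")])
        return p

    def test_multi_exon_intergenic_retained(self, tmp_path):
        asm = tmp_path / "asm.gtf"
        write_gtf(asm, [
            dict(chrom="chr1", feat="exon", start=20_001, end=20_500, strand="+", gid="n1", tid="t1"),
            dict(chrom="chr1", feat="exon", start=21_001, end=21_500, strand="+", gid="n1", tid="t1"),
        ])
        res = select_novel_transcripts(asm, self._known(tmp_path))
        assert res["intergenic"] == ["t1"] and res["multi_exon"] == ["t1"]

    def test_single_exon_intergenic_counted_not_retained(self, tmp_path):
        asm = tmp_path / "asm.gtf"
        write_gtf(asm, [dict(chrom="chr1", feat="exon", start=20_001, end=20_500,
                             strand="+", gid="n1", tid="t1")])
        res = select_novel_transcripts(asm, self._known(tmp_path))
        assert res["n_intergenic"] == 1 and res["n_multi_exon"] == 0

    def test_one_base_overlap_disqualifies(self, tmp_path):
        asm = tmp_path / "asm.gtf"
        write_gtf(asm, [
            dict(chrom="chr1", feat="exon", start=5_000, end=5_400, strand="-", gid="n1", tid="t1"),
            dict(chrom="chr1", feat="exon", start=6_001, end=6_400, strand="-", gid="n1", tid="t1"),
        ])
        res = select_novel_transcripts(asm, self._known(tmp_path))
        assert res["n_intergenic"] == 0

    def test_overlap_matches_brute_force(self, tmp_path, rng):
        known_rows = []
        bodies = []
        for i in range(15):
            s = int(rng.integers(0, 50_000))
            e = s + int(rng.integers(100, 3_000))
            bodies.append((s, e))
            known_rows.append(dict(chrom="chr1", feat="gene", start=s + 1, end=e,
                                   strand="+", gid=f"k{i}", tid=f"k{i}.t"))
        known = tmp_path / "known.gtf"
        write_gtf(known, known_rows)
        asm_rows, exons = [], {}
        for i in range(60):
            s = int(rng.integers(0, 50_000))
            e = s + int(rng.integers(50, 800))
            exons.setdefault(f"t{i % 30}", []).append((s, e))
            asm_rows.append(dict(chrom="chr1", feat="exon", start=s + 1, end=e,
                                 strand="+", gid=f"t{i % 30}", tid=f"t{i % 30}"))
        asm = tmp_path / "asm.gtf"
        write_gtf(asm, asm_rows)
        res = select_novel_transcripts(asm, known)
        expected = sorted(
            tid for tid, exs in exons.items()
            if all(
                not (max(s, bs) < min(e, be)) for s, e in exs for bs, be in bodies
            )
        )
        assert res["intergenic"] == expected


class TestPlantedElements:
    def test_recall_and_promoter_avoidance(self, small_bundle):
        """All planted intergenic pairs recovered; none near any planted TSS."""
        from startseq.coverage import build_end_coverage

        cov5 = build_end_coverage(small_bundle.reads[0], FIVE_PRIME)
        peaks = call_strand_peaks(cov5)
        tss_list = [(g.chrom, g.tss) for g in small_bundle.genes]
        nongenic = filter_promoter_proximal(peaks, tss_list)
        regions = merge_bidirectional(nongenic)
        truth = small_bundle.truth_elements
        recovered = 0
        for e in truth.itertuples():
            hit = any(
                r.chrom == e.chrom and r.start <= e.summit_minus and e.summit_plus < r.end
                for r in regions
            )
            recovered += hit
        assert recovered / len(truth) >= 0.95
        for r in regions:
            mid = (r.start + r.end) // 2
            assert all(
                not (c == r.chrom and abs(t - mid) <= 3000) for c, t in tss_list
            )
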
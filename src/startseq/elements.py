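"""Non-genic initiation elements: strand-specific peaks, promoter exclusion,
bidirectional merging, and the multi-exon filter for novel transcripts.

Bidirectionally transcribed non-genic loci are a hallmark of active
enhancers.  Peaks are called per strand from 5'-end coverage with a simple
greedy summit caller (an external peak BED is also accepted upstream), peaks
within +/- 3 kb of any known TSS are excluded, and remaining peaks are
chained when consecutive summits lie within 3 kb; a chain of two or more
peaks containing at least one adjacent opposite-strand pair is reported as a
bidirectional region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .coverage import StrandedEndCoverage

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    chrom: str
    strand: str
    summit: int
    summit_count: int
    start: int
    end: int  # half-open interval of contiguous support


@dataclass
class BidirectionalRegion:
    chrom: str
    start: int
    end: int
    member_peaks: list[Peak]

    @property
    def strand_composition(self) -> str:
        return "".join(p.strand for p in self.member_peaks)


def call_strand_peaks(
    cov5: StrandedEndCoverage, min_count: int = 10, min_separation: int = 150
) -> list[Peak]:
    """Greedy descending-count summit selection per chromosome and strand.

    A candidate summit is accepted when its count is at least ``min_count``
    and it lies at least ``min_separation`` from every previously accepted
    summit on the same strand.  Equal counts are visited left to right.  The
    peak interval is the contiguous run of nonzero positions through the
    summit, clipped to +/- min_separation.
    """
    peaks: list[Peak] = []
    for (chrom, strand), counts in sorted(cov5.data.items()):
        candidates = [(pos, v) for pos, v in counts.items() if v >= min_count]
        candidates.sort(key=lambda t: (-t[1], t[0]))
        accepted: list[int] = []
        nonzero = set(p for p, v in counts.items() if v > 0)
        for pos, v in candidates:
            if any(abs(pos - a) < min_separation for a in accepted):
                continue
            accepted.append(pos)
            lo = pos
            while lo - 1 in nonzero and pos - (lo - 1) <= min_separation:
                lo -= 1
            hi = pos
            while hi + 1 in nonzero and (hi + 1) - pos <= min_separation:
                hi += 1
            peaks.append(Peak(chrom, strand, pos, v, lo, hi + 1))
    peaks.sort(key=lambda p: (p.chrom, p.summit, p.strand))
    logger.info("called %d strand-specific peaks", len(peaks))
    return peaks


def filter_promoter_proximal(
    peaks: list[Peak], tss_list, exclusion: int = 3000
) -> list[Peak]:
    """Drop peaks whose summit is within +/- exclusion (inclusive) of any TSS.

    ``tss_list`` is (chrom, position) pairs — known annotation TSSs plus
    assembled-transcript TSSs when available; the check is strand-agnostic.
    """
    import numpy as np

    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss_list:
        by_chrom.setdefault(chrom, []).append(pos)
    arrays = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    kept = []
    for p in peaks:
        arr = arrays.get(p.chrom)
        if arr is not None and arr.size:
            i = int(np.searchsorted(arr, p.summit))
            near = min(
                abs(p.summit - arr[j]) for j in (i - 1, i) if 0 <= j < arr.size
            )
            if near <= exclusion:
                continue
        kept.append(p)
    logger.info(
        "promoter filter removed %d of %d peaks (+/- %d nt)",
        len(peaks) - len(kept), len(peaks), exclusion,
    )
    return kept


def merge_bidirectional(peaks: list[Peak], max_gap: int = 3000) -> list[BidirectionalRegion]:
    """Chain summit-sorted peaks with consecutive gaps <= max_gap.

    Each maximal chain of two or more peaks that contains at least one
    adjacent opposite-strand pair becomes a region spanning the member
    intervals.
    """
    regions: list[BidirectionalRegion] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        chain: list[Peak] = []
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.summit, p.strand))

        def flush(chain: list[Peak]):
            if len(chain) >= 2 and any(
                a.strand != b.strand for a, b in zip(chain, chain[1:])
            ):
                regions.append(
                    BidirectionalRegion(
                        chrom,
                        min(p.start for p in chain),
                        max(p.end for p in chain),
                        list(chain),
                    )
                )

        for p in ordered:
            if chain and p.summit - chain[-1].summit <= max_gap:
                chain.append(p)
            else:
                flush(chain)
                chain = [p]
        flush(chain)
    logger.info("merged %d bidirectional regions from %d peaks", len(regions), len(peaks))
    return regions


def write_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.summit_count}\t{p.strand}\n")


def write_regions(regions: list[BidirectionalRegion], bed_path, tsv_path=None) -> None:
    with open(bed_path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tbidir{i}\t{len(r.member_peaks)}\t.\n")
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write("region\tchrom\tstart\tend\tn_peaks\tstrands\tsummits\n")
            for i, r in enumerate(regions):
                summits = ",".join(str(p.summit) for p in r.member_peaks)
                fh.write(
                    f"bidir{i}\t{r.chrom}\t{r.start}\t{r.end}\t{len(r.member_peaks)}"
                    f"\t{r.strand_composition}\t{summits}\n"
                )


def load_peaks_bed(path) -> list[Peak]:
    """Accept an externally called peak BED6 (summit = interval midpoint)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            score = int(float(f[4])) if len(f) > 4 and f[4] != "." else 0
            peaks.append(Peak(f[0], f[5], (start + end) // 2, score, start, end))
    return peaks


def _gtf_exons_by_transcript(path):
    from .core_io import _iter_gtf_records

    exons: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, start, end, _strand, attrs, lineno in _iter_gtf_records(path, {"exon"}):
        tid = attrs.get("transcript_id") or attrs.get("gene_id")
        if not tid:
            raise ValueError(f"{path}:{lineno}: exon without transcript_id")
        exons.setdefault(tid, []).append((chrom, start, end))
    return exons


def select_novel_transcripts(assembled_gtf, known_gtf) -> dict:
    """Split assembled transcripts into intergenic and multi-exon-intergenic sets.

    A transcript is intergenic iff none of its exons shares a base with any
    known gene body (strand-agnostic).  Because short-read assembly
    over-reports single-exon transcripts, only multi-exon intergenic
    transcripts are retained as novel-gene candidates; both sets and their
    counts are returned.
    """
    from .core_io import IntervalSet, _iter_gtf_records

    bodies = []
    for chrom, start, end, _strand, _attrs, _ln in _iter_gtf_records(
        known_gtf, {"gene", "transcript"}
    ):
        bodies.append((chrom, start, end))
    if not bodies:
        # fall back to exon span per gene
        for tid, exs in _gtf_exons_by_transcript(known_gtf).items():
            chrom = exs[0][0]
            bodies.append((chrom, min(e[1] for e in exs), max(e[2] for e in exs)))
    mask = IntervalSet(bodies)

    exons = _gtf_exons_by_transcript(assembled_gtf)
    intergenic, multi_exon = [], []
    for tid, exs in sorted(exons.items()):
        if not exs:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        if any(mask.overlaps(chrom, s, e) for chrom, s, e in exs):
            continue
        intergenic.append(tid)
        if len(exs) >= 2:
            multi_exon.append(tid)
    frac = 100.0 * len(multi_exon) / len(intergenic) if intergenic else float("nan")
    logger.info(
        "%d intergenic transcripts, %d (%.1f%%) multi-exon (retained as novel)",
        len(intergenic), len(multi_exon), frac,
    )
    return {
        "intergenic": intergenic,
        "multi_exon": multi_exon,
        "n_intergenic": len(intergenic),
        "n_multi_exon": len(multi_exon),
    }
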
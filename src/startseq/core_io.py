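"""Readers and writers for the standard formats the pipeline touches.

All coordinates are internally 0-based half-open (the BED convention).
GTF input (1-based, end-inclusive) is converted on load.  A gene's TSS is
``body_start`` on the plus strand and ``body_end - 1`` on the minus strand.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: identifier, strand, body interval and TSS.

    ``occurrence`` distinguishes records that share a gene_id but have
    distinct TSSs; such records are retained as separate analysis units.
    """

    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int
    occurrence: int = 0

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.body_start < self.body_end:
            raise ValueError(
                f"{self.gene_id}: body_start {self.body_start} >= body_end {self.body_end}"
            )

    @property
    def tss(self) -> int:
        """0-based genomic coordinate of the annotated start nucleotide."""
        return self.body_start if self.strand == "+" else self.body_end - 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.occurrence)


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely-mapped stranded read as a 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Sorted, per-chromosome non-overlapping intervals (a removal mask)."""

    def __init__(self, intervals: Iterable[tuple] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start >= end:
                raise ValueError(f"empty interval [{start},{end}) on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares at least one base with the mask."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, end - 1) - 1
        return i >= 0 and self._ends[chrom][i] > start

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                rows.append((f[0], int(f[1]), int(f[2])))
        return cls(rows)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(s))


def _iter_gtf_records(path: str | Path, features: set[str]):
    """Yield (chrom, start0, end, strand, attrs, lineno) for selected features."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({len(f)} fields)")
            if f[2] not in features:
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
            yield f[0], start, end, f[6], _parse_gtf_attrs(f[8]), lineno


def load_gene_annotation(path: str | Path, dedupe: bool = True) -> list[GeneRecord]:
    """Load genes from GTF or BED, converting to the internal convention.

    With ``dedupe`` on, records sharing both gene_id and TSS collapse to one;
    records sharing a gene_id but with distinct TSSs are kept as separate
    entries tagged with an occurrence index.
    """
    path = Path(path)
    raw: list[tuple[str, str, str, int, int]] = []  # gene_id, chrom, strand, start, end
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        for chrom, start, end, strand, attrs, lineno in _iter_gtf_records(path, {"gene", "transcript"}):
            if strand not in ("+", "-"):
                logger.warning("%s:%d: record without strand rejected", path, lineno)
                continue
            gene_id = attrs.get("gene_id") or attrs.get("transcript_id")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: no gene_id attribute")
            raw.append((gene_id, chrom, strand, start, end))
        # prefer 'gene' rows; if a file has both gene and transcript rows for the
        # same id at the same locus, dedupe below collapses them
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: BED record needs >= 6 fields")
                strand = f[5]
                if strand not in ("+", "-"):
                    logger.warning("%s:%d: record without strand rejected", path, lineno)
                    continue
                try:
                    start, end = int(f[1]), int(f[2])
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
                raw.append((f[3], f[0], strand, start, end))

    records: list[GeneRecord] = []
    seen: set[tuple[str, int]] = set()
    occ_count: dict[str, int] = {}
    for gene_id, chrom, strand, start, end in raw:
        tss = start if strand == "+" else end - 1
        if dedupe:
            if (gene_id, tss) in seen:
                continue
            seen.add((gene_id, tss))
        occ = occ_count.get(gene_id, 0)
        occ_count[gene_id] = occ + 1
        records.append(GeneRecord(gene_id, chrom, strand, start, end, occurrence=occ))
    n_multi = sum(1 for v in occ_count.values() if v > 1)
    logger.info(
        "loaded %d gene records (%d unique gene ids, %d ids with multiple TSSs)",
        len(records), len(occ_count), n_multi,
    )
    return records


def load_reads(path: str | Path) -> list[AlignedRead]:
    """Load aligned reads from a BED6 file, preserving order."""
    reads: list[AlignedRead] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 record needs 6 fields")
            if f[5] not in ("+", "-"):
                logger.warning("%s:%d: read without strand rejected", path, lineno)
                rejected += 1
                continue
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            reads.append(AlignedRead(f[0], start, end, f[5]))
    if not reads:
        logger.warning("%s: no reads loaded", path)
    logger.info("%s: %d reads loaded, %d rejected", path, len(reads), rejected)
    return reads


def write_reads_bed(reads: Sequence[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


def filter_blacklist(reads: Sequence[AlignedRead], mask: IntervalSet) -> list[AlignedRead]:
    """Remove every read sharing at least one base with the mask (any strand)."""
    kept = [r for r in reads if not mask.overlaps(r.chrom, r.start, r.end)]
    logger.info("blacklist removed %d of %d reads", len(reads) - len(kept), len(reads))
    return kept


def write_bedgraph(coverage, strand: str, path: str | Path) -> None:
    """Write one strand of an end-coverage track as sorted, run-merged bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted({c for c, s in coverage.data if s == strand}):
            counts = coverage.get(chrom, strand)
            run_start = run_end = None
            run_val = 0
            for pos in sorted(counts):
                v = counts[pos]
                if v == 0:
                    continue
                if run_start is not None and pos == run_end and v == run_val:
                    run_end += 1
                else:
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")
                    run_start, run_end, run_val = pos, pos + 1, v
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")


def read_bedgraph(path: str | Path, strand: str, end_kind: str):
    """Parse a bedGraph written by :func:`write_bedgraph` back into coverage."""
    from .coverage import StrandedEndCoverage

    cov = StrandedEndCoverage(end_kind)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, val = line.split("\t")
            for pos in range(int(start), int(end)):
                cov.add(chrom, strand, pos, int(val))
    return cov
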
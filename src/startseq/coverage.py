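"""Strand-specific single-nucleotide 5'/3'-end coverage and window counting.

Coverage is held sparsely (position -> count per chromosome and strand) so a
toy genome and a full mammalian genome share the same code path.  All window
and metagene arithmetic is anchor-oriented: for a minus-strand anchor,
positive offsets point toward decreasing genomic coordinates (downstream in
gene orientation).  ``+/- N`` windows include both boundary offsets, so a
window of up=down=500 spans 1001 positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import AlignedRead

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass
class StrandedEndCoverage:
    """Sparse per-(chrom, strand) map of genomic position -> read-end count."""

    end_kind: str
    data: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end_kind not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown end_kind {self.end_kind!r}")

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        d = self.data.setdefault((chrom, strand), {})
        d[pos] = d.get(pos, 0) + count

    def get(self, chrom: str, strand: str) -> dict:
        return self.data.get((chrom, strand), {})

    @property
    def total(self) -> int:
        return sum(sum(d.values()) for d in self.data.values())


def read_end_position(read: AlignedRead, end_kind: str) -> int:
    """Genomic coordinate of the read's 5' or 3' terminal base."""
    if end_kind == FIVE_PRIME:
        return read.start if read.strand == "+" else read.end - 1
    if end_kind == THREE_PRIME:
        return read.end - 1 if read.strand == "+" else read.start
    raise ValueError(f"unknown end_kind {end_kind!r}")


def build_end_coverage(reads: Iterable[AlignedRead], end_kind: str) -> StrandedEndCoverage:
    cov = StrandedEndCoverage(end_kind)
    n = 0
    for r in reads:
        cov.add(r.chrom, r.strand, read_end_position(r, end_kind))
        n += 1
    logger.debug("built %s coverage from %d reads", end_kind, n)
    return cov


def offset_to_genomic(anchor: int, offset: int, orientation: str) -> int:
    """Map an anchor-oriented offset to a genomic coordinate."""
    return anchor + offset if orientation == "+" else anchor - offset


def window_count(
    cov: StrandedEndCoverage,
    chrom: str,
    strand: str,
    center: int,
    up: int,
    down: int,
    orientation: str | None = None,
) -> int:
    """Sum of end counts at offsets -up..+down (inclusive) around ``center``.

    ``strand`` selects which coverage strand is read; ``orientation`` (default:
    same as ``strand``) sets which genomic direction counts as downstream.
    """
    if up < 0 or down < 0:
        raise ValueError("window extents must be >= 0")
    orientation = orientation or strand
    counts = cov.data.get((chrom, strand))
    if counts is None:
        if (chrom, "+") not in cov.data and (chrom, "-") not in cov.data:
            logger.warning("window_count: chromosome %r absent from coverage", chrom)
        return 0
    if orientation == "+":
        lo, hi = center - up, center + down
    else:
        lo, hi = center - down, center + up
    if len(counts) > (hi - lo + 1):
        return sum(counts.get(p, 0) for p in range(lo, hi + 1))
    return sum(v for p, v in counts.items() if lo <= p <= hi)


@dataclass
class MetageneMatrix:
    """Anchor x offset count matrix in anchor orientation.

    Column ``j`` corresponds to offset ``j - flank_up``; minus-strand anchors
    are mirrored so positive offsets always point downstream of the anchor.
    """

    anchors: list  # (chrom, position, strand, label)
    flank_up: int
    flank_down: int
    matrix: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank_up, self.flank_down + 1)

    def profile(self) -> np.ndarray:
        """Column sums: the metagene profile over all anchors."""
        return self.matrix.sum(axis=0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=[a[3] for a in self.anchors], columns=self.offsets
        )


def metagene_matrix(
    cov: StrandedEndCoverage,
    anchors: Sequence[tuple],
    flank_up: int,
    flank_down: int,
) -> MetageneMatrix:
    """Build the per-anchor end-count matrix over -flank_up..+flank_down."""
    width = flank_up + flank_down + 1
    mat = np.zeros((len(anchors), width), dtype=np.int64)
    for i, (chrom, pos, strand, _label) in enumerate(anchors):
        counts = cov.data.get((chrom, strand))
        if not counts:
            continue
        row = mat[i]
        if len(counts) > width:
            for j in range(width):
                g = offset_to_genomic(pos, j - flank_up, strand)
                row[j] = counts.get(g, 0)
        else:
            for g, v in counts.items():
                off = (g - pos) if strand == "+" else (pos - g)
                if -flank_up <= off <= flank_down:
                    row[off + flank_up] += v
    return MetageneMatrix(list(anchors), flank_up, flank_down, mat)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
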
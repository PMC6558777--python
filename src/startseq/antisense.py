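"""Divergent and convergent antisense TSS calling around gene promoters.

Divergent initiation fires on the strand opposite a gene, upstream of its
TSS and directed away from it; convergent initiation fires opposite-strand
downstream, head-on into the promoter.  Both are called as the single base
with the most 5' ends on the opposite strand within a one-sided window, and
quantified by the +/- 50 nt count around the called peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import StrandedEndCoverage, offset_to_genomic, spearman_rho, window_count

logger = logging.getLogger(__name__)

DIVERGENT = "divergent"
CONVERGENT = "convergent"


@dataclass
class AntisenseCall:
    gene_id: str
    kind: str
    peak_position: int
    peak_offset: int  # signed, gene orientation, relative to the sense TSS
    peak_count: int
    flank50_count: int
    window_total: int


def flank50_count(
    cov5: StrandedEndCoverage, chrom: str, strand: str, peak_position: int, flank: int = 50
) -> int:
    """Inclusive +/- flank sum on the given strand around the called peak."""
    return window_count(cov5, chrom, strand, peak_position, flank, flank)


def call_antisense_tss(
    cov5: StrandedEndCoverage,
    chrom: str,
    gene_tss: int,
    gene_strand: str,
    kind: str,
    gene_id: str = "",
    window: int = 500,
    threshold: int = 10,
) -> AntisenseCall | None:
    """Call the divergent or convergent TSS for one gene, or None if below noise.

    Scans the opposite strand at gene-oriented offsets [-window, -1]
    (divergent) or [+1, +window] (convergent); offset 0 is excluded so the two
    searches are disjoint.  The call is absent when the one-sided window total
    is below ``threshold``.  Ties go to the offset nearest the sense TSS.
    """
    if kind not in (DIVERGENT, CONVERGENT):
        raise ValueError(f"unknown kind {kind!r}")
    opp = "-" if gene_strand == "+" else "+"
    counts = cov5.data.get((chrom, opp), {})
    offsets = range(-window, 0) if kind == DIVERGENT else range(1, window + 1)
    total = 0
    best_off: int | None = None
    best_count = 0
    for off in offsets:
        g = offset_to_genomic(gene_tss, off, gene_strand)
        v = counts.get(g, 0)
        if v == 0:
            continue
        total += v
        if v > best_count or (v == best_count and abs(off) < abs(best_off)):
            best_count = v
            best_off = off
    if total < threshold or best_off is None:
        return None
    peak_pos = offset_to_genomic(gene_tss, best_off, gene_strand)
    return AntisenseCall(
        gene_id=gene_id,
        kind=kind,
        peak_position=peak_pos,
        peak_offset=best_off,
        peak_count=best_count,
        flank50_count=flank50_count(cov5, chrom, opp, peak_pos),
        window_total=total,
    )


def call_antisense_table(
    cov5: StrandedEndCoverage,
    anchors,  # (chrom, tss, strand, gene_id)
    window: int = 500,
    threshold: int = 10,
) -> pd.DataFrame:
    """One row per (gene, kind) for every anchor with a call."""
    rows = []
    for chrom, tss, strand, gene_id in anchors:
        for kind in (DIVERGENT, CONVERGENT):
            call = call_antisense_tss(
                cov5, chrom, tss, strand, kind, gene_id, window, threshold
            )
            if call is not None:
                rows.append(vars(call))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "kind", "peak_position", "peak_offset",
            "peak_count", "flank50_count", "window_total",
        ],
    )
    n_div = int((df["kind"] == DIVERGENT).sum()) if len(df) else 0
    logger.info(
        "antisense calls on %d anchors: %d divergent, %d convergent",
        len(anchors), n_div, len(df) - n_div,
    )
    return df


def antisense_correlation_matrix(vectors: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Spearman matrix over an aligned gene universe.

    Each vector may contain NaN for genes lacking a call; pairs are dropped
    per cell.  Cells with fewer than 3 complete pairs are NaN.
    """
    names = list(vectors)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            x = np.asarray(vectors[a], dtype=float)
            y = np.asarray(vectors[b], dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            rho = spearman_rho(x[ok], y[ok]) if ok.sum() >= 3 else float("nan")
            mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat
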
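"""Promoter-proximal Pol II pausing quantification.

Short capped RNAs carry dual information: the 5' end marks where Pol II
initiated and the 3' end marks where it paused.  This module computes

* the pausing index PI = (sense 5'-end count in TSS +/- 500 bp) / FPKM,
* the 3'-end metaprofile around final TSSs (pause positions, peaking ~+35),
* RNA length as a function of each RNA's own initiation position, and
* initiation-class 5'/3' profiles that discriminate the two candidate pause
  rules: if pausing is sequence-anchored, RNAs initiating upstream or
  downstream of the main TSS end at the same genomic spot (3'-peak shift
  between classes ~ 0); if it is distance-anchored, the 3' peaks shift by the
  distance between the class initiation centroids.

Because sequencing reads were 50 nt, inserts longer than 47 nt cannot be
measured; reads longer than ``max_len`` are excluded from length statistics.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AlignedRead
from .coverage import (
    FIVE_PRIME,
    StrandedEndCoverage,
    metagene_matrix,
    read_end_position,
)

logger = logging.getLogger(__name__)


def compute_fpkm(gene_counts, gene_lengths, library_total: float) -> np.ndarray:
    """FPKM = count * 1e9 / (library_total * length)."""
    counts = np.asarray(gene_counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return counts * 1e9 / (library_total * lengths)


def pausing_index(tss_window_count, fpkm) -> np.ndarray:
    """Count / FPKM; NaN where FPKM is zero (logged, not infinite)."""
    counts = np.asarray(tss_window_count, dtype=float)
    f = np.asarray(fpkm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(f > 0, counts / f, np.nan)
    n_excluded = int((~(f > 0)).sum())
    if n_excluded:
        logger.info("pausing_index: %d genes with zero FPKM excluded", n_excluded)
    return pi


def pausing_table(
    reannotation: pd.DataFrame,
    fpkm_by_gene: dict[str, float],
    count_col: str = "window_count_rep1",
) -> pd.DataFrame:
    """Per-gene PausingRecord table for status-pass genes with an FPKM value."""
    sub = reannotation[reannotation["status"] == "pass"].copy()
    sub["fpkm"] = sub["gene_id"].map(fpkm_by_gene)
    sub = sub.dropna(subset=["fpkm"])
    sub["tss_window_count"] = sub[count_col]
    sub["pausing_index"] = pausing_index(sub["tss_window_count"], sub["fpkm"])
    return sub[
        ["gene_id", "occurrence", "tss_window_count", "fpkm", "pausing_index"]
    ].reset_index(drop=True)


def three_prime_metaprofile(
    cov3: StrandedEndCoverage, anchors, flank: int = 150
) -> tuple[np.ndarray, int]:
    """3'-end metagene profile over -flank..+flank and its peak offset.

    Ties at the maximum go to the smallest offset.  Sub-profiles (e.g. the
    top expression quartile) are obtained by passing a subset of anchors.
    """
    mm = metagene_matrix(cov3, anchors, flank, flank)
    profile = mm.profile()
    peak = int(np.argmax(profile)) - flank
    return profile, peak


def top_quartile_anchors(anchors, fpkm: np.ndarray):
    """Anchors of the top 25% of genes by FPKM (rank over the given set)."""
    f = np.asarray(fpkm, dtype=float)
    if len(f) != len(anchors):
        raise ValueError("fpkm must align with anchors")
    k = max(1, len(f) // 4)
    idx = np.argsort(-f, kind="stable")[:k]
    return [anchors[i] for i in sorted(idx)]


def assign_reads_to_genes(
    reads: list[AlignedRead],
    anchors,  # (chrom, tss, strand, gene_id)
    flank: int = 150,
) -> pd.DataFrame:
    """Assign each read to at most one gene by its sense-strand 5' end.

    A read is assigned when it lies on a gene's strand and its 5' end falls
    within +/- flank of that gene's final TSS, regardless of where within the
    window it initiated.  When several TSSs qualify the nearest wins; distance
    ties go to the upstream (lower-coordinate) gene.  Returns a frame with
    the gene id, the signed 5' offset (gene orientation), the read length and
    the signed 3' offset.
    """
    by_cs: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for chrom, tssp, strand, gid in anchors:
        by_cs.setdefault((chrom, strand), []).append((tssp, gid))
    for lst in by_cs.values():
        lst.sort()

    rows = []
    for read in reads:
        lst = by_cs.get((read.chrom, read.strand))
        if not lst:
            continue
        p5 = read_end_position(read, FIVE_PRIME)
        positions = [t for t, _ in lst]
        i = bisect_left(positions, p5)
        best = None  # (distance, tss, gid)
        for j in (i - 1, i):
            if 0 <= j < len(lst):
                t, g = lst[j]
                d = abs(p5 - t)
                if d <= flank and (best is None or (d, t) < (best[0], best[1])):
                    best = (d, t, g)
        if best is None:
            continue
        _, tssp, gid = best
        off5 = p5 - tssp if read.strand == "+" else tssp - p5
        rows.append((gid, off5, read.length, off5 + read.length - 1))
    return pd.DataFrame(rows, columns=["gene_id", "offset5", "length", "offset3"])


def length_by_initiation(
    assigned: pd.DataFrame, flank: int = 150, max_len: int = 47
) -> pd.DataFrame:
    """Per-initiation-offset read-length statistics (mean, SEM, n).

    Reads longer than ``max_len`` are dropped from the length statistics
    (their count is logged); offsets with no reads are absent from the table.
    """
    sub = assigned[assigned["offset5"].abs() <= flank]
    dropped = int((sub["length"] > max_len).sum())
    if dropped:
        logger.info("length_by_initiation: %d reads longer than %d nt dropped", dropped, max_len)
    sub = sub[sub["length"] <= max_len]
    if sub.empty:
        return pd.DataFrame(columns=["offset5", "n_reads", "mean_length", "sem_length"])
    g = sub.groupby("offset5")["length"]
    out = pd.DataFrame(
        {
            "n_reads": g.size(),
            "mean_length": g.mean(),
            "sem_length": g.std(ddof=1) / np.sqrt(g.size()),
        }
    ).reset_index()
    return out


@dataclass
class InitiationClassProfile:
    """5'/3' metaprofiles for reads initiating in one offset band."""

    name: str
    band: tuple[int, int]
    n_reads: int
    profile5: np.ndarray
    profile3: np.ndarray
    flank: int
    underpowered: bool
    centroid5: float = float("nan")
    centroid3: float = float("nan")
    peak3: int | None = None


@dataclass
class InitiationClassResult:
    upstream: InitiationClassProfile
    downstream: InitiationClassProfile
    # mean 3' offset of the downstream class minus that of the upstream class;
    # the mean (rather than the profile argmax, which is also reported per
    # class) is used because the within-band initiation distributions are
    # skewed, which biases the mode as a location measure
    shift_statistic: float
    centroid_gap: float  # downstream 5' centroid minus upstream 5' centroid


def _class_profile(
    assigned: pd.DataFrame, name: str, band: tuple[int, int], flank: int, min_reads: int
) -> InitiationClassProfile:
    lo, hi = band
    sub = assigned[(assigned["offset5"] >= lo) & (assigned["offset5"] <= hi)]
    n = len(sub)
    width = 2 * flank + 1
    p5 = np.zeros(width, dtype=np.int64)
    p3 = np.zeros(width, dtype=np.int64)
    for off in sub["offset5"]:
        if -flank <= off <= flank:
            p5[off + flank] += 1
    for off in sub["offset3"]:
        if -flank <= off <= flank:
            p3[off + flank] += 1
    under = n < min_reads
    prof = InitiationClassProfile(name, band, n, p5, p3, flank, under)
    if not under:
        prof.centroid5 = float(sub["offset5"].mean())
        prof.centroid3 = float(sub["offset3"].mean())
        prof.peak3 = int(np.argmax(p3)) - flank
    return prof


def initiation_class_profiles(
    assigned: pd.DataFrame,
    upstream: tuple[int, int] = (-10, -5),
    downstream: tuple[int, int] = (5, 40),
    flank: int = 150,
    min_reads: int = 100,
) -> InitiationClassResult:
    """Compare pause positions of upstream- vs downstream-initiating RNAs.

    Class membership is determined solely by each read's 5' offset relative
    to its gene's final TSS; the band between the classes (around the TSS
    itself) is excluded.  The shift statistic is NaN when either class is
    underpowered.
    """
    up = _class_profile(assigned, "upstream", upstream, flank, min_reads)
    down = _class_profile(assigned, "downstream", downstream, flank, min_reads)
    if up.underpowered or down.underpowered:
        logger.warning(
            "initiation classes underpowered (upstream n=%d, downstream n=%d)",
            up.n_reads, down.n_reads,
        )
        return InitiationClassResult(up, down, float("nan"), float("nan"))
    shift = float(down.centroid3 - up.centroid3)
    gap = float(down.centroid5 - up.centroid5)
    logger.info(
        "initiation-class 3' shift %.1f nt vs 5' centroid gap %.1f nt", shift, gap
    )
    return InitiationClassResult(up, down, shift, gap)
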
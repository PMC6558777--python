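"""Sequence context extraction and position-wise information content.

Used for the initiator (Inr) motif check at called TSSs and the G/C
preference at RNA 3' ends.  Information content per offset is
``2 + sum_b f_b log2 f_b`` bits against a uniform background, with no
pseudocounts or small-sample correction; ambiguous bases are excluded per
offset, not per sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PositionFrequencyMatrix:
    """Base counts per offset; column j is offset j - flank."""

    counts: np.ndarray  # (2*flank+1) x 4, columns A,C,G,T
    flank: int
    n_sequences: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.offsets, columns=list(BASES))


def _chrom_seq(genome, chrom: str) -> str | None:
    """Fetch a full chromosome string from a Mapping or a pyfaidx.Fasta."""
    try:
        rec = genome[chrom]
    except KeyError:
        return None
    return str(rec) if not isinstance(rec, str) else rec


def extract_contexts(
    genome, positions: Sequence[int], strands: Sequence[str], chroms: Sequence[str], flank: int
) -> list[str]:
    """Strand-aware sequence windows of length 2*flank+1 centred on anchors.

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of chromosome name to
    sequence string.  Minus-strand anchors are reverse-complemented so the
    centre base is the template-directed initiation base.  Out-of-bounds or
    unknown-chromosome anchors are skipped with a warning.
    """
    cache: dict[str, str | None] = {}
    out: list[str] = []
    skipped = 0
    for chrom, pos, strand in zip(chroms, positions, strands):
        if chrom not in cache:
            cache[chrom] = _chrom_seq(genome, chrom)
            if cache[chrom] is None:
                logger.warning("extract_contexts: unknown chromosome %r", chrom)
        seq = cache[chrom]
        if seq is None:
            skipped += 1
            continue
        lo, hi = pos - flank, pos + flank + 1
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        window = seq[lo:hi].upper()
        out.append(window if strand == "+" else revcomp(window))
    if skipped:
        logger.warning("extract_contexts: skipped %d out-of-bounds/unknown anchors", skipped)
    return out


def pfm_from_sequences(sequences: Sequence[str], flank: int) -> PositionFrequencyMatrix:
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    for seq in sequences:
        if len(seq) != width:
            raise ValueError(f"sequence length {len(seq)} != {width}")
        for j, base in enumerate(seq):
            i = _BASE_INDEX.get(base)
            if i is not None:
                counts[j, i] += 1
    return PositionFrequencyMatrix(counts, flank, len(sequences))


def pfm_information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-offset information content in bits, in [0, 2]."""
    if pfm.n_sequences < 1:
        raise ValueError("PFM built from zero sequences")
    f = pfm.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log2(f), 0.0)
    return 2.0 + term.sum(axis=1)


def analytic_ic(probs: Sequence[float]) -> float:
    """IC of an exactly known base distribution (the n -> inf value)."""
    p = np.asarray(probs, dtype=float)
    return float(2.0 + np.sum(np.where(p > 0, p * np.log2(p), 0.0)))


def three_prime_context(
    genome, positions, strands, chroms, flank: int = 15
) -> tuple[PositionFrequencyMatrix, float]:
    """PFM anchored on each RNA's own 3' base, plus the G/C fraction there."""
    seqs = extract_contexts(genome, positions, strands, chroms, flank)
    pfm = pfm_from_sequences(seqs, flank)
    centre = pfm.counts[flank]
    total = centre.sum()
    gc = float((centre[_BASE_INDEX["G"]] + centre[_BASE_INDEX["C"]]) / total) if total else float("nan")
    return pfm, gc


def genome_gc_fraction(genome, chroms: Sequence[str]) -> float:
    total = gc = 0
    for chrom in chroms:
        seq = _chrom_seq(genome, chrom)
        if seq is None:
            continue
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        total += sum(s.count(b) for b in BASES)
    return gc / total if total else float("nan")
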
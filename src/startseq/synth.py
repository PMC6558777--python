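"""Synthetic Start-seq study generator with recorded ground truth.

Emits a toy genome, a (deliberately mis-)annotated gene set, stranded
short-capped-RNA reads for two replicates, and an expression table, together
with truth tables recording every planted quantity, so that each pipeline
stage has a recoverable answer:

* each gene has a true TSS; the annotation it is given is offset by a
  planted error ~ round(N(0, annotated_offset_sd)) in gene orientation;
* read 5' ends concentrate at the true TSS (``tss_purity`` exactly there,
  the rest spread geometrically on either side);
* read lengths follow one of two pause models: ``distance_anchored`` draws
  length ~ truncN(length_mean, length_sd) on [18, 47] independent of the
  start (upstream-initiating reads get ``upstream_length_bonus`` extra mean
  length), while ``sequence_anchored`` pins every 3' end to one genomic
  position (true TSS + 34) whatever the start;
* a fraction of genes carries divergent initiation 80-200 nt upstream and/or
  convergent initiation 200-250 nt downstream, both on the opposite strand;
* intergenic bidirectional elements are planted as opposite-strand summit
  pairs at least 5 kb from any gene;
* an initiator-like PWM is written into the genome at every planted TSS;
* FPKM is derived by inverting the pausing-index definition from a planted
  per-gene PI, with optional multiplicative noise.

Replicates are independent draws from the same gene-level parameters, with
replicate 2 at lower depth (as in typical paired library preparations), so
replicate-correlation checks have a planted positive correlation.  All
randomness flows from one seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AlignedRead, GeneRecord, revcomp, write_reads_bed
from .coverage import offset_to_genomic

logger = logging.getLogger(__name__)

# Invented initiator-style PWM: pyrimidine-rich -2/-1, strong A at 0,
# weak W at +2 and pyrimidine lean at +3/+4.  Offsets relative to the TSS.
INR_PWM: dict[int, tuple[float, float, float, float]] = {
    # offset: (A, C, G, T)
    -2: (0.10, 0.40, 0.10, 0.40),
    -1: (0.05, 0.45, 0.05, 0.45),
    0: (0.85, 0.05, 0.05, 0.05),
    1: (0.25, 0.25, 0.25, 0.25),
    2: (0.40, 0.10, 0.10, 0.40),
    3: (0.15, 0.35, 0.15, 0.35),
    4: (0.15, 0.35, 0.15, 0.35),
}

BASES = "ACGT"
DISTANCE_ANCHORED = "distance_anchored"
SEQUENCE_ANCHORED = "sequence_anchored"


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; the defaults are the study conditions."""

    seed: int
    n_chrom: int = 2
    chrom_length: int = 700_000
    gc_content: float = 0.42
    n_genes: int = 200
    gene_length: int = 2000
    min_gene_gap: int = 1000
    promoter_margin: int = 600
    annotated_offset_sd: float = 20.0
    # per-gene sense read count: exp(N(mu, sigma)) floored at min_reads
    reads_lognorm_mu: float = float(np.log(150.0))
    reads_lognorm_sigma: float = 0.7
    min_reads_per_gene: int = 50
    replicate_depths: tuple[float, ...] = (1.0, 0.7)
    tss_purity: float = 0.9
    offtss_geom_p: float = 0.3
    length_mode: str = DISTANCE_ANCHORED
    length_mean: float = 35.0
    length_sd: float = 5.0
    length_min: int = 18
    length_max: int = 47
    upstream_length_bonus: float = 2.5
    divergent_fraction: float = 0.9
    divergent_offset_range: tuple[int, int] = (80, 200)
    divergent_lognorm_mu: float = float(np.log(30.0))
    divergent_lognorm_sigma: float = 0.6
    convergent_fraction: float = 0.35
    convergent_offset_range: tuple[int, int] = (200, 250)
    convergent_lognorm_mu: float = float(np.log(20.0))
    convergent_lognorm_sigma: float = 0.6
    antisense_purity: float = 0.8
    n_elements: int = 20
    element_reads: int = 25
    element_gap_range: tuple[int, int] = (100, 400)
    element_margin: int = 5000
    noise_rate_per_kb: float = 0.05
    pi_lognorm_mu: float = float(np.log(50.0))
    pi_lognorm_sigma: float = 1.0
    fpkm_noise_sd: float = 0.1
    inr_pwm: dict = field(default_factory=lambda: dict(INR_PWM))

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.length_mode not in (DISTANCE_ANCHORED, SEQUENCE_ANCHORED):
            raise ValueError(f"unknown length_mode {self.length_mode!r}")
        if not 0 <= self.tss_purity <= 1:
            raise ValueError("tss_purity must be in [0,1]")
        for lo, hi in (self.divergent_offset_range, self.convergent_offset_range,
                       self.element_gap_range):
            if lo > hi:
                raise ValueError("invalid range")


@dataclass
class SimBundle:
    """Everything one synthetic study produced, in memory."""

    config: GeneratorConfig
    genome: dict[str, str]
    genes: list[GeneRecord]  # the (mis-)annotated records fed to the pipeline
    truth_genes: pd.DataFrame
    truth_elements: pd.DataFrame
    reads: list[list[AlignedRead]] | None = None  # per replicate
    expression: pd.DataFrame | None = None


def _trunc_normal_int(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Rounded normal draws redrawn until inside [lo, hi]."""
    out = np.rint(rng.normal(mean, sd, size)).astype(int)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.normal(np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                                      sd, int(bad.sum()))).astype(int)
        bad = (out < lo) | (out > hi)
    return out


def _rng(cfg: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


def generate_genome_and_genes(cfg: GeneratorConfig) -> SimBundle:
    """Lay out genes and elements, draw the genome, plant Inr motifs.

    Genes are packed left to right with fixed margins plus a small random
    jitter; intergenic elements follow the genes on each chromosome with a
    wide safety margin.  Raises when the requested counts cannot fit.
    """
    rng = _rng(cfg, 0)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    genes_per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        genes_per_chrom[i] += 1
    elems_per_chrom = [cfg.n_elements // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_elements % cfg.n_chrom):
        elems_per_chrom[i] += 1

    slot = cfg.gene_length + 2 * cfg.promoter_margin + cfg.min_gene_gap
    for ci, (ng, ne) in enumerate(zip(genes_per_chrom, elems_per_chrom)):
        need = 1000 + ng * (slot + 200) + cfg.element_margin + ne * (
            cfg.element_gap_range[1] + cfg.element_margin
        )
        if need > cfg.chrom_length:
            raise ValueError(
                f"chromosome {ci + 1} too short: need ~{need} nt, have {cfg.chrom_length}"
            )

    gene_rows = []
    elem_rows = []
    gi = 0
    for chrom, ng, ne in zip(chroms, genes_per_chrom, elems_per_chrom):
        cursor = 1000
        for _ in range(ng):
            jitter = int(rng.integers(0, 200))
            strand = "+" if rng.random() < 0.5 else "-"
            body_start = cursor + cfg.promoter_margin + jitter
            body_end = body_start + cfg.gene_length
            true_tss = body_start if strand == "+" else body_end - 1
            ann_off = int(np.rint(rng.normal(0, cfg.annotated_offset_sd)))
            ann_off = int(np.clip(ann_off, -3 * cfg.annotated_offset_sd - 1,
                                  3 * cfg.annotated_offset_sd + 1))
            annotated_tss = offset_to_genomic(true_tss, ann_off, strand)
            gene_rows.append(
                dict(
                    gene_id=f"g{gi:05d}", chrom=chrom, strand=strand,
                    true_tss=true_tss, annotated_tss=annotated_tss,
                    annotated_offset=ann_off, body_start=body_start,
                    body_end=body_end,
                )
            )
            gi += 1
            cursor += slot + jitter
        cursor += cfg.element_margin
        for ei in range(ne):
            gap = int(rng.integers(cfg.element_gap_range[0], cfg.element_gap_range[1] + 1))
            # minus-strand summit on the left, plus-strand on the right:
            # transcription points away from the element centre, as at enhancers
            elem_rows.append(
                dict(
                    element_id=f"e_{chrom}_{ei}", chrom=chrom,
                    summit_minus=cursor, summit_plus=cursor + gap,
                )
            )
            cursor += gap + cfg.element_margin
        if cursor > cfg.chrom_length:
            raise ValueError(f"packing overflow on {chrom}")

    truth_genes = pd.DataFrame(gene_rows)
    truth_elements = pd.DataFrame(
        elem_rows, columns=["element_id", "chrom", "summit_minus", "summit_plus"]
    )

    # genome: iid bases at the requested GC, then motif bases at true TSSs
    p = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                  cfg.gc_content / 2, (1 - cfg.gc_content) / 2])
    genome: dict[str, list[str]] = {}
    base_arr = np.array(list(BASES))
    for chrom in chroms:
        draws = rng.choice(4, size=cfg.chrom_length, p=p)
        genome[chrom] = list(base_arr[draws])
    for row in gene_rows:
        seq_list = genome[row["chrom"]]
        for off in sorted(cfg.inr_pwm):
            probs = np.asarray(cfg.inr_pwm[off], dtype=float)
            base = BASES[rng.choice(4, p=probs / probs.sum())]
            gpos = offset_to_genomic(row["true_tss"], off, row["strand"])
            if row["strand"] == "-":
                base = revcomp(base)
            seq_list[gpos] = base
    genome_str = {c: "".join(s) for c, s in genome.items()}

    genes = [
        _annotated_record(row, cfg)
        for row in gene_rows
    ]
    logger.info(
        "generated %d genes and %d elements on %d chromosomes of %d nt",
        len(genes), len(elem_rows), cfg.n_chrom, cfg.chrom_length,
    )
    return SimBundle(cfg, genome_str, genes, truth_genes, truth_elements)


def _annotated_record(row: dict, cfg: GeneratorConfig) -> GeneRecord:
    """GeneRecord as the annotation sees it: body anchored at the annotated TSS."""
    if row["strand"] == "+":
        start = row["annotated_tss"]
        end = start + cfg.gene_length
    else:
        end = row["annotated_tss"] + 1
        start = end - cfg.gene_length
    return GeneRecord(row["gene_id"], row["chrom"], row["strand"], start, end)


def _draw_lengths(rng, cfg: GeneratorConfig, offsets: np.ndarray) -> np.ndarray:
    """Length draws under the distance-anchored model for given 5' offsets."""
    mean = np.where(offsets < 0, cfg.length_mean + cfg.upstream_length_bonus,
                    cfg.length_mean)
    out = np.rint(rng.normal(mean, cfg.length_sd)).astype(int)
    bad = (out < cfg.length_min) | (out > cfg.length_max)
    while bad.any():
        out[bad] = np.rint(rng.normal(mean[bad], cfg.length_sd)).astype(int)
        bad = (out < cfg.length_min) | (out > cfg.length_max)
    return out


def _draw_offsets(rng, cfg: GeneratorConfig, n: int, purity: float) -> np.ndarray:
    offs = np.zeros(n, dtype=int)
    spread = rng.random(n) >= purity
    k = int(spread.sum())
    if k:
        mag = rng.geometric(cfg.offtss_geom_p, k)
        sign = np.where(rng.random(k) < 0.5, -1, 1)
        offs[spread] = mag * sign
    return offs


def _emit_reads(chrom, strand, anchor, offsets, lengths) -> list[AlignedRead]:
    reads = []
    for off, L in zip(offsets, lengths):
        p5 = offset_to_genomic(anchor, int(off), strand)
        if strand == "+":
            reads.append(AlignedRead(chrom, p5, p5 + int(L), "+"))
        else:
            reads.append(AlignedRead(chrom, p5 - int(L) + 1, p5 + 1, "-"))
    return reads


def simulate_startseq(cfg: GeneratorConfig, bundle: SimBundle) -> list[list[AlignedRead]]:
    """Draw per-replicate stranded reads for genes, antisense, elements, noise.

    Updates ``bundle.truth_genes`` with per-replicate sense read counts and the
    planted antisense calls, and stores the reads on the bundle.
    """
    rng = _rng(cfg, 1)
    tg = bundle.truth_genes
    n_rep = len(cfg.replicate_depths)
    replicates: list[list[AlignedRead]] = [[] for _ in range(n_rep)]

    opp = {"+": "-", "-": "+"}
    div_present = rng.random(len(tg)) < cfg.divergent_fraction
    div_offset = rng.integers(cfg.divergent_offset_range[0],
                              cfg.divergent_offset_range[1] + 1, len(tg))
    conv_present = rng.random(len(tg)) < cfg.convergent_fraction
    conv_offset = rng.integers(cfg.convergent_offset_range[0],
                               cfg.convergent_offset_range[1] + 1, len(tg))

    base_n = np.maximum(
        cfg.min_reads_per_gene,
        np.rint(rng.lognormal(cfg.reads_lognorm_mu, cfg.reads_lognorm_sigma, len(tg))),
    ).astype(int)
    div_n = np.rint(rng.lognormal(cfg.divergent_lognorm_mu,
                                  cfg.divergent_lognorm_sigma, len(tg))).astype(int)
    conv_n = np.rint(rng.lognormal(cfg.convergent_lognorm_mu,
                                   cfg.convergent_lognorm_sigma, len(tg))).astype(int)

    for r, depth in enumerate(cfg.replicate_depths):
        n_sense_col = np.zeros(len(tg), dtype=int)
        purity_col = np.zeros(len(tg))
        for i, row in enumerate(tg.itertuples()):
            strand, chrom, t = row.strand, row.chrom, row.true_tss
            n = max(1, int(np.rint(base_n[i] * depth * rng.lognormal(0, 0.1))))
            offs = _draw_offsets(rng, cfg, n, cfg.tss_purity)
            if cfg.length_mode == DISTANCE_ANCHORED:
                lens = _draw_lengths(rng, cfg, offs)
            else:
                # pin each 3' end to true_tss + 34 (gene orientation); redraw
                # initiation offsets whose implied length is unsequenceable
                lens = 35 - offs
                bad = (lens < cfg.length_min) | (lens > cfg.length_max)
                while bad.any():
                    offs[bad] = _draw_offsets(rng, cfg, int(bad.sum()), cfg.tss_purity)
                    lens = 35 - offs
                    bad = (lens < cfg.length_min) | (lens > cfg.length_max)
            replicates[r].extend(_emit_reads(chrom, strand, t, offs, lens))
            n_sense_col[i] = n
            purity_col[i] = float((offs == 0).mean())

            a_strand = opp[strand]
            if div_present[i] and div_n[i] > 0:
                nd = max(1, int(np.rint(div_n[i] * depth)))
                p_div = offset_to_genomic(t, -int(div_offset[i]), strand)
                aoffs = _draw_offsets(rng, cfg, nd, cfg.antisense_purity)
                alens = _draw_lengths(rng, cfg, np.zeros(nd, dtype=int))
                replicates[r].extend(_emit_reads(chrom, a_strand, p_div, aoffs, alens))
                tg.loc[tg.index[i], f"divergent_n_rep{r + 1}"] = nd
            if conv_present[i] and conv_n[i] > 0:
                nc = max(1, int(np.rint(conv_n[i] * depth)))
                p_conv = offset_to_genomic(t, int(conv_offset[i]), strand)
                aoffs = _draw_offsets(rng, cfg, nc, cfg.antisense_purity)
                alens = _draw_lengths(rng, cfg, np.zeros(nc, dtype=int))
                replicates[r].extend(_emit_reads(chrom, a_strand, p_conv, aoffs, alens))
                tg.loc[tg.index[i], f"convergent_n_rep{r + 1}"] = nc
        tg[f"n_sense_rep{r + 1}"] = n_sense_col
        tg[f"tss_purity_rep{r + 1}"] = purity_col

        for erow in bundle.truth_elements.itertuples():
            for strand, summit in (("-", erow.summit_minus), ("+", erow.summit_plus)):
                ne = max(1, int(np.rint(cfg.element_reads * depth)))
                offs = _draw_offsets(rng, cfg, ne, 0.95)
                lens = _draw_lengths(rng, cfg, np.zeros(ne, dtype=int))
                replicates[r].extend(_emit_reads(erow.chrom, strand, summit, offs, lens))

        n_noise = int(np.rint(cfg.noise_rate_per_kb * cfg.chrom_length / 1000 * depth))
        for chrom in bundle.genome:
            pos = rng.integers(100, cfg.chrom_length - 100, n_noise)
            strands = np.where(rng.random(n_noise) < 0.5, "+", "-")
            lens = _draw_lengths(rng, cfg, np.zeros(n_noise, dtype=int))
            for p5, s, L in zip(pos, strands, lens):
                replicates[r].extend(_emit_reads(chrom, str(s), int(p5), [0], [int(L)]))

    for r in range(n_rep):
        logger.info("replicate %d: %d reads", r + 1, len(replicates[r]))
    tg["divergent_present"] = div_present & (div_n > 0)
    tg["divergent_offset"] = np.where(div_present, div_offset, np.nan)
    tg["convergent_present"] = conv_present & (conv_n > 0)
    tg["convergent_offset"] = np.where(conv_present, conv_offset, np.nan)
    bundle.reads = replicates
    return replicates


def simulate_expression(cfg: GeneratorConfig, bundle: SimBundle,
                        replicate: int = 0) -> pd.DataFrame:
    """Invert the pausing-index definition to give each gene a recoverable PI.

    FPKM = (sense window-equivalent count of the chosen replicate) /
    planted_PI, times exp(N(0, fpkm_noise_sd)).  Also emits a raw
    counts+lengths variant (library_total column constant) from which the
    standard FPKM formula approximately reproduces the table.
    """
    if bundle.reads is None:
        raise ValueError("simulate_startseq must run first")
    rng = _rng(cfg, 2)
    tg = bundle.truth_genes
    counts = tg[f"n_sense_rep{replicate + 1}"].to_numpy(dtype=float)
    planted_pi = rng.lognormal(cfg.pi_lognorm_mu, cfg.pi_lognorm_sigma, len(tg))
    noise = (
        np.exp(rng.normal(0.0, cfg.fpkm_noise_sd, len(tg)))
        if cfg.fpkm_noise_sd > 0
        else np.ones(len(tg))
    )
    fpkm = counts / planted_pi * noise
    lengths = rng.integers(1000, 5001, len(tg))
    library_total = 2e7
    raw_counts = np.rint(fpkm * library_total * lengths / 1e9).astype(int)
    expr = pd.DataFrame(
        dict(
            gene_id=tg["gene_id"],
            fpkm=fpkm,
            planted_pi=planted_pi,
            rnaseq_count=raw_counts,
            transcript_length=lengths,
            library_total=library_total,
        )
    )
    tg["planted_pi"] = planted_pi
    tg["fpkm"] = fpkm
    bundle.expression = expr
    return expr


def simulate_all(cfg: GeneratorConfig, outdir: str | Path | None = None) -> SimBundle:
    """Run the whole generator; optionally write every artifact to ``outdir``."""
    bundle = generate_genome_and_genes(cfg)
    simulate_startseq(cfg, bundle)
    simulate_expression(cfg, bundle)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(genes: list[GeneRecord], path: str | Path, source: str = "synth") -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body_start + 1}\t{g.body_end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
            )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "annotation": str(outdir / "genes.gtf"),
        "fpkm": str(outdir / "fpkm.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "truth_genes": str(outdir / "truth_genes.tsv"),
        "truth_elements": str(outdir / "truth_elements.tsv"),
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gtf(bundle.genes, paths["annotation"])
    reads_paths = []
    for r, reads in enumerate(bundle.reads or []):
        p = str(outdir / f"reads_rep{r + 1}.bed")
        write_reads_bed(reads, p)
        reads_paths.append(p)
    paths["reads"] = reads_paths
    if bundle.expression is not None:
        bundle.expression[["gene_id", "fpkm"]].to_csv(
            paths["fpkm"], sep="\t", index=False
        )
        bundle.expression[
            ["gene_id", "rnaseq_count", "transcript_length", "library_total"]
        ].to_csv(paths["counts"], sep="\t", index=False)
    bundle.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    bundle.truth_elements.to_csv(paths["truth_elements"], sep="\t", index=False)
    manifest = {"config": _config_dict(bundle.config), "paths": paths}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["inr_pwm"] = {str(k): list(v) for k, v in d["inr_pwm"].items()}
    return d
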
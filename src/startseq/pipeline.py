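"""One-command orchestration of the full Start-seq analysis.

Stages run in order core_io -> coverage -> tss -> antisense -> pausing ->
motif -> elements.  Optional inputs degrade gracefully: no expression table
skips the pausing stage, no genome skips motifs, an external peak BED
replaces the internal caller.  Every parameter is echoed into a run manifest
and the funnel counts (genes above noise, genes passing the distance filter,
shift classes, antisense calls, peak/region tallies) land in a summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import antisense as anti
from . import coverage as covmod
from . import elements as elmod
from . import motif as motmod
from . import pausing as pausemod
from . import tss as tssmod
from .core_io import (
    IntervalSet,
    filter_blacklist,
    load_gene_annotation,
    load_reads,
    write_bedgraph,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("tss", "antisense", "pausing", "motif", "elements")


@dataclass
class RunConfig:
    """Paths and every stage parameter, with the pipeline defaults."""

    reads: list[str]
    annotation: str
    outdir: str
    genome: str | None = None
    expression: str | None = None
    assembled_gtf: str | None = None
    blacklist: str | None = None
    peaks: str | None = None  # external peak BED replaces the internal caller
    window: int = 500
    noise_threshold: int = 10
    antisense_window: int = 500
    antisense_flank: int = 50
    three_prime_flank: int = 150
    class_upstream: tuple[int, int] = (-10, -5)
    class_downstream: tuple[int, int] = (5, 40)
    class_min_reads: int = 100
    max_len: int = 47
    promoter_exclusion: int = 3000
    merge_gap: int = 3000
    peak_min_count: int = 10
    peak_min_separation: int = 150
    motif_flank: int = 15
    primary_replicate: int | None = None  # None = highest-coverage replicate
    write_bedgraphs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("class_upstream", "class_downstream"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_expression(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if "fpkm" in df.columns:
        return dict(zip(df["gene_id"], df["fpkm"].astype(float)))
    required = {"rnaseq_count", "transcript_length", "library_total"}
    if required <= set(df.columns):
        fpkm = pausemod.compute_fpkm(
            df["rnaseq_count"], df["transcript_length"], float(df["library_total"].iloc[0])
        )
        return dict(zip(df["gene_id"], fpkm))
    raise ValueError(f"{path}: need an 'fpkm' column or counts+lengths+library_total")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute the pipeline and write all result tables under ``config.outdir``.

    Returns a result bundle: the reannotation table, stage outputs and the
    summary dict (also written as summary.json).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    results: dict = {"summary": summary}

    genes = load_gene_annotation(config.annotation)
    replicates = [load_reads(p) for p in config.reads]
    if config.blacklist:
        mask = IntervalSet.from_bed(config.blacklist)
        replicates = [filter_blacklist(r, mask) for r in replicates]
    summary["n_genes_annotated"] = len(genes)
    summary["n_reads_per_replicate"] = [len(r) for r in replicates]

    cov5 = [covmod.build_end_coverage(r, covmod.FIVE_PRIME) for r in replicates]
    cov3 = [covmod.build_end_coverage(r, covmod.THREE_PRIME) for r in replicates]

    # -- TSS reannotation (always runs: everything downstream anchors on it)
    tss_cfg = tssmod.TssConfig(
        window=config.window,
        noise_threshold=config.noise_threshold,
        primary_replicate=config.primary_replicate,
    )
    tss_table = tssmod.reannotate_tss(genes, cov5, tss_cfg)
    primary = tss_table.attrs.get("primary_replicate", 0)
    tss_table.to_csv(out / "tss_table.tsv", sep="\t", index=False)
    tssmod.write_tss_bed(tss_table, out / "tss.bed")
    results["tss_table"] = tss_table
    summary["primary_replicate"] = int(primary) + 1
    summary["n_genes_above_noise"] = int(tss_table["noise_pass"].sum())
    summary["n_genes_pass"] = int((tss_table["status"] == "pass").sum())
    summary["n_identical"] = int(tss_table["identical"].sum())
    summary["n_within_5"] = int(tss_table["within_5"].sum())
    summary["n_within_10"] = int(tss_table["within_10"].sum())
    summary["n_reannotated_gt_5"] = int(tss_table["gt_5"].sum())
    summary["offset_fits"] = [
        {"mean": f.mean, "sd": f.sd, "n": f.n} for f in tss_table.attrs["offset_fits"]
    ]
    anchors = tssmod.passing_tss_anchors(tss_table)

    if config.write_bedgraphs:
        for r, (c5, c3) in enumerate(zip(cov5, cov3)):
            for cov, end in ((c5, "five"), (c3, "three")):
                for strand, sname in (("+", "plus"), ("-", "minus")):
                    write_bedgraph(
                        cov, strand, out / f"rep{r + 1}.{end}prime.{sname}.bedgraph"
                    )

    pass_tbl = tss_table[tss_table["status"] == "pass"].reset_index(drop=True)

    if "antisense" in stages:
        as_table = anti.call_antisense_table(
            cov5[primary], anchors, config.antisense_window, config.noise_threshold
        )
        as_table.to_csv(out / "antisense.tsv", sep="\t", index=False)
        results["antisense"] = as_table
        summary["n_divergent"] = int((as_table["kind"] == "divergent").sum())
        summary["n_convergent"] = int((as_table["kind"] == "convergent").sum())

        vectors: dict[str, np.ndarray] = {}
        for r in range(len(cov5)):
            vectors[f"sense_rep{r + 1}"] = pass_tbl[f"window_count_rep{r + 1}"].to_numpy(
                dtype=float
            )
        for kind in (anti.DIVERGENT, anti.CONVERGENT):
            for r, cov in enumerate(cov5):
                vals = []
                for chrom, tssp, strand, _gid in anchors:
                    call = anti.call_antisense_tss(
                        cov, chrom, tssp, strand, kind,
                        window=config.antisense_window,
                        threshold=config.noise_threshold,
                    )
                    vals.append(call.flank50_count if call else np.nan)
                vectors[f"{kind}_rep{r + 1}"] = np.asarray(vals)
        corr = anti.antisense_correlation_matrix(vectors)
        corr.to_csv(out / "antisense_correlation.tsv", sep="\t")
        results["antisense_correlation"] = corr

    fpkm_map: dict[str, float] | None = None
    if config.expression:
        fpkm_map = _load_expression(config.expression)
    if "pausing" in stages and fpkm_map is None:
        logger.warning("no expression table: pausing stage skipped")
    if "pausing" in stages and fpkm_map is not None:
        pi_table = pausemod.pausing_table(
            tss_table, fpkm_map, count_col=f"window_count_rep{primary + 1}"
        )
        pi_table.to_csv(out / "pausing.tsv", sep="\t", index=False)
        results["pausing"] = pi_table
        summary["n_pi_genes"] = int(pi_table["pausing_index"].notna().sum())

        profile, peak = pausemod.three_prime_metaprofile(
            cov3[primary], anchors, config.three_prime_flank
        )
        fpkm_vec = np.array(
            [fpkm_map.get(a[3].rsplit(".", 1)[0], np.nan) for a in anchors]
        )
        prof_df = pd.DataFrame(
            {
                "offset": np.arange(-config.three_prime_flank, config.three_prime_flank + 1),
                "count_all": profile,
            }
        )
        ok = ~np.isnan(fpkm_vec)
        if ok.sum() >= 4:
            top = pausemod.top_quartile_anchors(
                [a for a, k in zip(anchors, ok) if k], fpkm_vec[ok]
            )
            prof_top, _ = pausemod.three_prime_metaprofile(
                cov3[primary], top, config.three_prime_flank
            )
            prof_df["count_top_quartile"] = prof_top
        prof_df.to_csv(out / "three_prime_profile.tsv", sep="\t", index=False)
        results["three_prime_profile"] = prof_df
        summary["three_prime_peak_offset"] = int(peak)

        assigned = pausemod.assign_reads_to_genes(
            replicates[primary], anchors, config.three_prime_flank
        )
        results["assigned_reads"] = assigned
        lbp = pausemod.length_by_initiation(
            assigned, config.three_prime_flank, config.max_len
        )
        lbp.to_csv(out / "length_by_initiation.tsv", sep="\t", index=False)
        results["length_by_initiation"] = lbp
        classes = pausemod.initiation_class_profiles(
            assigned[assigned["length"] <= config.max_len],
            config.class_upstream,
            config.class_downstream,
            config.three_prime_flank,
            config.class_min_reads,
        )
        results["initiation_classes"] = classes
        summary["initiation_class_shift"] = classes.shift_statistic
        summary["initiation_class_centroid_gap"] = classes.centroid_gap
        with open(out / "initiation_classes.tsv", "w") as fh:
            fh.write("class\tband\tn_reads\tcentroid5\tcentroid3\tpeak3\tunderpowered\n")
            for prof in (classes.upstream, classes.downstream):
                fh.write(
                    f"{prof.name}\t{prof.band[0]}..{prof.band[1]}\t{prof.n_reads}"
                    f"\t{prof.centroid5}\t{prof.centroid3}\t{prof.peak3}\t{prof.underpowered}\n"
                )

    if "motif" in stages:
        if not config.genome:
            logger.warning("no genome FASTA: motif stage skipped")
        else:
            import pyfaidx

            genome = pyfaidx.Fasta(config.genome)
            for label, use_final in (("reannotated", True), ("annotated", False)):
                if use_final:
                    chroms = [a[0] for a in anchors]
                    poss = [a[1] for a in anchors]
                    strands = [a[2] for a in anchors]
                else:
                    chroms = pass_tbl["chrom"].tolist()
                    poss = pass_tbl["annotated_tss"].tolist()
                    strands = pass_tbl["strand"].tolist()
                seqs = motmod.extract_contexts(
                    genome, poss, strands, chroms, config.motif_flank
                )
                pfm = motmod.pfm_from_sequences(seqs, config.motif_flank)
                ic = motmod.pfm_information_content(pfm)
                df = pfm.to_frame()
                df["ic_bits"] = ic
                df.to_csv(out / f"inr_pfm_{label}.tsv", sep="\t", index_label="offset")
                summary[f"inr_ic_center_{label}"] = float(ic[config.motif_flank])
                results[f"pfm_{label}"] = pfm

            if "pausing" in stages and fpkm_map is not None:
                p3 = [
                    covmod.read_end_position(r, covmod.THREE_PRIME)
                    for r in replicates[primary]
                ]
                p3chroms = [r.chrom for r in replicates[primary]]
                p3strands = [r.strand for r in replicates[primary]]
                pfm3, gc = motmod.three_prime_context(
                    genome, p3, p3strands, p3chroms, config.motif_flank
                )
                pfm3.to_frame().to_csv(
                    out / "three_prime_pfm.tsv", sep="\t", index_label="offset"
                )
                summary["three_prime_gc_fraction"] = gc
                results["pfm_three_prime"] = pfm3

    if "elements" in stages:
        if config.peaks:
            peaks = elmod.load_peaks_bed(config.peaks)
        else:
            peaks = elmod.call_strand_peaks(
                cov5[primary], config.peak_min_count, config.peak_min_separation
            )
        summary["n_peaks"] = len(peaks)
        tss_list = [(g.chrom, g.tss) for g in genes]
        if config.assembled_gtf:
            asm = load_gene_annotation(config.assembled_gtf)
            tss_list += [(g.chrom, g.tss) for g in asm]
        nongenic = elmod.filter_promoter_proximal(
            peaks, tss_list, config.promoter_exclusion
        )
        regions = elmod.merge_bidirectional(nongenic, config.merge_gap)
        elmod.write_peaks_bed(nongenic, out / "nongenic_peaks.bed")
        elmod.write_regions(
            regions, out / "bidirectional.bed", out / "bidirectional.tsv"
        )
        results["peaks"] = nongenic
        results["regions"] = regions
        summary["n_nongenic_peaks"] = len(nongenic)
        summary["n_bidirectional_regions"] = len(regions)

        if config.assembled_gtf:
            novel = elmod.select_novel_transcripts(config.assembled_gtf, config.annotation)
            summary["n_intergenic_transcripts"] = novel["n_intergenic"]
            summary["n_novel_multi_exon"] = novel["n_multi_exon"]
            pd.DataFrame(
                {
                    "transcript_id": novel["intergenic"],
                    "multi_exon": [t in set(novel["multi_exon"]) for t in novel["intergenic"]],
                }
            ).to_csv(out / "novel_transcripts.tsv", sep="\t", index=False)
            results["novel_transcripts"] = novel

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": config.to_dict(), "stages": list(stages)}, fh, indent=2)
    return results
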
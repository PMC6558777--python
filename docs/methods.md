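# Methods

## Data model and coordinate conventions

All genomic coordinates are 0-based, half-open (BED convention); GTF input
(1-based, end-inclusive) is converted on load. A gene's TSS is `body_start`
on the plus strand and `body_end − 1` on the minus strand. All offsets are
*anchor-oriented*: positive offsets point downstream in the orientation of
the anchoring gene or read, so on a minus-strand gene "+35" means 35 nt
toward lower genomic coordinates. Windows written "±N" include both boundary
offsets (a ±500 bp window covers 1001 positions); whether the upstream tool
chain that inspired these windows included its boundaries is not knowable, so
inclusivity is fixed here as a package convention and applied uniformly.

End coverage is held sparsely as per-(chromosome, strand) maps of position →
count of read 5′ or 3′ termini, so toy genomes and full mammalian genomes use
the same code path. The 5′ terminus of a read is `start` (+) or `end − 1`
(−); the 3′ terminus is the opposite end.

Genes that share an id but have distinct TSSs are retained as separate
analysis units keyed by (gene_id, occurrence index) rather than collapsed;
result tables carry both.

## TSS reannotation

Per replicate and gene: the sense-strand position with the most read 5′ ends
within ±500 bp of the annotated TSS is the observed peak; ties are broken by
smallest absolute offset, then upstream (these ties are rare and the rule is
deterministic). Genes with fewer than 10 sense-strand reads in the window in
*any* replicate are discarded as noise. The signed peak offsets of the
surviving genes are fitted per replicate to a normal distribution (plain
sample mean and SD, ddof 1 — no trimming, since nothing in the procedure
requires robustness beyond the noise filter), and a gene is kept only when
every replicate's offset satisfies |offset − mean| ≤ SD. The "1 SD" rule is
interpreted as a symmetric one-sided bound each way (`distance_rule` in
config); a zero-SD fit is refused as degenerate rather than silently passing
everything. The final TSS is the peak of the primary replicate — by default
the replicate with the larger genome-wide read total, overridable — and the
shift magnitude |final − annotated| is summarised with the flags *identical*,
*within 5 nt*, *within 10 nt*, *shifted by >5 nt* (these overlap by design, so
they are flags, not a partition).

The noise filter window is centred on the *annotated* TSS, matching the order
of operations (the noise filter precedes reannotation).

## Antisense calling

Divergent and convergent TSSs are the opposite-strand 5′-end maxima in the
one-sided windows [−500, −1] and [+1, +500] around the final sense TSS
(offset 0 is excluded from both so the searches are disjoint). A call is
made only when the one-sided opposite-strand window total reaches the same
10-read threshold used for sense noise — the thresholded quantity is the
window total, not the peak height, keeping the two filters symmetric. Calls
are quantified by the ±50 nt opposite-strand count around the called peak,
and sense/antisense correlation matrices use Spearman correlation with
pairwise-complete observations (cells with <3 complete pairs are missing).

## Pausing

`FPKM = count × 10⁹ / (library_total × length)`;
`PI = (sense 5′-end count, TSS ± 500 bp) / FPKM`. Genes with zero FPKM get a
missing PI, not an infinite one, and are logged. PI is scale-equivariant:
doubling Start-seq depth doubles PI; doubling RNA-seq depth halves it.

3′-end metaprofiles are column sums of the anchor × offset matrix over
±150 nt around final TSSs; the reported pause position is the profile argmax.
A top-expression-quartile sub-profile uses FPKM rank over the passing genes.

For initiation-anchored analyses each read is assigned to at most one gene:
same strand, 5′ end within ±150 nt of the final TSS, nearest TSS winning and
coordinate ties going to the upstream gene. Because the sequencing insert
length caps measurable RNA length at 47 nt, reads longer than 47 nt are
excluded from length statistics (counted and logged). Length-by-initiation
tables report per-offset mean, SEM (ddof 1) and n.

The initiation-class analysis compares RNAs initiating in the upstream
[−10, −5] and downstream [+5, +40] bands (band membership is decided solely
by each read's 5′ offset; the band between them, around the TSS itself, is
excluded; all bounds configurable). Under a *sequence-anchored* pause model
all RNAs of a gene end at one genomic position, so the classes' 3′-end
locations coincide; under a *distance-anchored* model RNA length is conserved
instead, so the classes' 3′ ends separate by the gap between their initiation
centroids. The shift statistic is the difference of the per-class **mean** 3′
offsets. The per-class 3′ profile argmax is also computed and reported, but
the mean is the statistic: within-band initiation densities are skewed, which
makes the profile mode a biased location measure, whereas the mean equals the
centroid gap exactly under distance anchoring and zero exactly under sequence
anchoring. Classes with fewer than 100 reads (configurable) are flagged
underpowered and yield no statistic.

## Motif analysis

Sequence contexts are strand-aware windows of length 2·flank+1 (default
flank 15; logo-style summaries in tests use 10) centred on anchors, with
minus-strand anchors reverse-complemented. Information content per offset is
`2 + Σ_b f_b log₂ f_b` bits against a uniform background with no pseudocounts
and no small-sample correction; ambiguous bases are excluded per offset, not
per sequence. The expected small-sample bias is ≈ 3/(2 ln2 · n) bits and is
accounted for explicitly where near-zero IC is asserted. The 3′-end context
analysis anchors a PFM on each read's own 3′ base and reports the G/C
fraction at offset 0 against the genome-wide G/C fraction.

## Non-genic elements

The internal peak caller is a deliberately simple, documented greedy
procedure: per chromosome and strand, candidate positions with ≥10 read 5′
ends are visited in descending count (ties left to right) and accepted when
≥150 nt from every previously accepted summit on that strand; the peak
interval is the contiguous nonzero run through the summit clipped to
±150 nt. An externally produced peak BED can be supplied instead, keeping
the downstream filter/merge stages comparable across peak callers. Peaks
whose summit lies within ±3 kb (inclusive, summit-based) of any known or
assembled-transcript TSS are excluded. Remaining peaks are chained when
consecutive summits are ≤3 kb apart; each maximal chain of ≥2 peaks
containing at least one adjacent opposite-strand pair becomes a bidirectional
region spanning its members' intervals. "Adjacent" means
consecutive-in-coordinate order (chains, not cliques), so the emitted regions
are non-overlapping and partition the chained peaks.

Novel-transcript filtering calls an assembled transcript intergenic iff none
of its exons shares a base with any known gene body (strand-agnostic — the
conservative reading of "intergenic"), and retains only multi-exon intergenic
transcripts as novel-gene candidates, because short-read assemblers
over-report single-exon fragments.

## Synthetic study generator

The generator emulates the data structure the pipeline consumes, with every
planted value recorded in truth tables:

| parameter | default | rationale |
|---|---|---|
| annotated TSS error | round(N(0, 20)) nt, clipped at ±3 SD | an appreciable fraction of genes misannotated by >5 bp |
| reads/gene | lognormal(ln 150, 0.7), floor 50 | promoter-window counts spanning ~2 orders of magnitude |
| replicate depths | (1.0, 0.7) | replicate 2 at lower depth, as in paired library preps |
| TSS purity | 0.9 | fraction of 5′ ends exactly at the true TSS |
| off-TSS spread | geometric(0.3), random sign | single-parameter, heavy-at-centre initiation scatter |
| RNA length | truncN(35, 5) on [18, 47] | pause sites peak ~+35 nt; inserts ≤47 nt measurable |
| upstream length bonus | +2.5 nt | upstream-initiating RNAs run 2–3 nt longer |
| divergent | 90% of genes, offset U[80, 200] nt upstream | most genes show divergent initiation, concentrated 80–200 nt upstream |
| convergent | 35% of genes, offset U[200, 250] nt downstream | convergent initiation is sparser and further out |
| elements | opposite-strand summit pairs ≤400 bp apart, ≥5 kb from genes | enhancer-like bidirectional loci clear of promoters |
| planted PI | lognormal(ln 50, 1.0); FPKM = count/PI × e^N(0, 0.1) | inverts the PI definition so recovery is checkable |
| genome | iid bases at GC 0.42; Inr PWM written at each true TSS | mammalian-like GC; initiator context only at real TSSs |

The Inr PWM is an invented, documented matrix (pyrimidine-rich −2/−1, strong
A at 0, weak A/T at +2) whose analytic information content is the reference
for motif tests. Two pause models are generable: `distance_anchored` (length
independent of start, the default) and `sequence_anchored` (3′ ends pinned to
true TSS +34; initiation offsets implying unsequenceable lengths are
redrawn). All randomness flows from a single seed through stage-keyed
generators, and generation is deterministic to the byte.

For analyses that need well-populated initiation bands (the class-shift and
length-bonus analyses), tests and the acceptance script lower TSS purity to
0.5 and widen the spread (geometric p 0.08) with ~800 reads/gene so each band
holds ≥2000 reads; the pure distance-anchoring scenario additionally sets the
upstream bonus to 0, since that scenario is defined by length being
independent of the start position.

**What the generator does not emulate:** sequencing errors, rRNA/tRNA
contamination (a blacklist input exists but contamination is not planted),
mappability structure, chromatin-driven positioning of antisense initiation
(+1 nucleosome), overlapping or nested genes, and non-normal annotation-error
tails. Passing tests therefore demonstrate the correctness of the
computations and filters under the stated generative model, not performance
on the idiosyncrasies of real libraries.

## Problem sizes and numerics

The test suite and acceptance script run studies of 40–1000 genes on 0.2–2.5
Mb toy chromosomes with two replicates (tens of thousands to ~300k reads) —
sizes chosen so the whole suite completes in a couple of minutes while every
statistical check retains comfortable power. Determinism is asserted
byte-for-byte on all written artifacts at a fixed seed. Degenerate inputs are
handled explicitly: empty coverage windows yield no peak (the gene fails the
noise filter), a zero-variance offset fit and vectors with <3 observations or
zero variance in correlation are refused or reported missing, and zero-FPKM
genes are excluded from PI with a log line.
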
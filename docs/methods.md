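# Methods

`luatscan` detects and characterizes long upstream antisense transcripts
(LUATs): long (>200 nt), generally non-coding transcripts that initiate
near the transcription start site (TSS) of a protein-coding gene and run
in the opposite direction, into the upstream region. This note records
the models and procedures the package implements, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was open.

## Coordinates and orientation

All coordinates are 0-based, half-open (`[start, end)`, BED convention);
GTF input is converted on read. A transcript's TSS is its strand-aware
5'-most base. "Upstream" is strand-aware throughout: `[TSS-5kb, TSS)`
for a plus-strand gene, `(TSS, TSS+5kb]` for a minus-strand gene.
Promoter windows hold `2*flank/bin` left-closed bins with the TSS base
in the first downstream bin; minus-strand windows are the mirror image
(`(TSS-flank, TSS+flank]` genomically) and are reversed after binning,
so column 0 is always the most-upstream bin and every
orientation-sensitive statistic (binned signal, GC content, GC skew) is
exactly symmetric under strand reflection. Sequence features for
minus-strand genes are computed on the reverse complement, so a positive
downstream GC skew reads the same way for every gene.

## Promoter selection

Anchors are coding-gene TSSs after two filters. (1) TSS deduplication:
within a gene, TSSs closer than 100 bp (strict) are clustered by single
linkage and the longest transcript represents each cluster (ties:
lexicographically smallest id). The representative choice is a package
decision; any deterministic rule preserves the downstream statistics.
(2) Clear upstream region: a candidate is dropped when any coding
transcript of another gene — either strand, transcription-unit span —
overlaps its upstream 5 kb window, or when the window runs off the
chromosome (windows are dropped, never zero-padded).

## Signal model and LUAT calling

Per-base, per-strand fragment coverage counts each aligned fragment once
per overlapped base. Around each candidate TSS the ±5 kb window is cut
into 100-bp bins; bin values are `log2(coverage_sum + 1)`; the channels
are sense/antisense relative to the gene. The antisense score is the sum
of the 50 most-upstream antisense bins. The log scale is the default for
both candidates and the null (a `raw` transform is available); the score
is therefore robust to single coverage spikes.

The calling threshold is empirical: 10,000 regions of 5 kb are sampled
uniformly (with replacement over start positions) from positions at
least 1 kb away from every annotated transcript span, each given a
random pseudo-TSS orientation, and scored with the identical binning,
transform and summation. The threshold is the order statistic
`k = M - floor(alpha*M)` of the M null scores (`alpha = 0.005` default),
which guarantees that at most a fraction `alpha` of the null scores lie
strictly above it; candidates are called on strict `>` so the guarantee
carries over exactly, including ties. No parametric null and no per-gene
FDR are used — one empirical cutoff, as the score's sampling
distribution under "no upstream antisense transcription" is exactly what
the intergenic regions measure.

## LUAT assembly and quantification

Transcribed fragments on the gene's antisense strand are detected as
maximal runs of coverage ≥ 1 (configurable) at least 200 bp long, within
±20 kb of the TSS; externally assembled fragments (BED) are accepted in
place of internal segmentation. Assembly is seed-and-extend: a fragment
seeds a LUAT when its strand-aware 5' end (the right-hand coordinate for
a minus-strand LUAT) lies within ±1.5 kb of the gene TSS; the model then
absorbs, in both directions until closure, every fragment ≥ 200 bp whose
gap to the current span (`next.start − span.end` on half-open intervals)
is strictly below 800 bp. When several seeds exist the one closest to
the TSS is used; the result is order-independent and equals
single-linkage gap-clustering restricted to the seed's cluster (verified
against an independent oracle). The merged span is treated as a
single-exon model — internal structure is unknowable without
splice-aware assembly — and quantified as
`FPKM = 1e9 * assigned / (length * library_size)`, where a fragment is
assigned if same-strand and overlapping the model by ≥ 1 bp. The 5'
offset is reported signed, negative = upstream of the gene TSS.

## Gene sets

Three comparison sets: `luat_associated` (called genes with a single
deduplicated TSS), `coding_coding` (genes with an opposite-strand coding
gene whose TSS is strictly closer than 1.5 kb — divergent head-to-head
pairs), and `unidirectional` (no other gene's transcript in the upstream
5 kb, no call). Control sets can be expression-matched to the
LUAT-associated set by quantile-bin sampling: the reference expression
values define 10 equal-count bins (configurable), controls are drawn per
bin in proportion, and the max |ECDF difference| between control and
reference expression is reported as the matching diagnostic.

## Sequence features

GC content and GC skew (`(#G−#C)/(#G+#C)`, NaN on windows without G or
C) are averaged per oriented bin across anchors. CpG islands follow the
classical Gardiner-Garden–Frommer definition (length ≥ 200 bp, GC ≥
0.50, observed/expected CpG ≥ 0.6 with `obs/exp = N_CpG·L/(N_C·N_G)`),
called by a 200-bp sliding window whose passing windows are merged
greedily only while the union still satisfies both thresholds — every
reported island re-satisfies the definition, and islands are disjoint.
The caller targets synthetic genomes; for real assemblies a curated
track should be supplied as BED. Promoter summaries report coverage
(any island overlapping TSS ± 500 bp) and total island length within
TSS ± 1 kb, summing full island lengths by default (clipped mode
available). PWM scoring is log2-odds against a uniform background with
a 0.01 pseudo-count when built from counts; N scores as the column
minimum; the TATA window is TSS-centered ([−250, +250)), sense strand
only. The 5'-splice-site accumulation curve reports, for x = 1..span,
the fraction of genes whose first downstream motif hit is fully read
within x nt.

## Expression statistics

Tissue specificity is `TS = (e − Q3)/(Q3 − Q1)` across conditions with
linear-interpolation (type 7) quartiles; `TS > 1` flags specificity; a
zero IQR leaves TS undefined and the gene non-specific (rather than
infinite, avoiding spurious calls on constant genes). TS is invariant
under positive affine transforms of the expression vector. Pair
correlation is plain Pearson across conditions, excluding (and
counting) zero-variance members. Co-regulation crosses "changed"
status (|log2 ratio| ≥ log2(2), +0.01 FPKM pseudo-count) of LUAT and
gene in a 2×2 table tested by chi-square without continuity correction;
both-changed-opposite-direction pairs are counted separately and kept
in the both-changed cell by default — dropping them (available via
`drop_discordant`) biases the test away from its nominal type-I rate
under an independent null.

The splicing index quantifies immature transcription as the log2 ratio
of exonic to intronic FPKM, for transcripts with ≥ 4 exons and FPKM >
0.1, all features pseudo-counted (+0.01): the 5' index pairs the mean of
exons 1–2 with intron 1; the middle index pairs the central exon (mean
of the two central exons for even counts) with the mean of its flanking
introns (single-flank mode available — the intronic pairing is the
minimal consistent reading of the exonic definition). First-intron read
density is same-strand fragments overlapping the strand-aware first
intron per bp.

## The synthetic-data generator

The generator emulates the data regimes the analysis assumes; its
defaults are the package's study conditions and are not tuned per test.

**Genome.** i.i.d. background at GC 0.42 with CpG depletion: 80% of
background CpG dinucleotides are lost to simulated methyl-CpG
deamination, applied strand-symmetrically (C→T or G→A with equal
probability, since CpG is its own reverse complement), giving background
obs/exp CpG ≈ 0.25 — the property that makes CpG islands detectable —
while keeping global GC skew near zero. At LUAT-class promoters a GC
skew of amplitude 0.3 (configurable) is planted over 1 kb downstream
with the mirrored deficit upstream, in the gene's orientation; skew
regions are exempt from CpG depletion so the planted amplitude is
exactly the configured `(p_G − p_C)/(p_G + p_C)`. CpG-dense blocks
(median 1 kb) are centered on promoters with per-class probabilities
0.80 / 0.89 / 0.56 (LUAT-associated / head-to-head / unidirectional),
the coverage ordering reported for real promoter classes.

**Annotation.** 200 genes by default (25% LUAT-associated, 10% in
divergent head-to-head pairs with TSS separation 0.3–1.4 kb, the rest
unidirectional), 6 exons of 200 bp with 1-kb introns, first-exon lengths
log-normal with per-class medians 242/195/190 bp. Genes are laid out
with 12–25 kb intergenic gaps so every non-head-to-head upstream 5 kb
region is clear by construction, on 4 × 15 Mb chromosomes — large enough
that 10,000 × 5 kb of intergenic null space exists and planted LUATs
contaminate a negligible fraction of null regions (at genome scale this
dilution is what the real calibration relies on).

**Expression and reads.** Per transcript, fragment counts are Poisson
with mean `FPKM · exonic_kb · library_Mfrags` (gene FPKM log-normal,
median 8; library 2×10^7 fragments, so coverage ≈ FPKM × 2 at 100-bp
fragments); fragments are uniform on the mature transcript and clipped
at exon boundaries (no junction-split fragments — coverage statistics,
not alignments, are what the analysis consumes). A `premrna_fraction`
(default 0.3) of each gene's fragments is drawn from the unspliced
pre-mRNA span, emulating the substantial intronic signal of
ribo-depleted Total RNA-seq; this sets the intron baseline that makes
splicing indices finite (control 5' index ≈ 3.7) instead of
pseudo-count-dominated. An additional per-class `intron1_retention`
fraction is drawn from a template retaining intron 1 only. LUAT
fragments are drawn antisense over the planted interval (length
log-normal, median 2 kb; FPKM log-normal, median 4, floored at 2; 5'
offsets exponential with mean 580 bp so ~58% start within 500 bp of the
TSS). Background fragments fall uniformly genome-wide on both strands at
0.2 fragments/kb/strand (≈0.02× coverage), a realistic intergenic floor.
Poisson counts (no overdispersion) are the default; real libraries are
overdispersed, so variance-sensitive conclusions transfer only
qualitatively.

**Multi-tissue tables.** 17 conditions; gene vectors log-normal, a
configured fraction boosted 8-fold in one tissue; each paired LUAT
vector is `rho·standardized(gene) + sqrt(1−rho²)·noise`, rescaled and
floored at 0, giving linear Pearson correlation ≈ rho (default 0.8).

**What passing tests do not show.** The generator has no mappability
structure, no multi-reads, no sequencing error, no fragment-length
variation, no splice junction reads and no unannotated background
transcription other than the planted LUATs. Recovery results therefore
validate the statistical machinery (calibration, merging, estimator
consistency), not robustness to alignment artifacts; on real data the
external-assembler input path and curated feature tracks should be
preferred.

## Numerical choices and degenerate inputs

Strict inequalities at every printed cutoff (<100 bp, <1.5 kb, <800 bp,
score > threshold). The threshold order statistic is computed as
`M − floor(alpha·M)` (identical to `ceil((1−alpha)·M)` in exact
arithmetic, robust to floating rounding of `1−alpha`). Empty read sets
yield zero coverage, not errors; anchors at chromosome edges are dropped
with a warning; all-N bins are excluded from GC denominators; zero-GC
windows give NaN skew and are excluded from profile means; degenerate
contingency tables (an empty margin) and intron-less transcripts raise.
All randomness flows through seeded `numpy` generators with fixed
per-stage substreams; every simulate/sample operation is bit-reproducible
from (config, seed).

## Problem sizes used in the test suite

The suite exercises the full default simulation (4 × 15 Mb genome, 200
genes, 10,000 null regions) for calibration and recovery checks, and
1–3 Mb genomes with 8–60 genes elsewhere; estimator-equivalence checks
run on 1,000–10,000 random instances. These sizes make every documented
recovery property statistically decisive while keeping a full run of
suite plus acceptance script within a few minutes on one CPU.

## Known limitations

LUATs are modeled and quantified as single-exon spans; expression-matched
sampling requires every reference quantile bin to be populated in the
pool (reduce `n_bins` otherwise); the CpG caller is not the UCSC
algorithm (supply the curated track for real genomes); the co-regulation
test assumes pairs are independent observations; FPKM inherits all the
usual caveats of length-normalized counting near exon boundaries
(fragments overlapping a feature by ≥1 bp count fully, which inflates
short-feature FPKM by a factor ≈ 1 + fragment_len/feature_len — a
shared factor that cancels in the splicing-index differences the
package interprets).
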
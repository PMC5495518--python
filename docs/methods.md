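# Methods

This note documents the models and numerical conventions implemented in
`dsbsirna`, the choices made where the underlying assay descriptions left
the design open, and what the synthetic-data generators do and do not
emulate.

## Coordinates and gene models

All internal coordinates are 0-based, half-open; GFF3 (1-based, closed)
and BED12 conversions happen only at the I/O boundary. A gene is a
single transcript model (one isoform): ordered non-overlapping exons
whose gaps are introns, bounded by the TSS and the transcript 3'-end.
Minus-strand genes are flipped onto the transcription axis
(`GeneModel.oriented`, x → reference_length − x) before any analysis, so
"upstream" always means 5' of the transcript and downstream code never
branches on strand.

Junctions are boundaries between adjacent bases: each exon→intron
boundary (5' splice site), each intron→exon boundary (3' splice site) on
the genomic axis, and each exon–exon junction on the spliced (cDNA)
axis. For size normalization a junction's "size" is the number of
distinct read start positions that can span it with at least `o` bases
on each side: `L − 2o + 1` (defaults L = 21, o = 1). This makes junction
densities comparable to exon densities under uniform read placement; the
assays themselves do not fix a junction normalizer, so this is a package
convention, exposed in configuration.

## Read processing and mapping

Reads are demultiplexed by exact 5'-barcode prefix match, and the 3'
adapter is removed by the longest exact suffix/prefix overlap
(≥ `min_overlap`, default 5) or a full internal occurrence; reads
shorter than `min_len` (default 18) after trimming are rejected and
counted. The mapper is exact-match and ungapped on both strands via a
k-mer seed index (k = 12) with full verification — appropriate for a
locus-scale reference of a few kilobases where 21-nt reads are almost
always unique. Reads with more than `max_hits` placements (default 1)
are discarded; multi-mapping would otherwise inflate the sgRNA-peak
region. The reads-per-million denominator defaults to all reads entering
mapping (configurable to mapped-only); the upstream/downstream ratio is
scale-free, so this choice affects only absolute RPM values.

## Coverage and the cut-site ratio

Per-base coverage counts every read overlapping a base, scaled to RPM,
split by gene-relative sense/antisense. End traces place each sense read
at its 5'-end and each antisense read at its 3'-end — the leftmost
genomic coordinate on the (oriented) plus axis, so a trace spike means
"a read extends L nt downstream of here"; only reads wholly inside the
transcript window enter the end traces.

The cut-site statistic divides the mean per-base RPM between the TSS and
the cut by the mean between the cut and the transcript 3'-end. The
protospacer ± `exclusion_pad` (default 5) bases are excluded from both
numerator and denominator, removing the artifactual peak of reads
derived from the sgRNA itself by position rather than by sequence
matching (robust to sequencing errors). Whether the guide's PAM should
be part of the exclusion zone is not specified by the assay; the pad
parameter subsumes it. Both strands are combined (per-strand ratios are
reported alongside). Reads straddling the cut contribute their
overlapped bases to each side — the statistic is a per-base average, so
no whole-read assignment rule is needed. A zero downstream mean yields
an explicitly flagged undefined ratio, never infinity, keeping replicate
tabulation well-defined.

## Feature coverage and junction-spanning reads

Exons and introns count every intersecting read; genomic junctions count
reads with ≥ `min_overhang` bases on each side of the boundary (default
1; the counting is re-run at o = 3 in tests since the assay gives no
threshold). Counts are RPM-scaled and divided by feature size. Note
that an interval of size s is intersected by s + L − 1 start positions,
so short introns show edge inflation relative to junctions; the uniform-
placement equality of feature densities holds exactly only after this
edge correction (tests state it that way).

Exon–exon junction reads are detected by mapping raw reads to the
spliced cDNA sequence; reads that also map to the unspliced genomic
sequence are excluded (they are not evidence of a spliced product).
This exclusion is a declared package decision (an option disables it);
it can only decrease counts. Replicate comparisons use a paired
two-sided t-test on per-replicate normalized densities — paired because
the two features share library-level scaling within a replicate; the
degenerate zero-variance case is flagged rather than given a p-value.
Sub-complex enrichment uses Pearson's χ² with 1 df (optional Yates
correction) via `scipy.stats.chi2_contingency`.

## Screen scoring

Per plate and channel, raw luminescence is log-transformed (natural log;
any base cancels after centering) and centered on the median of the
valid sample wells. Wells with nonpositive raw values are excluded and
counted. Dead-cell exclusion: wells whose raw FLuc falls below the
per-plate mean of the thread-control wells are dropped — the thread
knockdown kills cells and thereby defines the floor; the precise rule is
a package decision since only the purpose of the control is stated.

The LOESS of normalized RLuc on normalized FLuc uses tricube weights
`(1 − (d/dmax)³)³` over the `ceil(span·n)` nearest neighbors in x and a
local polynomial fit (span 0.9; degree 2 by default — classic LOESS —
with degree 1 available; only the span is fixed by the original screen
description). Degenerate neighborhoods fall back to the weighted mean.
Controls are excluded from fitting but scored against the curve (the
original analysis does not say; this avoids the strong positive controls
bending the curve). Residuals are standardized against the sample-well
residual distribution (mean/SD; a median/1.4826·MAD robust variant is
provided).

Sign convention: siRNAs repress the Renilla reporter, so knocking down a
factor required for siRNA biogenesis de-represses RLuc — a positive
residual. Positive candidates are genes whose score exceeds the
negative-control mean + 1 SD threshold; negative candidates (repressors)
fall below mean − 1 SD.

Replicate aggregation: wells are scored per plate and a gene's score is
its mean z across replicate plates, while the candidate threshold is
derived from the well-level negative-control z distribution. Averaging
across r plates shrinks the null-gene spread by √r relative to that
threshold; this is what gives the screen its low false-positive rate at
a threshold of only one control SD. Scoring a single plate (r = 1)
reverts to the naive ~16% one-sided null exceedance, so replication is
essential. Validation applies the 2-of-3 independent-trigger rule and
then drops genes whose knockdown de-represses a perfect-match miRNA
reporter in the counter-screen (core-pathway or transcription effects
rather than break-specific ones).

## qPCR

Relative quantification follows 2^−ΔΔCt with amplification efficiency
fixed at 2: ΔCt = Ct(target) − Ct(exon-internal reference) within each
condition, ΔΔCt between conditions, computed per biological replicate
(matched by replicate index when both conditions share it, against the
control mean otherwise) and summarized as mean ± SD of the replicate
folds. Splicing efficiency reports, per intron, the pre-mRNA level
2^−(Ct_intron–exon − Ct_total) and per junction the spliced level
2^−(Ct_exon–exon − Ct_total). Cut/uncut fold changes per amplicon use the
same ΔΔCt machinery with a one-sample two-sided t-test of the replicate
ΔΔCt values against zero. Folds are shift-invariant in Ct and
reciprocal between condition orderings.

## Synthetic data

**siRNA libraries.** The positional model is piecewise-uniform: a
uniform background over the whole transcript plus an induced component
confined to [TSS, cut), weighted so the expected upstream/downstream
per-base density ratio equals `induction_ratio`; reads are 21-nt genomic
substrings (sense) or their reverse complements (antisense, sampled
independently — no phasing is modeled), plus a spike of protospacer-
sequence reads (`sgrna_peak_fraction`, default 2%). Cuts in intron-less
genes or upstream of the first intron multiply the induced excess by
`unspliced_damping` (default 0.03), so a 50× target damps to ~2.5 — the
weak response of an unspliced target, in the observed 1.6–2.9 range for
intron-less loci, versus ratios in the tens for spliced ones. Because
sense reads come from the unspliced pre-mRNA, no simulated read can span
an exon–exon junction on the spliced axis; the zero-count test verifies
the analysis code, not sequencing reality. Not emulated: sequencing
errors, Dicer processivity/phasing, chromatin or expression gradients —
a green recovery test establishes that the pipeline inverts this stated
world, not that real libraries are this clean. The default locus is a
~3 kb four-exon gene with three short introns; library size defaults to
1e6 reads.

**Screen plates.** Replicate 384-well plates of one layout: log-normal
well intensities with per-plate, per-channel multiplicative effects
(SD 0.15), a power-law FLuc→RLuc coupling absorbed by the LOESS fit,
well noise (SD 0.10 on the log scale), and 15 spiked hits acting
multiplicatively on RLuc only at 3 residual SD. Positive controls
de-repress RLuc strongly (+6 SD), the Renilla-knockdown control
suppresses it, thread wells collapse both channels to 2% of baseline.
Spatial (row/column) gradients and edge effects are not modeled — plate-
median centering would not remove them, and the package deliberately
implements no spatial correction.

**Ct tables.** Ct = baseline − log2(planted fold) + N(0, noise_sd) per
replicate; defaults (pre-mRNA 8 cycles above total, spliced ≈ total,
noise 0.1 cycles, 3 replicates) emulate a strongly expressed locus where
splicing is near-complete at steady state.

All generators take a single seed, record it with all parameters in a
machine-readable truth record, and produce byte-identical outputs for
identical configurations.

## Numerical and degenerate-case conventions

* Undefined ratios and degenerate-variance t-tests are flagged values
  (`None`), never infinities or NaNs in result tables.
* The LOESS fallback hierarchy: zero-spread neighborhood → weighted
  mean; fewer than degree+1 positively weighted points → weighted mean.
* χ² requires all-positive marginals; zero-marginal tables are errors.
* A palindromic read (equal to its reverse complement) is reported on
  the plus strand only, so it does not spuriously count as a
  multi-mapper.
* Workflow seeds derive per-stage substreams from the top-level seed via
  `numpy.random.SeedSequence`; all derived seeds stay below 2³¹.

## Known limitations

Single-isoform gene models only; exact-match ungapped mapping (no
mismatch tolerance, no spliced alignment — spliced products are handled
by mapping against the constructed cDNA); no multiple-testing correction
across features (raw p-values, as the assays report them); no GO or
network analysis; plotting is limited to bedGraph/TSV exports for
external viewers.
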
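# Methods

## Overview

`sgekit` implements the analysis of a saturation genome editing (SGE)
experiment in a haploid human cell line: every possible SNV in a set of
genomic regions is engineered by CRISPR/HDR, one variant per cell, and the
population is sampled by amplicon sequencing over a selection time course.
The package covers four stages — HDR-gated variant counting from reads,
function/RNA/InDel scoring, synonymous-null significance testing with
function classes, and benchmarking against clinical/population annotation
tables — plus a synthetic-experiment generator that makes every stage
testable without external data.

## Read processing and HDR gating

Read pairs are merged only when the overlap (≥ 20 bp, configurable) matches
perfectly; merged reads containing N are dropped. Merged reads are aligned
end-to-end against the region's reference amplicon with Biopython's
`PairwiseAligner` using EDNAFULL-like scoring (match +5, mismatch −4, gap
open 10, gap extend 0.5, end gaps penalized). Our gap convention charges
`open + (L−1)·extend` for a gap of length L. Equal-length reads whose
mismatch count is provably too cheap to justify any gapped detour take a
gap-free fast path.

Every HDR library molecule carries one or two synonymous PAM-blocking
marker edits; a read counts toward a variant only if at least one marker is
present (`hdr_gated`). RNA (cDNA) reads additionally require the exact
spliced-transcript flanks on both sides of the target exon — exon skipping
or intron retention breaks the flank match and the read is excluded. The
RNA gate is therefore strictly stronger than the HDR gate.

Two decisions the underlying protocol leaves open:

- **Frequency denominator.** `sample_total` is the number of reads passing
  the HDR gate (gDNA) or RNA gate (RNA). Gated totals make day-to-day
  frequency ratios insensitive to drift in editing efficiency.
- **Multi-variant reads.** Reads carrying ≥ 2 designed SNVs contradict the
  one-variant-per-haploid-cell design and are discarded from both numerator
  and denominator.

InDel outcomes are keyed by CIGAR string and retained only if seen in more
than 0.1% of day-6 reads, contain at most one InDel operation, and begin
with ≥ 100 bp of exact 5' match.

## Function scores

Frequencies are pseudocounted, `(count + 0.5) / (total + 0.5)`, so fully
depleted variants remain finite in log space (the pseudocount is a package
choice; 0.5 is half a read). The raw score is the mean over two transfection
replicates of log2(day-20 / day-6 frequency). Six quality filters remove
unreliable SNVs; all are evaluated independently so the reason set is
order-invariant:

1. HDR library frequency < 1e-4;
2. day-6 frequency < 1e-5 in either replicate;
3. replicate log2(d20/d6) ratios differing by > 1.5, unless both < −1.0;
4. log2(d13/d6) vs log2(d20/d13) differing by > 2.0, unless both < −0.5
   (evaluated on replicate means);
5. estimated sequencing-error frequency — the variant's frequency in the
   day-6 negative-control sample (library + non-targeting guide, so any
   variant signal is error) — exceeding half of max(day-6, day-20)
   frequency in either replicate;
6. a variant sharing a codon with a PAM marker edit whose joint codon
   encodes a different amino acid than the variant alone.

Raw scores are centered by subtracting the region's median passing
synonymous score (median of an even-sized set = mean of the middle two), so
the synonymous median is exactly 0 per region. Regions without synonymous
variants (the deep-intronic region) center on the median of all passing
SNVs. Scores are then scaled linearly across regions: anchors are passing
nonsense SNVs with residue number inside the scaling window (54–198, where
nonsense is uniformly deleterious); each region is multiplied by
`global anchor median / region anchor median`, which maps all anchor
medians onto the pooled median while preserving the synonymous median at 0.
Regions with < 3 anchors or a non-negative anchor median keep factor 1 with
a warning. Variants assayed in two overlapping regions are merged after
scaling: a configurable policy keeps the second region's score or averages
the two, mirroring the three overlap rules of the original experiment.

## RNA scores

For coding SNVs that passed function-score filtering, the day-6 and day-20
RNA scores are the replicate-mean log2 ratio of the SNV's frequency in
spliced mRNA to its frequency in the matched gDNA sample. The log2 transform
is a package decision (the observed dynamic range of splice-disrupting
variants is consistent with it). Non-coding variants never receive RNA
scores: they are absent from spliced transcripts.

## InDel scores

Retained CIGAR outcomes get the replicate-mean log2(day-13 / day-6
frequency), with a reading-frame class from net length mod 3 (0 in-frame,
1 "+1", 2 "−1"). A frequency floor of 1e-6 guards the log for outcomes that
vanish by day 13.

## Significance and function classes

Per region, a normal null is fit (sample mean/SD, ddof 1) to passing
synonymous SNVs, excluding those with day-6 RNA score < −1.0 (likely
cryptic splice disruptors); in the intron-only region all SNVs form the
null. Normality is assumed, never tested, and at least 10 null variants are
required. P-values are one-sided lower-tail normal probabilities (depletion
is the only alternative of interest), adjusted by Benjamini–Hochberg within
each region; q < 0.01 (strict) defines "depleted". Four classes are
assigned with fixed precedence: neutral (q > 0.10 and score > −0.2188),
LOF1 (score < −1.26), LOF2 (q < 0.01 and score < −0.3875), otherwise
intermediate. The thresholds are anchored to gold-standard variant score
distributions and are constants of the method. For variants merged across
regions by averaging, the more conservative (larger) q is carried.

## Benchmarking

Gold-standard sets from annotation tables: tumor-associated = ≥ 2 ccRCC
observations, or 1 observation plus a pathogenic/likely-pathogenic
assertion; neutral = benign/likely-benign and seen at least once in a
combined population allele count (gnomAD v2 + v3 + TOPMed het + UKB);
missense-neutral = missense seen in ≥ 2 population controls without a
pathogenic assertion. The tumor-associated and neutral sets are disjoint by
construction. Performance sweeps all thresholds with the strict convention
"positive call = score < threshold" (ties negative); AUC by trapezoid.
Phenotype grouping follows the clinical-database convention: type 1 =
entries only type 1/ccRCC; pheo-predominant = entries only type 2 or more
pheochromocytoma than ccRCC entries; explicit type 2B, mixed or absent
phenotypes = unclear; only pathogenic, non-recessive variants seen < 2
times in population controls are grouped.

Stop-codon context: a nonsense SNV's stop type (amber UAG / ochre UAA /
opal UGA) plus the following base form a 4-mer; opal followed by a
pyrimidine is flagged readthrough-permissive.

## Synthetic VHL-like transcript

The terminal-frameshift analysis needs a CDS + 3'UTR. The repository cannot
ship the RefSeq transcript, so `sgekit.vhl` constructs a SYNTHETIC stand-in
with the landmark properties the analyses use: 213 codons; TGG at residues
88 and 117 each followed by C (third-base G>A transitions there create opal
stops in the permissive UGA-C context); an A-free arginine tail from
residue 200 so no premature stop arises in any frame; and a 3'UTR whose
first +1-frame stop sits exactly where any single-base duplication between
residue 200 and the natural stop yields a 41-residue C-terminal extension,
while −1 frameshifts terminate within a few residues. Tests verify all of
this against an independent codon-by-codon translation oracle, so they
validate the frameshift-translation logic, not the real gene's sequence.

## Synthetic experiments

The generator emulates the study design: per region, a random stop-free
coding exon with intronic flanks, all 3L possible SNVs (minus the PAM
marker alleles), two synonymous PAM marker edits, and consequence labels
from codon translation. True effects are class-dependent: nonsense and
canonical-splice SNVs and a 0.224 fraction of missense get the LoF growth
effect (−2.5 log2 over the 14-day day-6→20 window, the magnitude of
observed nonsense depletion); 2% of synonymous SNVs are splice-disruptors
(RNA effect −4 log2, attenuated to half by day 20 in surviving cells, plus
the LoF growth effect); everything else is neutral (s = 0 exactly).
Library representation is lognormal (σ = 0.5); each replicate jitters day-6
frequencies (σ = 0.15); selection is exponential in log2 units with
renormalization; sequencing is multinomial at 1e6 gated reads per gDNA
sample (3e5 for RNA) with per-base error 1e-4 moving reads between a
variant and its single-base neighbors (ε/3 per alternate). The negative
control models an unedited genome: designed variants appear only through
sequencing error, which is what makes it an error estimator for filter 5.
Annotation tables draw tumor observations Poisson(2.0) for true-LoF
variants and population counts Poisson(2.0 combined) for neutral ones, with
optional ClinVar-style labels and a configurable miscall rate. All
randomness flows from one seed through named substreams.

What the simulation does not model: HDR efficiency and recutting, cell-cycle
and bottleneck stochasticity beyond multinomial resampling, PCR jackpotting,
position-dependent error, batch effects between transfections. Passing
recovery tests therefore demonstrates correctness of the scoring arithmetic
and calibration of the statistics under the generative model, not
robustness to every artifact of real sequencing data.

## Numerical choices and problem sizes

Tests and the acceptance script run the generator at two regions × ~300
SNVs (or one region × ~500 for null calibration), 20 seeds for aggregate
rates — sizes chosen so the full suite completes in well under a minute of
simulation time while keeping ≥ 1000 LoF variants in aggregate estimates.
Scaling identities are asserted to 1e-12; the centering identity is exact
by construction. A known property of rank-based recovery summaries: with
two-valued true effects (0 or s_LoF) and LoF fraction p, the Spearman
correlation of even a perfect recovery is bounded by √(3p(1−p)) ≈ 0.76 at
p = 0.25, because neutral variants are tied in truth but ranked by noise in
the estimate.

## Known limitations

- Error estimation uses the negative-control day-6 sample only; no
  position-specific or quality-aware error model.
- Selection between day 13 and 20 is summarized, not modeled, beyond the
  trajectory filter.
- The aligner is exact but quadratic; it is intended for amplicon-length
  references, not genome-scale alignment.
- Benchmarking joins annotations by coding-level variant name; genomic
  coordinate liftover is out of scope.
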
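# Methods

This note records the models, parameter choices and numerical conventions
behind `cernet`, and what the synthetic-data experiments do and do not show.

## Coordinates and alphabets

Genomic coordinates are 1-based inclusive (GFF convention) throughout;
transcript-space positions are 1-based from the 5' end. All pairing logic
runs in RNA space (A/C/G/U); I/O converts at the boundary, so U/T mix-ups
cannot reach the duplex scorer. Minus-strand spliced sequences are the
reverse complement of the concatenated exon sequence. GFF3 and GTF are both
accepted, auto-detected from the attribute separator.

## Differential expression

Counts within one tissue (3 control "ck" + 3 salt-treated "st" replicates)
are scaled to the mean library size, summed per group, and tested with a
two-sided negative-binomial exact test: conditional on the two-group total
T, the split S_st follows a beta-binomial-like law that depends only on the
NB size parameters n/phi per group, so the test needs one dispersion phi
(var = mu + phi mu^2) per feature. The two-sided p-value sums the
probabilities of all splits no more likely than the observed one (the
"minlike" convention, with a 1e-7 log-scale tie tolerance so mirror-image
splits stay paired under floating-point noise). As phi -> 0 the law is
Binomial(T, 1/2), which is the closed-form oracle used in the tests;
dispersions below 1e-8 are routed to that branch directly, which also avoids
gammaln cancellation at huge NB sizes.

Per-feature dispersion is a method-of-moments estimate, averaged over the
two condition groups, with the unbiased estimate of mu^2 (mean^2 - var/n) in
the denominator, then shrunk 50/50 toward the **across-feature mean**.
The mean anchor is deliberate: with 3 replicates the per-feature moment
estimates are strongly right-skewed, so their median sits well below the
true common dispersion (about 0.083 for a true 0.1 in simulation), and a
median anchor leaves the exact test liberal (empirical type-I ~0.08-0.09 at
alpha 0.05). With the mean anchor and unbiased denominator the empirical
type-I error is ~0.06 and directional power at planted |log2FC| = 2,
mean >= 100, is above 99%. These rates are recomputed, not quoted, by
`scripts/acceptance.py` and the test suite.

Call thresholds follow the study conventions: gene-like features
(mRNA/lncRNA/circRNA) are up/down when p < 0.05 (strict) and |log2FC| > 1
(strict); miRNAs when p < 0.05 and fold change >= 1.5 (inclusive) in either
direction. Raw p-values are filtered, not FDR-adjusted. A relaxed p < 0.1
mode re-filters stored results without recomputation and flags every
downstream output; it exists for tissues where the strict cutoff yields no
ceRNA candidates. FPKM (count x 1e9 / (length x library)) and CPM are stored
in linear space; the 1e-6 pseudo-count is applied only when logs are taken.

## lncRNA, circRNA and miRNA annotation

lncRNA identification keeps transcripts that are >= 200 nt, have no
same-strand exonic overlap with a known mRNA (antisense overlappers are
kept, the standard lncRNA convention), and look non-coding. Coding potential
uses a deterministic stand-in for external classifiers: longest
AUG-initiated ORF across the three forward frames (stop codon included;
open-ended ORFs counted to the last complete codon) below 300 nt. The
published CPC/CNCI phrasing for this filter removes the low-scoring (i.e.
non-coding) transcripts as written, which inverts its stated goal; the
implementation follows the evident intent and retains them. A precomputed
coding-potential table can override the ORF heuristic.

circRNA locus types are exhaustive and exclusive: *exon* if the circularized
span overlaps any exon of a same-strand transcript, else *intron* if it lies
fully inside an intron of a same-strand transcript, else *intergenic*.
lncRNA cis-targets are all coding genes whose span lies within 100 kb
(overlap = distance 0; sign is negative upstream of the gene in gene
orientation).

Small-RNA reads of 18-25 nt are *known* miRNAs when within 3 Hamming
mismatches (no indels, equal length) of a reference mature; otherwise
*novel* when their exact genomic locus ±200 nt folds into a stem-loop; else
dropped, with the three outcomes partitioning the input. The stem-loop
heuristic replaces thermodynamic folding: an antidiagonal complementarity
scan over all fold axes with arm/loop/arm geometry (loop 3-150 nt) passes
when >= 80% of mature positions pair (Watson-Crick or G:U) against the
opposite arm. The 80% threshold was frozen after Monte-Carlo calibration:
at 60% virtually every random 421-nt window passes (many axes x ~0.375
per-position pair chance), while at 80% random windows pass ~1% of the time
and exact-complement stems always pass.

## Target discovery

Duplexes are antiparallel: miRNA position i (5'->3') pairs the window's
(L - i + 1)-th base. Cleavage mode admits no bulges; mimic mode admits
exactly one target-side bulge of 1-4 nt inserted between the target bases
paired to miRNA positions 9-10 or 10-11 ("middle" = 9-11, the scissile
region; configurable), choosing the minimal-penalty insertion point with
leftmost tie-break.

Cleavage scoring stands in for uncited external-tool parameter sets and is
exposed in `PairingRules`: mismatch 1, G:U wobble 0.5, both doubled over
the 5' pairing core (positions 2-13), accept at score <= 4 with Watson-Crick
pairs required at positions 10-11. The predicted cleavage position is the
target base paired to miRNA nt 10 — slicing occurs between the bases paired
to nts 10-11, so the 3' fragment's first base is the nt-10 partner, which is
what degradome tags measure. Mimic acceptance follows the three eTM rules:
(I) exactly one middle, target-side bulge; (II) over non-middle positions a
budget of <= 4 units (MM = 1, G:U = 0.5) with no run of > 2 consecutive
mismatches, G:U pairs neither counting toward nor extending a run (the
G:U-in-rule-II convention is a documented choice; the source rules are
silent); (III) no other bulge. Scanning slides every admissible window
(vectorized, verified against the scalar aligner and an exhaustive
enumeration oracle), keeps the best-scoring window per cleavage position,
and treats circRNA sequences circularly by doubling and modular
deduplication. Calibration: random 21-mers against random 2-kb transcripts
yield < 0.05 accepted cleavage sites per pair.

## Degradome validation

Tag 5' ends are placed by exact match of the tag's first 20 nt on the sense
strand of the transcriptome (degradome tags are short and high-quality;
alignment would add a dependency without changing the answer at this error
rate); a tag matching k positions contributes count/k to each, conserving
total abundance. A predicted site becomes a cleavage event when the
abundance at its predicted position is positive. Categories follow the
degradome-tool convention: 0 = count > 1 equal to a unique transcript
maximum; 1 = equal to a shared maximum; 2 = above the median; 3 = at or
below the median; 4 = count <= 1 (fractional multi-map weights land here).
The median is taken over positions with at least one (possibly fractional)
tag, not all positions. An attached binomial enrichment p-value
(P[X >= count], X ~ Bin(total tags, 1/length)) is reference-only, never a
filter. Degradome evidence is condition-agnostic, matching designs that pool
treatment and control RNA into one library per tissue.

## Network assembly

Networks are per tissue (no cross-tissue edges) over DE features only. An
edge miRNA->ceRNA requires (a) a predicted site (cleavage preferred when
both modes hit), (b) Pearson r <= -0.7 between the two features' log2
(normalized + 1e-6) abundances over the six within-tissue samples, and,
by default, (c) the competing-pair condition: at least one other retained
ceRNA of the same miRNA with pairwise r >= +0.7, applied to a fixed point
so dropped edges cannot keep their former partners alive. Constant series
give an undefined (NaN) correlation and are excluded. The Pearson/0.7
choice is a package default, not a claim about the original analyses, which
specify only that correlation filtering occurred; n = 6 makes rank
correlations too coarse. Negative-regulation DEmiRNA-mRNA pairs (opposite
DE directions plus a predicted site) are tabulated with a Y/N
degradome-detection flag; the bundled published sugar-beet table of 33 such
pairs is reproduced by counting (16 leaf, 17 root, 11 Y).

## Synthetic data: what it emulates, and what it does not

The generator emulates the study design (2 tissues x 2 conditions x 3
replicates), not the sequencing process. Defaults: 25 mRNA genes (ORFs >=
300 nt, alternating single/two-exon so introns exist), 15 lncRNAs (200-1000
nt, longest ORF < 300 nt by rejection sampling — both sides of the
annotation filters are exercised), 10 circRNAs cycling the three locus
types, and 20 miRNAs (lengths drawn from {21, 24} with 5'-U on 21-mers and
5'-A on 24-mers, the DCL composition bias taken to its extreme). Each miRNA
gets one cleavage site (exact reverse complement written into an mRNA, with
0-2 substitutions outside the doubled-penalty core so planted sites always
score below the acceptance cutoff) and one mimic site (reverse complement
with a 1-4 nt bulge between the nt 10-11 partners and 0-2 non-middle
mismatches) planted **by replacement** into a lncRNA or intergenic circRNA,
leaving exon structures intact; the genome is then re-patched so sequence
extraction and planted sites agree exactly.

Counts are negative binomial with a single dispersion (default 0.1) shared
across features — the original study sequenced real libraries and states no
noise model, so NB with common dispersion is a documented stand-in chosen so
the stated DE thresholds are meaningful. Planted DE features split their
base mean (U(200, 800)) symmetrically across conditions by the planted
log2FC. Triplet correlation is induced structurally, not by post-hoc matrix
shaping: the three members share a per-sample latent log-normal factor
(sd 0.3) with loading +1 on the two ceRNAs and -1 on the miRNA, restricted
to the triplet's planted tissue, keeping counts integer and marginally NB.
Stand-alone DE features are planted at |log2FC| = 2 (the value the DE
power experiments use); triplet members at |log2FC| = 4, i.e. 16-fold —
within the range reported for strongly salt-responsive genes in this system
(~20-fold) — because the generator's contract is that planted correlations
clear the network's |r| >= 0.7 filter essentially surely, and at 4-fold the
per-edge miss probability from 6-sample Pearson noise is no longer
negligible. Degradome profiles put `peak_reads` (default 50) tag ends at
each planted nt-10 partner over Poisson(0.01)/position background.

Passing tests on these data show the pipeline recovers exactly the structure
the rules define, under NB noise, at desk scale. They do not show robustness
to real-data pathologies the generator omits: sequencing error, adapter
contamination, isomiR heterogeneity, multi-mapping ambiguity beyond exact
duplicates, assembly artifacts, unequal library sizes, or batch effects.

## Problem sizes and determinism

The packaged experiments use desk-scale sizes chosen to keep the full suite
and the acceptance script in the minutes range on one CPU: 50-transcript /
20-miRNA datasets for recovery (five seeds), 2000 null features for type-I
calibration, and 20 seeds x 100 planted features for power. Every stochastic
step takes a `numpy` Generator or integer seed; the end-to-end pipeline
writes byte-identical outputs across runs with the same seed, which the test
suite asserts.

## Known limitations

* The ORF and stem-loop heuristics are deliberate, documented stand-ins for
  external coding-potential and folding tools; they are calibrated, not
  thermodynamic.
* Cleavage-mode scoring constants approximate the behaviour of standard
  plant target predictors whose exact parameters are unpublished; all are
  configurable.
* Degradome mapping is transcriptome-wide exact-prefix matching, not
  genome-wide alignment.
* The exact DE test conditions on rounded normalized group sums; with very
  small libraries the rounding is a coarser approximation.
* Correlation over n = 6 samples is intrinsically noisy; the 0.7 threshold
  is a screening default, not an inference guarantee.
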
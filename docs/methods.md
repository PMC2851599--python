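# Methods

This note documents the models and procedures implemented in `estmine`, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic-data generator does and does not emulate.

## SSR detection

A locus is defined from *maximal periodic regions*: a region of period *u*
is a maximal stretch where every base equals the base *u* positions before
it. The reported locus is the left-anchored complete-unit portion of such a
region, so `end − start = unit_size × n_units` and the run cannot be
extended by one full unit in either direction. The repeat unit must be
*primitive* (not itself a repetition of a shorter unit), which both
excludes homopolymers from the dinucleotide class and guarantees each
physical run is reported exactly once — a `(ATAT)ₖ` region is reported as
`(AT)₂ₖ`, never as a tetranucleotide repeat. The motif is canonicalized to
the lexicographically smallest rotation of the unit *on the reported
strand*; there is no reverse-complement folding because EST sequence is
strand-specific cDNA. `N` breaks runs and never participates in one.

Defaults: unit sizes {2, 3, 4}, minimum 4 contiguous units, and for marker
discovery a strict `< 50 bp` length cap. The QC flagging path reuses the
detector without the cap and flags runs strictly *longer* than 50 bp, so a
run of exactly 50 bp is a legitimate marker and not a QC discard.
Compound or interrupted repeats are reported as separate loci; no merging
rule is applied. An SSR counts as *coding* when it overlaps a CDS interval
by at least 1 bp (the simplest defensible rule; straddling loci are coding).

The detector is verified against a brute-force oracle that enumerates every
(start, unit size, unit count) triple — exhaustively over all 4-letter
strings up to length 8 and all {A,T} strings up to length 14, and on 500
random 1-kb strings plus derandomized property tests.

## Primer design

Candidate windows of 18–24 bp are enumerated in the 5' and 3' flanks of
each SSR (within amplifiable distance), and every forward/reverse pair
passing all five rules is returned:

1. product length 100–450 bp,
2. each Tm in 52–62 °C,
3. |ΔTm| ≤ 4 °C,
4. each primer GC ≥ 30% (inclusive),
5. two-base 3' GC clamp.

Tm uses nearest-neighbor thermodynamics at 50 mM monovalent salt and 50 nM
annealing oligo (comparable to batch primer-design tools); the Wallace
2(A+T)+4(G+C) rule is available via `PrimerConstraints(tm_method="wallace")`.
Pairs are ranked by |mean Tm − 57| then |product − 250 bp|, tie-broken by
position so output is deterministic. The primer length range is 18–24 bp:
a shorter minimum (down to 12 bp) is sometimes quoted in marker-design
protocols but 12-mers are not PCR-credible, so the flank-length
interpretation of such settings is left to the enumeration bounds rather
than primer length. Secondary-structure screening (hairpins, dimers) is
deliberately out of scope.

## Read QC

Filters run in a fixed order — adapter trim, retroelement similarity, long
SSR run, mean quality — and a read is attributed to the *first* filter it
triggers, making report counts reproducible for reads failing several
filters (the order itself is a convention; any fixed order gives the same
kept set). Boundaries are strict: mean quality exactly 18 passes
("less than 18" discards), a 50 bp run passes ("longer than 50 bp"
discards). `N` bases contribute their recorded quality to the mean and
never extend an SSR run. Adapter trimming is exact prefix/suffix matching
and disabled by default.

## Mapping and SNP calling

The mapper places a read where its k-mer seeds (k = 21, sampled every k
bases, both strands) support exactly one (reference, diagonal) candidate,
then extends ungapped end-to-end; reads with no seed, ambiguous seeds,
mismatch rate above 5%, or overhanging the reference are unmapped. Gapped
alignment is omitted on purpose: the SNP definition used here considers
substitutions only and disregards indels, and homopolymer-indel realism is
a non-goal.

Pileup columns count every aligned base, so summed column depth equals
summed aligned length exactly (a conservation law asserted in tests). The
caller emits a SNP where the A/C/G/T depth reaches `min_depth` and the most
frequent non-reference base reaches `min_alt_freq` of that depth, both
inclusive — depth 10 with 8 reference / 2 alternate is called at the 20%
preset. Two preset combinations mirror pooled-sample 454 practice:
10× / 20% for inspecting the most deeply covered contigs, and 8× / 20%
across all contigs with more than a threshold number of reads (default
20, exposed as a parameter since conventions vary between 20 and 25).
Multi-allelic columns yield the single most frequent alternate, ties
broken alphabetically. Coordinates are 0-based half-open internally;
VCF output is 1-based per the standard. Per-contig coverage depth is
defined as summed aligned read length divided by contig length.

## Retroelement screening

The internal screen indexes the library's 11-mers and, for each query
diagonal (either strand), extends greedily from the seed in both
directions, keeping the longest arm whose running identity stays ≥ 80%;
a query matches when some diagonal achieves ≥ 50 aligned bases. The whole
diagonal overlap is scanned, so a localized mismatch cluster (e.g. a
planted SSR inside a retro transcript) cannot hide a long flanking match.
These thresholds are a portable proxy for a BLASTn search at E ≤ 1e-6,
whose E-values depend on database size; `external-table` mode consumes a
real BLAST tabular file for exact parity, and the two modes agree exactly
on error-free reads containing ≥ 200 bp library segments.

Keyword classification is case-insensitive whole-word matching on seven
terms (copia, gag, pol, retroelement, integrase, reverse transcriptase,
retrotransposon); "pol" and "gag" match only as standalone words so
"polymerase" never counts. The retro-contig protein classification is an
automated keyword proxy for manual protein-database inspection and is
flagged as such in its output. Abundance percentages are reported to
4 decimals and are re-derivable from their counts by construction.

## Annotation summaries

Best hits keep one record per query at E ≤ 1e-6, ordered by (E ascending,
bit score descending, accession ascending) — the final lexicographic rule
makes the result a total order, hence independent of input row order and
idempotent. Hit tables are the 12-column BLAST tabular dialect, optionally
extended with subject length, taxon label and description (15 columns);
subject intervals follow the 1-based inclusive BLAST convention and are
converted internally to half-open.

The hit-vs-length relationship is fit by maximum-likelihood logistic
regression (`statsmodels`); single-class input, non-convergence, or fitted
probabilities pinned to 0/1 raise a separation error rather than returning
meaningless estimates. Ortholog length ratios divide the query's nucleotide
length by 3 × the subject's residue length by default (configurable to the
raw ratio, since published plots do not always state units; ratios above 1
generally reflect UTR sequence). Union coverage per subject is the length
of the union of aligned subject intervals divided by subject length, capped
at 1 — computed by interval merging and checked against a membership-set
oracle. The transcriptome coverage estimate is
(n_reads × mean read length) / (n_genes × mean gene length) with
Arabidopsis-scale defaults of 25,000 genes × 2,000 bp. Reported precisions
follow the conventions of each summary: whole percent for database-match
fractions, 1 decimal for taxonomy/GO percentages and rates per 100 bp,
4 decimals for retro abundance.

## Synthetic-data generator

The generator emulates the *structure* of a normalized-cDNA 454 experiment,
not its chemistry. Defaults (all in `SimulationConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| gene length | N(2000, 500) bp, min 300 | the mean gene length assumed in coverage estimates |
| read length | N(306, 75) bp truncated [50, 600] | observed mean 306 bp; sd is free (only a histogram is published) |
| SSR plant rate | 0.25 per transcript | ≈ one SSR per four contigs, the observed density scale |
| SSR unit weights | 2:0.771, 3:0.201, 4:0.028 | observed di/tri/tetra proportions |
| SSR repeat counts | 4–12 units | detectable class, < 50 bp total |
| SNP rate | 0.006 per bp | the 0.6/100 bp observed rate |
| allele frequencies | k/8, k = 1..7 | four pooled diploids = eight chromosomes |
| retro fraction | 0.04 | ≈ the 3.9% retro-matched EST fraction |
| contaminant fraction | 0.10 | ≈ the fungal-hit fraction |
| base error rate | 0.004 | an assumption; per-base error characteristics are unpublished |
| quality model | N(28, 6) per base, clipped [2, 40] | typical Titanium-era quality scale; an assumption |

SSRs are planted by overwriting a window (length-preserving) with guard
bases on both sides chosen to break the periodicity, so planted coordinates
are exact and the run is maximal by construction; a primitivity argument
(two incompatible periods force a common divisor period) guarantees a
planted primitive run can never spawn a second reportable locus inside
itself. SNPs are placed on `round(freq × 8)` of 8 explicit haplotype
copies, so a read from a uniformly drawn chromosome carries the alternate
with probability exactly the design frequency; sites inside planted SSRs
are excluded. Retro transcripts are contiguous segments of synthetic
library elements with configurable divergence. Reads are drawn
length-proportionally across transcripts (uniform per-bp coverage, the
idealized result of normalization), from both strands at 0.5, with iid
substitution errors and iid per-base qualities. All randomness flows
through one `numpy` generator seeded from the config, giving byte-identical
FASTA/FASTQ across runs.

What it does **not** emulate — and therefore what passing tests do not
show about real data: 454 homopolymer indel errors and flowgram noise,
position-dependent quality decay, expression-level variation surviving
normalization, chimeric reads, alternative splicing, paralog collapse
during assembly, and real BLAST statistics (fabricated E-values are
decorative). Recovery metrics on synthetic data certify the *logic* of the
detectors, not their field performance.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale — typically 20–40
transcripts, a few thousand reads, 500 random kilobase strings for the SSR
oracle, 10,000 random pileup columns, 100 primer templates, and n = 5,000
for logistic recovery — sizes chosen so the full suite completes in well
under a minute per module while keeping every check statistically
meaningful (binomial/CLT bounds at 3 SD). Frequency threshold comparisons
use an epsilon of 1e-12 to keep `2/10 ≥ 0.20` exact under floating point;
quantiles are numpy linear interpolation; all percent roundings are
round-half-even (Python `round`).
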
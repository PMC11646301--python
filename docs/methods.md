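# Methods

This note documents the models and procedures implemented in `sedchiro`,
the parameter defaults and why they hold, the numerical choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Taxonomy model

Lineages are fixed seven-rank Linnaean tuples (kingdom … species) with no
internal gaps; records known only to an intermediate level (e.g. an
ostracod annotated to order Podocopida) occupy that rank with everything
below absent. Name comparison is exact, case-sensitive string equality
after whitespace normalization — deterministic and reproducible, at the
price of treating spelling/authority variants of the same name as distinct
taxa. No synonym resolution or name correction is attempted.

Sanitization removes open-nomenclature annotations: a rank whose name
contains one of the markers `sp.`, `aff.`, `gr.`, `var.` (whole-token,
case-insensitive; trailing punctuation tolerated, so `sp.` matches the
token "sp." but never "spinosa") is cleared together with every rank below
it, truncating the lineage to the last trustable rank
("*Cladotanytarsus* gr. *mancus*" → genus *Cladotanytarsus*). The
operation is idempotent. The LCA of a lineage collection is the deepest
rank-prefix on which all inputs agree; it is idempotent, commutative and
associative, and an empty input collection is an error (there are no hits
to combine).

## Reference curation and in-silico PCR

Curation: terminal Ns stripped, minimum length 200 bp, no internal Ns,
exact-sequence dereplication. Duplicate sequences with different
annotations merge to the LCA of their sanitized lineages — a conservative
choice that never asserts more resolution than the duplicates agree on.
Dereplication is keyed on the exact full-length string, not on substring
containment.

In-silico PCR matches a degenerate primer at zero cost wherever the
subject base is inside the IUPAC set of the primer character; inosine (I)
matches all four bases (universal-base chemistry — the CH reverse primer
carries two inosines). An N in the subject counts as a mismatch unless the
primer position accepts everything. Both strands are scanned with a
one-mismatch budget per primer; the leftmost forward site wins, with the
nearest downstream reverse site whose implied insert is within ± 10 bp of
the expected length. When both strands yield a qualifying amplicon the
plus-strand hit is kept and a warning logged, keeping output
deterministic. Expected insert lengths are configuration values,
defaulting to 139 bp (CH) and 205 bp (FWH) from the amplicon arithmetic
(fragment length minus both primer lengths).

## Resolution screen

Distances between aligned inserts are raw p-distances in percent with
pairwise deletion: sites carrying a gap or N in either member of a pair
are excluded for that pair; a pair with zero comparable sites is reported
as undefined rather than guessed. A substitution-model-corrected distance
(e.g. K80) would shift values upward; the raw proportion is used because
the screen's output is interpreted as a percent of differing sites.
Inserts are expected pre-aligned (the synthetic generator emits them at a
fixed length, i.e. trivially aligned); multiple sequence alignment is out
of scope.

## Read processing

*Merging.* The overlap length maximizing the number of matching positions
is selected by offset scan; the merge is accepted at overlap ≥ 50 nt with
≤ 10 mismatches. Consensus takes the higher-quality base at conflicts;
merged quality is max(q1, q2) at agreements and |q1 − q2| at conflicts — a
simple, monotone rule chosen over posterior recomputation.

*Trimming.* Linked-primer semantics with a 5′-anchored forward primer: the
forward primer must match at position 0 and the reverse complement of the
reverse primer flush at the 3′ end, each within ⌊0.1 × length⌋ mismatches
(degenerate-aware). Reads lacking either site are discarded.

*Quality filter.* Keep iff |length − expected| ≤ 10, expected errors
Σ 10^(−Q/10) < 1, and mean Phred ≥ 30. "Below Q30" is interpreted as a
read-level mean — a per-base Q30 truncation would duplicate the
expected-error filter's job; the threshold is configurable.

*Denoising.* Swarm-style single-linkage clustering at d = 1: seeds are
taken in decreasing abundance; any unassigned unique within Levenshtein
distance 1 (substitutions and single-base indels) of any cluster member
joins, growing chains. In fastidious mode, clusters with total abundance
below 3 are grafted onto a large cluster when a member sits within
distance 2 of a large-cluster member. The cluster representative is its
most abundant member (ties: lexicographically smallest); no
abundance-gradient subseed splitting is performed — at d = 1 with
desk-scale data the refinement does not change the partition, which
equals the connected components of the distance-≤ 1 graph.

*Chimera removal.* An ESV is flagged iff its sequence is exactly
prefix(A) + suffix(B) for two distinct higher-ranked ESVs A ≠ B, each with
abundance ≥ 16× the query, with the crossover strictly inside the query.
This is the perfect-chimera criterion of uchime3-style de novo detection;
three-parent or inexact chimeras are not modelled. Queries are processed
in decreasing abundance with parents drawn from already-retained ESVs, so
a parent can never be flagged by its own chimera.

*Numt filter.* ESVs are translated in the single forward frame given by
the primer set's codon phase under the invertebrate mitochondrial code
(translation table 5, where AGA/AGG encode serine); any stop codon removes
the ESV. Testing one fixed frame is the default because the primer anchors
the reading frame; sequences too short to hold a codon are removed with
their own reason.

*Mapping.* Quality-filtered reads (pooled across samples) are assigned to
the closest ESV within one edit; ties go to the higher-abundance ESV, then
the lexicographically smaller sequence. Per-sample abundances are
tabulated from the mapping; unmapped reads are counted. Every stage is
deterministic given sorted inputs — the pipeline needs no random seed.

## Taxonomic assignment

Alignment is global Needleman–Wunsch with affine gaps; the scoring
constants (match +2, mismatch −4, gap open −10, extend −1) and the
Karlin–Altschul constants used to express raw scores as bit scores and
e-values (λ = 0.625, K = 0.41, search space 10⁶) are package defaults
recorded in configuration. Under global alignment of near-equal-length
sequences the e-value/bit-score ordering is monotone in raw score, so the
best-hit ranking — e-value ascending, identity descending, bit score
descending, gap openings ascending, mismatches ascending — is well defined
regardless of the constants. Identity excludes terminal-gap columns
(usearch-style); "alignment gaps" is read as gap openings. Hits at ≥ 90%
identity are kept (at most 5000); all hits tied on the full ranking key
are best hits; their LCA is the assignment; species-level assignments
below 95% identity are demoted to genus and flagged. Unassigned ESVs are
retained in outputs with an `unassigned` rank, since unidentified-ESV
proportions are themselves a result. Assignment is invariant under
permutation of the database, and raising the identity floor can only
shrink the detected taxon set.

The full pairwise search is O(|ESVs| × |references|) alignments — adequate
at desk scale; no k-mer prefilter is implemented.

## Morphotype comparison and ordination

Crosswalk lookup is exact on (name, rank); a species absent from the table
falls back to its genus row (morphotypes are frequently genus-level), and
taxa absent at both ranks are dropped and reported — taxa without a
described larva cannot be compared against remains. Abundances are reduced
to presence–absence before ordination because read counts and
head-capsule counts are not comparable quantities; all-zero taxon columns
are removed.

DCA: axis 1 is the first correspondence-analysis axis (computed by SVD of
the standardized residual matrix). Higher axes are extracted by reciprocal
averaging with detrending by segments against all previous axes: the
previous axis is cut into 26 equal segments, row-weighted segment means of
the trial scores are interpolated across empty segments, smoothed with a
(1,2,1)/4 running average, and subtracted each iteration. Smoothing keeps
detrending well-posed when segments hold few samples (raw per-segment
means would annihilate the scores outright for small n). Rare-taxon
downweighting (iweigh = 1) multiplies each taxon column whose total is
below max/5 by total/(max/5); this reproduces vegan's `downweight`
exactly, verified against `decorana` through an Rscript oracle in the test
suite. Rescaling to SD units deshrinks species scores by the axis
eigenvalue and applies a single global scaling that sets the mean
row-weighted within-sample dispersion of species scores to one — a
deliberate simplification of Hill's iterative segment-wise nonlinear
rescaling, so axis lengths are approximate SD units. With detrending and
rescaling disabled the result is plain CA and matches both a
power-iteration oracle (1e−8) and `decorana(…, ira = 1)` (1e−6).

Venn region counts are exact cardinalities of the 2- or 3-set partition;
percentages use half-up rounding at the requested precision, matching the
convention of printed report percentages.

## Synthetic-data generator

The generator encodes the study design it emulates: 3 cores × 3 layers;
two littoral cores sharing a Jaccard fraction ≈ 0.8 of their 10-species
pools against ≈ 0.3 with the deep core (pool overlaps are constructed from
the target Jaccard index, j = o/(2n − o)); layers subsample their core's
pool with retention 0.9; per-taxon abundances are log-normal (μ = 1,
σ = 1). Species inserts are random stop-free 139-mers rejected until every
pair differs at ≥ ⌈0.08 × 139⌉ sites, satisfying the resolution premise by
construction (and verified, not assumed, in tests). Full reference records
are pad + concrete forward-primer expansion + insert + reverse-complement
of a concrete reverse expansion + pad.

Reads are paired 150-mers from the amplicon ends (119 nt overlap on the
181 bp CH amplicon). The quality profile is constant Q35 with 1% of
positions dipping to Q15; substitution probability per base is 10^(−Q/10),
matching the expected-error filter's model. Artefacts: 2% of reads are
two-parent chimeras crossed at a uniform breakpoint inside the insert, 2%
are numts (a premature TAA replacing an insert codon at ≥ 2 substitutions
from the original, so the numt is not absorbed at d = 1), and 5% come from
contaminant templates constructed at < 85% identity to every reference so
they fall below the 90% search floor and stay unassigned. A truth table
records every read's origin class. All randomness flows from one seed
through per-stage child generators; the same configuration is
byte-reproducible.

What the generator does **not** emulate: PCR-cycle amplification bias and
polymerase error accumulation, indel sequencing errors (substitution-only
by default), quality-score miscalibration, length variation among real
CO1 haplotypes, intraspecific sequence variation, and degradation-driven
fragment-length distributions of old sedDNA. Passing tests therefore show
the pipeline's rules behave as specified under controlled conditions —
not that real sediment libraries are free of the corresponding
artefacts.

## Problem sizes

The packaged analyses run at desk scale by design: the default synthetic
study uses 20 species, 9 samples and 1,000–1,500 read pairs per sample;
the acceptance script processes 9,000 read pairs end to end and repeats
the assemblage/ordination design comparison over 20 seeded replicates.

## Known limitations

- DCA rescaling is a global standardization, not Hill's segment-wise
  algorithm; detrended axis scores and lengths are approximations
  (axis 1 and all detrend/rescale-off results are exact).
- Merge consensus qualities use the max/difference rule, not a posterior
  error model.
- The chimera detector only sees perfect two-parent crossovers; real
  chimeras with additional mismatches escape it (and are then usually
  absorbed or left as unassigned singletons).
- Conflicting reference annotations that differ only in spelling or
  authority are treated as distinct names and resolve to their common
  ancestor.
- e-values are reported under fixed Karlin–Altschul constants for ranking
  purposes; they are not calibrated significance estimates.
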
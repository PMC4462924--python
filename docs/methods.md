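# Methods

`itschimera` implements chimera control for fungal ITS (internal
transcribed spacer) sequence collections: constructing a chimera-free
reference dataset from a corpus, simulating benchmark chimeras with known
parents, and reference-mode detection of chimeric queries. This note
records the models, parameter choices and numerical conventions, and what
the synthetic benchmark does and does not demonstrate.

## The biological setting

The nuclear ribosomal ITS region — ITS1, the highly conserved intercalary
5.8S gene, and ITS2 — is the standard fungal DNA barcode, averaging about
550 bp across the kingdom. During mixed-template PCR, an aborted extension
product from one template can prime on another, producing chimeras; the
conserved 5.8S is a natural bridge point, so a typical artefact carries
ITS1 (+ part of the 5.8S) from one species and the rest from another.
Reference-mode detectors decide whether a query is explained better by a
two-parent model drawn from a trusted reference set than by any single
reference.

## Pairwise identity and alignment conventions

One scoring scheme is used everywhere (clustering, 5.8S anchoring, chimera
scoring): match +1, mismatch −1, gap open −2, gap extension −1 (a gap of
length L costs 2+(L−1)). Identity is the fraction of matching columns over
all alignment columns after trimming terminal gap columns. Alignments come
from Biopython's `PairwiseAligner`; the first reported optimal alignment is
used, and the argument order is canonicalised (lexicographically) before
aligning so identity is exactly symmetric even when co-optimal alignments
with different column statistics exist. IUPAC ambiguity codes are retained
and match only themselves — a parameter-free convention that keeps every
comparison reproducible. Coordinates are 0-based half-open throughout.

## Reference-set construction

Two-stage greedy centroid clustering, with records processed in decreasing
length order (ties by id); each record joins the first centroid it matches
at or above the threshold, else founds a centroid. Stage one clusters the
corpus at 80% identity (genus/subgenus level); stage two refines each genus
cluster into species hypotheses (SHs) at 97–100% identity in 0.5% steps.
The species levels are produced hierarchically — each SH's members are
re-clustered at the next higher threshold — so SHs nest across thresholds
by construction (a single independent pass per threshold would not
guarantee this). SH identifiers are content-derived hashes of the sorted
member ids plus the threshold, so identical inputs yield identical ids.

The representative of an SH at the 98.5% level is the most frequent exact
sequence type; ties break by length (longest first), then lexicographic id.
Manually designated reference sequences supersede the automatic choice, and
their provenance is recorded as `manual`. Singleton SHs are excluded unless
explicitly sanctioned. The reference set holds one sequence per SH.

A caveat on exact species recovery: with conspecific sequences ~1%
divergent on average, Poisson fluctuation occasionally pushes a member pair
past the 1.5% threshold, splitting off a small SH. The SH count at 98.5%
therefore tracks, but does not exactly equal, the number of true species;
the species *partition* at 97% is recovered essentially perfectly (Rand
index > 0.95 in tests).

## 5.8S anchoring and subregion extraction

Rather than a profile-HMM battery, the 5.8S is located by a glocal
alignment: the consensus must align end-to-end while the record's overhangs
are gap-free. Because the gene is nearly invariant, the optimal placement
spans the true gene exactly even when the record carries 5.8S point
substitutions (a plain local alignment would trim a mismatching first or
last base). A placement must score at least half the consensus length
(match +1 / mismatch −1), far above random placements, which score near
zero. Everything upstream of the anchor is ITS1, everything downstream
ITS2. The approach assumes forward-strand ITS amplicons without long
SSU/LSU flanks; inputs with >200 bp of flanking rDNA are out of scope.

## Benchmark simulation

Every annotated reference is bisected at `r58s.start + floor(len(5.8S)/2)`
(floor rule for odd lengths). Right halves are reassigned by a uniform
random derangement — rejection-sampling random permutations until none has
a fixed point (acceptance → 1/e, so ~e draws regardless of n). This reading
of "random reshuffling without self-grafting" guarantees the chimera count
equals the reference count and each reference is used exactly once per
side; sampling with replacement would not. Replicates draw from
`SeedSequence.spawn` child streams, so each replicate is independently
reproducible. Reshuffling is global (not constrained within genera), so
nearly all simulated chimeras have parents from different genera.

## The chimera score

Both candidate parents are globally aligned to the query and projected onto
query coordinates (columns where the query has a gap carry no coordinate
and are dropped; a parent deletion appears as `-` and mismatches every
base). Columns where query and both parents agree are ignored. For the
model "A left of the crossover, B right of it", each informative column
votes *yes* (query matches the side's own parent and not the other), *no*
(the reverse) or *abstain* (query matches neither). Each side earns a
support factor and the weaker side sets the score:

    f_side = Y / (beta*N + alpha*A + reg)        beta=8, alpha=0.5, reg=1
    h      = min(f_left, f_right)^2

maximised over all crossovers (via prefix sums over informative columns)
and both orientations. Ties prefer the earlier crossover and the (A,B)
orientation, making the optimum deterministic. A perfect chimera with ten
clean diagnostic columns per side scores min(10/1, 10/1)² = 100; scores are
unbounded above. Two gates must hold at the optimum:

* `min_diffs` (default 10): at least ten *yes* votes on each side. At
  species-level divergence a genuine half-parent contributes tens of
  diagnostic columns, while chance runs of one-sided agreement near a
  sequence end rarely reach ten.
* `min_div` (default 0.8 percentage points of query length): the two-parent
  model must have fewer mismatches than the best single parent by at least
  this margin — a clean query between two relatives gains almost nothing
  from a second parent.

The per-side *minimum* (rather than a pooled ratio or a product of a large
and a small factor) is the load-bearing choice: in pilot simulations,
pooled or product forms let the crossover maximiser exploit short terminal
windows of chance agreement on one side, flagging 14–37% of clean
reference queries; the min-form with `min_diffs=10` drove false positives
to zero while leaving three orders of magnitude between clean and chimeric
scores. The flagging threshold is 0.28; it sits in the wide gap between
the clean score distribution (≲0.1) and genuine chimeras (≳100 here).

Candidate parents are found by cleaving the query into four near-equal
segments (longer first) and ranking references per segment by the number of
distinct shared 8-mers (ties by id); the top four per segment are pooled.
Unordered candidate pairs are enumerated in rank order up to `max_pairs`
(24). These are search heuristics: with exhaustive settings the detector
provably returns the brute-force maximum over all pairs and crossovers
(tested). Self-exclusion is by record id only, for screening a corpus that
contains its own references.

## Statistics

Detection rate is the flagged fraction per replicate, summarised by mean
and sample SD (n−1; NaN for a single replicate), in percent. Flagged
scores are binned into (0.28, 1], (1, 10] and (10, ∞) — left-open,
right-closed at the printed boundaries. Group comparison uses the
two-sided Wilcoxon–Mann–Whitney test with midranks, tie-corrected variance
and continuity correction (SciPy's asymptotic method, matching R's default
for large samples), with medians reported alongside. Tests cross-check the
asymptotic p against exact permutation enumeration for small groups; in
deep tails (p < ~0.01) the normal approximation is intrinsically a
relative-error-tens-of-percent estimate, as for any asymptotic
implementation.

## The synthetic corpus

The generator emulates the nested similarity structure of curated fungal
ITS data: one corpus-wide 5.8S ancestor (158 bp, a typical fungal 5.8S
length) drifted per species at 0.002 substitutions/site (no indels, so the
anchor stays well defined); independently drawn per-genus ITS1/ITS2
ancestors (170–220 and 175–225 bp, mean total ≈550 bp); species spacer
templates at 0.05 divergence from the genus ancestor; records at 0.005 from
the species template. Ten percent of spacer mutation events are single-base
indels. Lengths are uniform in their ranges. Generation is a pure function
of the spec (seed included).

What the benchmark does **not** show: real chimeras preferentially join
*closely related* templates, breakpoints are not always mid-5.8S, real
corpora contain ambiguity codes, orientation errors, chimera-free-reference
violations and taxa missing from the reference set. Detection of 99%+ on
the synthetic benchmark therefore bounds ideal-condition behaviour, not
field performance; on real data a sequence flagged near the threshold
warrants manual review, and queries whose parents are absent from the
reference set can be neither flagged nor cleared reliably.

## Problem sizes

The shipped benchmark uses 40 genera × 3 species × 3 sequences (120
species, 360 records, ~120 references) with ten replicates — the package's
default desk-scale configuration, chosen so a full run completes in a few
minutes on one core while every species still has the multi-member
structure the SH pipeline requires. All pipeline stages scale linearly in
the number of query–reference alignments.
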
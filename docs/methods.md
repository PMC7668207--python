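# Methods

## Problem setting

Therapeutic L-asparaginases are screened for predicted MHC class II
immunogenicity before any experimental work: CD4+ T-cell help drives the
anti-drug antibody responses that limit the *E. coli* enzyme in the clinic,
and MHC-II presentation of 9-mer peptide cores by HLA-DRB1 molecules is the
rate-limiting, predictable step. `asnscreen` ranks candidate enzymes by how
many strong predicted binders they carry, how strong those binders are, and
how many alleles of a standard 8-allele HLA-DRB1 panel (DRB1\*01:01, 03:01,
04:01, 07:01, 08:01, 11:01, 13:01, 15:01 — collectively covering >95% of the
population) they touch, relative to the EcAII reference.

## Sequence intake and clustering

Candidates enter as FASTA. Records outside configurable length bounds are
excluded as putative partial or aberrant sequences; the defaults, 316–428
residues, are the extremes observed in the curated representative table
shipped with the package. Sequences containing ambiguity codes (X/B/Z/U) are
rejected by default; when admitted, those residues never count as identical
in alignments and match only wildcard motif positions, keeping both identity
and motif calls conservative.

Redundancy is removed by greedy incremental clustering in the CD-HIT style:
records are processed longest-first (ties by id, making the procedure
deterministic), each joining the first established representative it matches
at or above the cutoff (default 0.6), otherwise founding a new cluster. The
identity between two sequences is the number of identical columns in an
optimal global alignment divided by the shorter sequence's length — the
CD-HIT denominator convention. The alignment maximizes match +1 / mismatch 0
with a linear gap penalty of −0.5 and free end gaps. Because co-optimal
alignments under this scoring can differ in how many identical columns they
contain, the implementation maximizes (score, identity count)
lexicographically in a single packed-integer dynamic program, so the reported
identity is well defined and deterministic. The resulting partition
guarantees: members reach their representative at ≥ cutoff, and
representatives of distinct clusters sit below it pairwise.

## Motifs and family labels

The two asparaginase families are told apart by conserved sequence motifs
rather than profile HMMs (a deliberately lightweight proxy; it is *not* a
PFAM domain call). Motifs are written as fixed residues plus `x` wildcards
(`x(n)` for runs), e.g. the PF06089.11-family blocks `NCSGKHxAM`, `DGCGAPL`,
`SHSGEx(2)H`, `PRSx(2)KPxQ` and the active-site motif `SHTGQxHFV`; for
PF00710.11 the packaged set uses the catalytic-threonine context motifs of
bacterial type-II asparaginases (`GGTIA`, `HGTDT`), which are expressible in
this notation. Scanning reports every overlapping occurrence with 1-based
inclusive coordinates; a sequence is labeled with the family whose motif set
hits more often, `unassigned` with no hits, `ambiguous` on ties.

## Epitope prediction

Each protein is tiled into its L−14 overlapping 15-mer windows. The in-repo
scorer is an additive pocket-profile matrix per allele — 9 positions × 20
residues of binding-contribution weights, Sturniolo/TEPITOPE style. A 15-mer's
raw score is the best of its seven 9-mer frames (ties resolved to the
smallest offset for determinism); the winning frame is the putative binding
core.

Raw scores are mapped to percentile ranks against a background of random
15-mers scored identically (best-of-seven frames, so query and background
live on the same scale): the percentile is 100 × the fraction of background
peptides scoring *strictly* above the query, making 0 the strongest possible
rank, 100 the weakest, and ties non-penalizing. The background is drawn
residue-wise from configurable amino-acid frequencies — uniform by default
(the maximal-entropy null used throughout the tests); a Swiss-Prot-like
composition table ships as an alternative for realism. The default background
size is 100,000 peptides per allele, a size at which the 1st-percentile
boundary relevant to the core filter is estimated from ~1,000 order
statistics; it is configurable. Backgrounds are seeded per allele from one
spawning seed sequence, so runs are exactly reproducible.

The consensus percentile rank (CPR) of a (window, allele) pair is the median
of the per-method percentiles. Only the pocket-profile method is computed
in-repo; percentiles exported by external MHC-II predictors can be supplied
as TSV tables and enter the same median. When a method lacks coverage for an
allele the median is simply taken over the methods present. With a single
method the CPR equals that method's percentile, which is the configuration
all in-repo tests exercise.

Windows with CPR < 2 count as high-affinity binders. From each, the
best-scoring 9-mer frame per allele is rescored on its own, and the core is
retained only when its pocket-profile percentile is < 1 — the core's own
percentile, not the parent window's, is gated, which is the stricter and
better-defined choice. Retained cores are deduplicated by (protein, allele,
core start), pooling the overlapping source windows; this prevents a single
planted or natural binder from being counted once per covering window.

## Screening statistics

Per protein:

* **epitope count** *n*: distinct (core sequence, start) pairs, pooled across
  alleles — allele multiplicity is deliberately *not* multiplied into the
  count;
* **mean CPR** $\bar{c}$: arithmetic mean over counted epitopes of each
  epitope's minimum core percentile across alleles (its strongest allele);
* **allele coverage**: distinct panel alleles with ≥ 1 retained core — the
  population-coverage proxy;
* **epitope density**: $\mathrm{ED} = n(2-\bar{c})/(L-s+1)$ with epitope size
  $s=9$ (the counted unit is the 9-mer core; $s$ is configurable to 15 for
  window-based counting). ED is linear in $n$, strictly decreasing in
  $\bar{c}$ on [0, 2) and in $L$, and zero iff $n=0$.

Per-residue density maps add one count to each of the nine positions covered
by every (core, allele) instance, so the map total is exactly 9 × the
instance count — an invariant asserted in tests.

The curated screening table shipped with the package carries its tabulated
ED values verbatim. Recomputing ED from the tabulated epitope numbers, CPRs
and lengths does **not** reproduce the tabulated values (most plausibly the
tabulated density was computed from a different epitope count than the
tabulated 9-mer core number); the loader
therefore treats tabulated EDs as opaque data and reports the recomputation
mismatch as a warning, never an error. All cross-candidate comparisons
(extrema, candidates above the reference) use the tabulated values
consistently, so they are unaffected by the unit question.

## Candidate ranking

Candidates are compared to a named reference (EcAII in the shipped table):
`compare_to_reference` lists everything with strictly higher ED, and
`select_candidates` computes the Pareto front under joint minimization of
(ED, allele coverage, antigenicity probability) — dominance requires ≤ in
all three criteria and < in at least one. A weighted composite was rejected
on purpose: the three criteria are stated as independent "lower is better"
axes with no principled weights, and Pareto dominance is the assumption-free
order. The selected set equals the front, optionally restricted to one
family label; the reference is never selectable. Antigenicity probabilities
are consumed from an external predictor's TSV — computing them is out of
scope.

## Synthetic data

The generators emulate the screening inputs, not protein biology:

* `generate_pssm` plants one favored 9-mer in an otherwise standard-normal
  matrix, raising the favored residues until the core sits ≥ `contrast`
  standard deviations above the mean random-9-mer score. At contrast ≥ 10 the
  favored core outranks every random peptide in practice; at tiny contrast it
  is deliberately not separable.
* `generate_proteome` draws proteins of 300–430 residues (i.i.d. residues
  from a configurable frequency model) and splices planted cores at stated
  positions, overwriting rather than inserting so lengths stay fixed;
  overlapping plants are an error. The realized truth table is returned.
* `generate_homolog_family` derives equal-length members from one random
  ancestor by per-site substitution at rate *r*, drawing replacements
  uniformly over the whole alphabet (silent substitutions allowed); expected
  pairwise identity follows the two-independent-draws coincidence formula and
  is ~0.81 at r = 0.1 on 20 letters — comfortably above the 0.6 clustering
  cutoff, while unrelated random proteins align near 0.3–0.4.
* `generate_screening_table` emits tables whose unique ED extrema are planted
  ids, for exercising ingest and comparison code.

What the synthetic data does *not* emulate: indels and domain architecture
(so clustering is tested in the substitution-only regime), true MHC binding
chemistry, correlated residue composition, and any relationship between
antigenicity scores and sequence. Passing the planted-recovery tests
therefore demonstrates that the pipeline's bookkeeping and thresholds behave
as specified, not that the pocket-profile scorer predicts real epitopes —
for real screening, externally validated matrices or predictor exports are
the intended inputs.

The standard end-to-end check runs 10 proteins × 2 alleles with 8 planted
cores on each of 9 proteins and one background-only control. These sizes
keep the whole run under a few seconds while leaving a wide statistical
margin: the control's expected ED (driven only by the ~1% false-positive
rate intrinsic to a percentile-1 cutoff) sits several standard deviations
below every planted protein's, and planted cores at contrast 12 exceed the
entire 100,000-peptide background, so recovery is complete for any seed.

## Numerical and design notes

* Percentile calibration uses strictly-greater counting on a sorted
  background (binary search), exactly matching brute-force counting.
* Median consensus uses `numpy.median`: for even method counts, the mean of
  the two central order statistics.
* Frame ties in window scoring and ordering ties in ranking are broken
  deterministically (smallest offset; lexicographic id).
* The identity DP packs (2×score, identities) into one integer with base
  512; sequence length is capped below 512 residues, ample for asparaginases
  (~330–430 aa).
* Degenerate inputs: proteins shorter than 15 residues yield zero windows
  (warning, not error); zero retained cores yield a screening row with
  ED = 0 and mean CPR 0; an empty background or empty consensus input is a
  domain error.
* Accession version suffixes are stripped when joining the screening table
  to the family/length table, because curated sources are inconsistent about
  carrying them.

## Known limitations

* Only the pocket-profile scorer is implemented; consensus quality on real
  data depends on supplying external predictor percentiles.
* Motif-based family labels are a heuristic stand-in for profile-HMM domain
  assignment and will mislabel divergent family members.
* The greedy clustering is exact but quadratic in the number of sequences
  per representative comparison; it targets hundreds, not millions, of
  sequences.
* Antigenicity is an opaque external score; the Pareto selection is only as
  meaningful as that input.
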
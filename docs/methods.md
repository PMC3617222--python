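# Methods

## Model

Each protein is represented solely by its amino-acid composition: the vector
of relative frequencies of the 20 standard residues, `f(a) = count(a) / L`
with `L` the protein's declared residue length. This representation is
order-free by construction — permuting a sequence leaves its vector
unchanged, and the composition of a concatenation is the length-weighted
average of the parts. Similarity is Euclidean distance between frequency
vectors, and structure is extracted with agglomerative hierarchical
clustering, so no number of clusters has to be chosen in advance; flat
partitions are obtained afterwards by undoing the last k−1 merges.

Nonstandard residues (B, Z, X, U, O) are counted in the denominator but not
assigned to any column, surfacing as a `nonstandard_fraction`; rows
containing them sum to less than 1. The alternative — renormalising over
standard residues only — would silently change what a frequency means, so it
was rejected. Affected records trigger a warning.

## Linkage schemes and conventions

The merge hierarchy is maintained with the Lance–Williams recurrence
d(k, i∪j) = αᵢ d(k,i) + αⱼ d(k,j) + β d(i,j) + γ |d(k,i) − d(k,j)| using the
standard coefficients for single, complete, average (UPGMA), weighted
(WPGMA), Ward, centroid (UPGMC) and median (WPGMC). Three conventions are
fixed explicitly, since they vary between implementations:

* **Euclidean in, Euclidean out.** For Ward, centroid and median the
  recurrence runs on squared distances and merge heights are reported as
  square roots. Consequence: two singleton clusters always merge at exactly
  their Euclidean distance, for every scheme.
* **Tie-breaking.** When two candidate merges are equidistant, the pair with
  the lexicographically smaller (min cluster index, max cluster index) wins,
  with leaves indexed 0..n−1 and the k-th merge creating cluster n+k. The
  fast path and the oracle implement the same rule, so their outputs can be
  compared exactly.
* **Inversions.** Centroid and median are not reducible, so a merge may be
  lower than an earlier one. Inversions are preserved (never reordered) and
  propagate into negative branch lengths in the tree, with a warning.

The five reducible schemes use the nearest-neighbor-chain algorithm — O(n²)
distance evaluations, with merges re-sorted by height afterwards, valid
because their heights are monotone. Centroid and median use the generic
repeated-global-minimum algorithm, because the chain algorithm is incorrect
for non-reducible schemes. Distances are kept in a condensed double array
(n(n−1)/2 entries) and distance computation is row-chunked, so memory
scales to proteome-sized inputs (~1.6 GB of condensed distances at n ≈
20,000); the nearest-neighbor-chain path needs no additional quadratic
storage.

## The independent oracle

`naive_linkage` validates the fast path. It never uses Lance–Williams:
single/complete/average distances are recomputed as min/max/mean over the
original pairwise distances of the merged members; weighted and median use
bilinear forms with dyadic (2^−depth) leaf weights; Ward and centroid
recover the centroid separation from quadratic forms of the squared-distance
matrix (‖c_A − c_B‖² = w_Aᵀ D² w_B − ½ w_Aᵀ D² w_A − ½ w_Bᵀ D² w_B for
uniform weights, Ward scaled by 2n_An_B/(n_A+n_B)). The test suite and the
acceptance script require exact topological agreement and heights within
1e-9 across hundreds of random instances of all seven schemes; scipy's
hierarchy module provides a second, external cross-check via cophenetic
distances.

## Numerical choices

* Rounding mode: three decimals, half away from zero (the digit count is the
  only convention fixed by the historical table format; the tie rule had to
  be chosen). Rounded and full-precision tables differ by at most 0.0005 per
  cell (plus one double ulp on exact ties). Clustering defaults to full
  precision; `--round3` reproduces the fixed-precision table.
* Composition tables and merge tables are written as TSV with `repr`-exact
  floats in full-precision mode, so a write/read round trip is bit-exact and
  stage-by-stage CLI invocation is byte-identical to the single-shot
  pipeline.
* Newick branch lengths are printed with 12 significant digits: 9 digits
  (the minimum some tools emit) cannot guarantee the package's own 1e-9
  round-trip tolerance on branch lengths of magnitude ~1.
* Internally, squared-distance updates for centroid/median are clipped at 0
  before the square root; genuinely Euclidean inputs never need the clip.
* Degenerate inputs: clustering requires ≥ 2 points; zero-length sequences,
  negative or non-finite distances, label/leaf count mismatches and
  out-of-range cuts raise immediately.

## Subtree and concordance semantics

A subtree selector (glob over leaf labels) returns the **minimal containing
clade**: the deepest internal node whose leaf set contains every selected
leaf, with all bystander leaves retained — the neighbourhood of a family in
the tree is usually the scientifically interesting part. `--prune`
additionally offers the selection-only view (unary nodes collapsed, branch
lengths summed).

Concordance with a reference classification is **best-clade Jaccard
recovery**: for family F, max over clades C of |F∩C|/|F∪C|. It is 1 exactly
when the family is a clade, needs no tree cut, and is invariant under leaf
reordering. Families of size 1 are reported but excluded from the summary
mean (they trivially score 1). The summary also reports the fraction of
families scoring ≥ 0.5. For flat partitions (simulation studies) the
adjusted Rand index is used. No claim is made that any particular published
"overlap" percentage is reproduced by these metrics; that would require the
original database release and an exactly specified metric.

## Synthetic data

The generator emulates families of proteins whose residues are i.i.d. draws
from a family-specific composition profile, itself drawn from a symmetric
Dirichlet over the 20 standard amino acids. This is the correct null for a
composition-only method: it contains exactly the signal the method can see
(letter frequencies) and none it cannot (motifs, domains, residue order).
Defaults define the package's standard recovery study: 5 families × 20
members, length 500, profile concentration 0.05 (profiles concentrated on a
few residues, hence well separated). Optional per-protein jitter re-draws
each member's profile from a Dirichlet centred on the family profile
(default off). Everything is reproducible from a single seed, and the
fixture writers emit the exact FLAT/FASTA dialects the parsers read.

What passing recovery tests shows — and does not show: with well-separated
profiles and length-500 proteins, Ward clustering at the true family count
recovers the simulated partition essentially perfectly (ARI 1.0 in 20/20
replicates at concentration 0.05, and still at 5.0, where profiles are much
closer but multinomial sampling noise at length 500, ~0.02 per coordinate,
remains smaller than typical profile separation). Real proteomes are not a
mixture of i.i.d.-residue families: compositions vary continuously, family
sizes are skewed, and lengths span two orders of magnitude. Synthetic
recovery validates the machinery, not a biological claim.

## Problem sizes

The default test suite clusters instances up to n = 50 against the O(n³)
oracle (hundreds of instances), round-trips 100 random trees, and runs the
recovery study at 40 × 100 proteins; the whole suite finishes in well under
a minute. The acceptance script uses 20 recovery replicates per
concentration and 30 oracle/MST instances. A full proteome-scale run
(n ≈ 20,000) is supported by the same code path via the condensed distance
array and is an out-of-suite workstation job.
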
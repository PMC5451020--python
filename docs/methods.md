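# Methods

## Distance model

Distances are Kimura two-parameter (K2P) estimates. For a sequence pair,
alignment columns where either sequence carries a gap, an N or an IUPAC
ambiguity code are excluded (ambiguity codes are treated as missing rather
than partially matched, avoiding arbitrary weighting). Over the remaining
n sites, P is the fraction differing by a transition (A↔G, C↔T) and Q by a
transversion, and

d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)]  (expected substitutions/site).

When n = 0 or either logarithm factor is non-positive (substitution
saturation) the distance is UNDEFINED (stored as NaN). UNDEFINED
propagates: summaries exclude such pairs and report how many were dropped,
neighbour joining refuses matrices containing them, and bootstrap
replicates that produce them are dropped and counted. Saturation is
diagnostic information and is never clamped to a number.

Gap handling defaults to **pairwise deletion**, which maximizes usable data
when fragments of heterogeneous length are pooled; **complete deletion**
(drop every column containing any missing character before all
comparisons) is available as a sensitivity switch. Distance summaries
report min/max/mean and a standard error defined as the sample standard
deviation of the pairwise distances divided by √(number of pairs); pairwise
distances are not independent, so this SE is descriptive, not inferential.

## Barcoding-gap and cutoff statistics

Per species, Max-WSD is the largest defined conspecific distance; species
with one sequence (singletons) have none and are excluded from the gap
analysis. Per species pair, the pair-level Max-WSD is the **maximum** of
the two species' values — the conservative choice, since a gap claimed
against the larger within-species spread is the harder claim — and the
pair has a barcoding gap when Min-BSD (smallest cross-species distance)
**strictly exceeds** it; ties count as no gap, again the conservative
reading.

The cutoff analysis uses the group's overall Max-WSD (largest Max-WSD over
all its species) as a conservative identification threshold and flags every
species pair with Min-BSD **strictly below** it. Unlike the gap analysis it
includes pairs involving singletons, because between-species distances
exist regardless of within-species sampling. The two analyses therefore
have different denominators: C(k, 2) over the k species with ≥ 2 sequences,
and C(m, 2) over all m species carrying data for the gene. Applied to the
published per-species sequence counts of the cereal-aphid parasitoid
reference library (embedded in `barcodegap.refcounts`; for COI only the
~658 bp fragments count, and 16S pools the ~468 bp and ~342 bp amplicons),
these laws give 91, 120 and 210 gap-analysis pairs for non-Aphidiinae COI,
non-Aphidiinae 16S and Aphidiinae COI. Some published cutoff-analysis
totals (e.g. 211 or 232) are not of the form C(m, 2) under any species
subset we can construct; the package documents its own rule and reports its
own denominators.

Two species are "identical" when some sequence of one matches some sequence
of the other at every site where both carry an unambiguous base, with at
least one comparable site. Ignoring gap/N columns pairwise lets fragments
of different lengths match on their shared region, which is how identical
18S fragments across species are actually detected in mixed-length
libraries. Species groups are the connected components (size ≥ 2) of the
resulting graph.

## Overlap trimming and QC

Genes amplified as multiple overlapping fragments are reduced to the column
range covered by every sequence. Coverage is defined by each sequence's
leading/trailing gap-or-N flanks only; internal gaps do not shrink the
overlap, because fragments are contiguous subregions of the amplicon. The
operation is idempotent and errors on disjoint spans.

The pseudogene screen removes gaps, translates all three frames under NCBI
table 5 (invertebrate mitochondrial; configurable — the study taxa are
insects), skips codons containing N/ambiguity, and does not count a stop in
the final codon as internal. With no external reference frame, the best
frame is the one with the fewest internal stops (ties → lowest index),
standard NUMT-screening practice. A sequence is a frameshift suspect when
every frame carries at least ⌈L/300⌉ internal stops — roughly the stop load
expected of non-coding sequence, scaled to fragment length. Verdicts follow
the contract *clean ⇔ no internal stops in the best frame and no frameshift
signature*; note that a single stop in an otherwise stop-free low-complexity
repeat can be absorbed by an alternative clean frame (see the ATT-repeat
test case) — a false negative inherent to reference-free frame selection.

## Neighbour joining and bootstrap

Saitou–Nei agglomeration: join the pair minimizing
Q(i, j) = (r − 2)·d(i, j) − Σ_k d(i, k) − Σ_k d(j, k), with standard limb
lengths. Ties in Q are broken lexicographically on the smallest leaf name
contained in each cluster, making output deterministic. The Q minimum is
taken over one matrix triangle because the vectorized Q evaluation is
asymmetric at one ulp. Negative limb lengths are clamped to zero with the
deficit moved to the sibling limb, preserving the joined pair's distance;
the final three-way join clamps negatives to zero. On additive matrices NJ
is exact; the test suite and acceptance script verify topology and
path-length recovery to 1e-9 on random additive matrices, and cross-check
topology against scikit-bio's independent NJ implementation.

Bootstrap support follows the reference-topology convention (as used by
common phylogenetics GUIs): the tree from the full alignment is kept, and
each of its internal edges is labelled with the percentage of
column-resampled replicate trees (same alignment length, columns drawn
uniformly with replacement from a single seeded generator) containing the
same bipartition. The production default is 2,000 replicates; tests and the
acceptance script use 100–200 to keep runtimes in seconds, which is ample
for supports near 100%.

## Synthetic data generator

The simulator evolves sequences site-independently under the exact K2P
transition kernel (matrix exponential of the Kimura rate matrix) with
transition/transversion **rate** ratio κ (default 2; the expected
transition:transversion *count* ratio at small divergence is κ/2) and equal
base frequencies, as the K2P model requires. Species centroids descend from
a random root along a species tree; individuals descend from centroids with
branches of intra_divergence/2, so expected conspecific divergence equals
intra_divergence. Two tree shapes: **star** (every centroid pair exactly
inter_divergence apart — analytic control, used wherever a separation
guarantee is asserted) and **yule** (random topology, join depths uniform,
rescaled so the mean centroid pair divergence equals inter_divergence —
realistic heterogeneity, with no lower bound on the closest pair).
Defaults (10 species × 4 sequences, 658 bp, intra 0.01, inter 0.20) emulate
a COI-like barcode study with conspecific divergence well below the
heterospecific range observed in real parasitoid libraries (within-species
up to ~0.17, between-species up to ~0.42).

What the simulator deliberately omits: indels and alignment error (the
pipeline consumes aligned data; gap handling is exercised by constructed
fixtures and the fragment-masking helper), among-site rate heterogeneity,
base-composition bias, coalescent population structure and selection.
Passing tests on synthetic data therefore demonstrate correctness of the
statistics and their bookkeeping under the model's own assumptions, not
robustness to real-data violations of them. Degenerate cases found in real
libraries are reproducible on demand: singleton species (per-species sample
sizes), cross-species identical sequences (`share_centroid_pairs` with zero
intra-divergence) and cryptic deep splits (per-species intra-divergence),
the mechanism by which a species with large within-species divergence
loses its barcoding gap against a close neighbour. `coding_mode` draws the
root from stop-free codons of the chosen genetic code so the QC screen has
realistic protein-coding input; substitutions may still create stops, and
the QC tests cross-check every flag by independent translation.

## Pipeline

`run_marker_evaluation` analyzes each gene × group: optional short-fragment
filter (default: COI records need ≥ 400 ungapped sites, excluding
sub-length amplicons with too few diagnostic characters), optional overlap
trimming (default for 16S), QC for protein-coding genes, distances,
summaries, gap/cutoff tables, identical-sequence groups, scatter data and a
bootstrapped NJ tree, plus a JSON manifest of parameters, seeds and counts
(dropped sequences, UNDEFINED pairs, dropped replicates, singletons). Group
membership comes from the metadata sidecar, and each input file's gene is
pinned onto its sequences, since a sidecar keyed by specimen cannot
disambiguate markers for specimens sequenced at several genes. The run is a
pure function of (inputs, configuration, seed); per-analysis bootstrap
seeds are derived from the run seed by enumeration order.

## Validation sizes

The acceptance script uses 1,000 random (P, Q) points for the closed-form
check, 200 random small datasets (≤ 8 species × ≤ 5 sequences, 120 bp) for
brute-force equivalence, 100 random additive matrices (4–12 taxa) for NJ
exactness, and one 10 kb, 10-species × 4-sequence star-mode library with
100 bootstrap replicates for parameter recovery — sizes chosen so the whole
script completes in well under a minute while keeping Monte-Carlo noise far
below the tested tolerances.
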
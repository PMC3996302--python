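# Methods

## Sequence preparation

Input FASTA is read verbatim, preserving letter case (soft-masking: lower
case marks repeats found by RepeatMasker-style tools). When repeat/unique
analysis is requested, each record is first partitioned by case — all
upper-case runs concatenated in order, likewise the lower-case runs — and
the two compartments are fragmented independently; this concatenate-then-cut
order is deliberate, so windows never straddle a repeat/unique boundary
mixture of the original coordinates.

Fragmentation uses consecutive non-overlapping windows from position 0
(default 100 000 nt, configurable; 50 kb behaves similarly for signature
work). The trailing remainder shorter than one window is discarded rather
than padded: the analysis is defined on fixed-length fragments, and a
padded or short tail would enter the composition space with a different
sampling variance. Every character outside {A, C, G, T} (case-insensitive)
counts as undetermined — ambiguity codes (R, Y, W, …) are collapsed onto N
so the counting alphabet stays closed. A fragment is excluded when its
undetermined fraction *strictly exceeds* 20% (a fragment at exactly 20% is
kept); included fragments are normalized by their effective (non-N) length.
Coordinates are 0-based half-open throughout.

## Degenerate k-mer composition

`build_index(k, mode)` maps all 4^k k-mers onto slots. In degenerate mode a
k-mer and its reverse complement share one slot (for odd k: 4^k/2 slots —
512 for pentanucleotides; for even k, self-complementary words get
singleton slots, e.g. 10 slots at k=2, 136 at k=4). Slots are ordered
lexicographically by their canonical (smaller) member, which fixes the
serialization. Counting slides a width-k window with step 1; a window
containing any non-ACGT character contributes nothing — no fractional
attribution — which combined with effective-length normalization keeps
frequencies comparable across fragments with different N content.

The mononucleotide composition of a composition vector is read off the
vector itself, not recounted from sequence: each slot is expanded into its
member k-mers (a complementary pair at half weight each), letters are
tallied weighted by the slot values, and the result normalized to sum 1.
This is the right definition for per-lattice diagnostics, where only the
weight vector exists. The expected slot frequency under that composition is
the product of base frequencies over each member k-mer, summed over
members; the observed/expected ratio then isolates k-mer-specific structure
(CpG suppression, motif enrichment) from plain base content. Conventions
that keep the ratio a total function: 0/0 → 1, x/0 → +inf (clipped to the
deepest red when rendered).

## The map

PCA is computed on the covariance (not correlation) of the frequency
vectors — no variable scaling, since the lattice is meant to span the
widest raw scale of the distribution. Eigenvector signs are fixed by making
each eigenvector's largest-magnitude component positive; otherwise the map
could mirror arbitrarily between runs. When the second eigenvalue is
numerically zero the second lattice dimension collapses to J=1 with a
warning.

Lattice sizing targets about four fragments per lattice point: with
ρ = σ2/σ1, `I = round(sqrt(n / (4ρ)))` (floored at 2) and J is the smallest
integer strictly greater than ρ·I. Initial weights follow

    w_ij = x_av + (5σ1/I)[b1(i − I/2) + b2(j − J/2)]

with 0-based i ∈ {0…I−1}, j ∈ {0…J−1}; the half-step asymmetry for even
I or J affects only the initial geometry, not the trained topology.

Training alternates full batch assignment (Euclidean best match, exact ties
broken to the smaller row-major lattice index) with the batch update: for
each lattice point, the weight moves by a fraction α(r) toward the weighted
mean of all fragments whose best match lies within Chebyshev radius β(r).
α decays linearly from 0.6 to 0.01 over the epochs (default T=100);
β starts at ceil(I/10) and shrinks by one per epoch, never below 1. Points
with an empty neighborhood keep their weights that epoch.

Inside the radius the contribution is tapered by a Gaussian in lattice
distance, σ = max(0.5, β/2) (`kernel="gaussian"`; a uniform box mean is
available as `kernel="box"`). The taper matters: with a uniform box,
adjacent lattice points receive near-identical neighborhood means, their
weight vectors become degenerate, and the training data collapses onto
alternating lattice rows — leaving interleaved empty points inside
territories that then swallow held-out queries as "unassigned". The
tapered kernel keeps neighboring weights distinct, occupancy contiguous,
and lets training converge to an exact fixed point (the logged per-epoch
quantization error is non-increasing over the late epochs, settling to
machine precision).

### Exact order independence

The defining contract — the trained map does not depend on the order of the
input rows — is implemented as an exact, bitwise property, not an
approximate one: before any floating-point reduction, the input rows are
sorted lexicographically, so every sum in PCA, assignment scatter and
neighborhood smoothing is evaluated in a canonical order; the final
assignment is mapped back to the caller's row order. Duplicated rows are
interchangeable, so stable sorting makes the whole computation a pure
function of the row multiset.

### Query mapping

New fragments (same k-mer index) are assigned to their nearest weight; the
prediction is the majority training category at that lattice point (ties to
the lexicographically smallest name), or `"unassigned"` when no training
fragment landed there — empty lattice points are exactly the white points
of the category display.

## Derived layers

* **U-matrix**: mean Euclidean distance from each weight to its existing
  8-neighbors (4-neighbor variant configurable); edges average over the
  neighbors that exist. Rendered with linear min–max gray scaling, larger
  distance = darker.
* **Category coloring**: empty / single-category / multi ("black") — an
  exact partition of the lattice.
* **G+C bins**: per-lattice G+C from the weight vector (components clipped
  at 0, since PCA-plane initialization can leave small negative entries),
  ranked into 21 equal-count bins, ties broken by row-major order so
  renders are reproducible; bin counts differ by at most 1.
* **o/e layers**: per lattice point, observed = weight slot value,
  expected from that weight's own mononucleotide composition scaled to the
  weight total. Render thresholds are symmetric on log2 ratio
  (default |log2| ≥ 0.263, i.e. ratio 1.2).
* **Sz zones**: connected components (8-connectivity) of nonempty points
  that either exceed the 90th percentile of the U-matrix over nonempty
  points (strictly — a flat U-matrix yields no zones) or form an island
  nowhere touching the lattice border (hence fully surrounded by empty
  points); components below 2 points are discarded. The published zones
  are identified visually; this percentile + enclosure rule is an
  operationalization with both knobs exposed.

## Synthetic data

`synthdata` generates genomes from an order-m Markov chain over
{A, C, G, T} (order 0 = i.i.d. "random sequence" padding). The chain's
transition matrix controls the stationary k-mer composition — exactly the
structure the genome signature consists of — so it is the minimal generator
that makes clustering testable. Species panels share a base transition
matrix (Dirichlet(10) rows, mildly structured) perturbed per species by a
row-wise mixture with independent Dirichlet(1) draws at weight =
divergence; divergence 0 gives statistically identical species, 1 gives
independent signatures. `cg_suppression` multiplies P(G | context ending
in C) by a factor and renormalizes (0.1 ≈ vertebrate-like suppression;
0 removes CG entirely). Soft-masking and N content are injected as random
disjoint 200-nt runs hitting the requested fractions to the character.

What the generator does *not* emulate: within-genome heterogeneity
(isochores, interspersed repeats, satellite arrays), so synthetic species
territories are compact noise balls rather than the elongated,
substructured territories of real vertebrate maps. Passing tests therefore
demonstrate the machinery (counting, training, invariance, diagnostics) and
the separability of genuinely distinct signatures — not performance on real
genomes, whose within-species structure is richer.

## Problem sizes and numerical choices

The test and acceptance runs use three species of ~1.1 Mb at divergence
0.5, 5 kb windows, k=5 degenerate (600 training fragments in 512
dimensions; maps of ~150 lattice points), and 1 Mb genomes for the o/e
diagnostics — sizes chosen so the full pipeline, including two complete
training runs for the permutation check, executes in seconds while leaving
every statistic far from its decision boundary. The o/e Monte-Carlo check
uses k=3 (32 degenerate slots): at 1 Mb a uniform genome puts ~60 000
counts in each slot, so all ratios concentrate within about 1 ± 0.02,
whereas at k=5 the per-slot counts (~2 000) would leave the extreme of 512
ratios above a 5% band by sampling noise alone; the property being checked
is k-generic. Seeds are explicit everywhere; training itself uses no
randomness beyond the data, so a (config, data) pair reproduces maps
bit-exactly across runs and row orders.

Known limitations: no parallel training (a single NumPy process handles
~10^3–10^4 fragments comfortably; the millions-of-fragments regime is out
of scope), no growing or hierarchical map variants, k ≤ 8, and nucleotide
alphabets only.
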
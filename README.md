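# blsom

Batch-Learning Self-Organizing Map (BLSOM) for alignment-free clustering of
genomic sequence fragments by oligonucleotide composition.

Every genome carries a "genome signature": a species-specific bias in its
k-mer (oligonucleotide) frequencies that is detectable even in fragments of
50–100 kb. A self-organizing map projects these high-dimensional composition
vectors onto a 2-D lattice, clustering fragments by species with no species
information given to the algorithm. This package is aimed at people doing
composition-based sequence analysis — genome-signature studies, metagenomic
phylotype binning, detection of regions with peculiar composition
(CpG-suppressed repeats, motif-enriched zones) — who want a small,
deterministic, fully testable implementation rather than supercomputer
tooling.

## The method

Fragments are cut from FASTA input as fixed non-overlapping windows (default
100 kb; fragments whose non-ACGT content exceeds 20% are dropped, the rest
are normalized by their length without Ns). Each fragment becomes a vector
of **degenerate** k-mer frequencies: the counts of each complementary pair
(e.g. AAAAC and GTTTT) are summed, since only one strand of a duplex is
registered in databases — for pentanucleotides this gives the
512-dimensional "DegPenta" space.

The BLSOM differs from Kohonen's on-line SOM in two ways:

1. **PCA initialization.** With `x_av` the mean vector, `b1, b2` the first
   two covariance eigenvectors and `σ1 ≥ σ2` the corresponding standard
   deviations, the initial lattice weights are

   ```
   w_ij = x_av + (5σ1/I) · [ b1 (i − I/2) + b2 (j − J/2) ]
   ```

   so the first lattice dimension `I` spans five standard deviations of the
   first principal component. `J` is the smallest integer strictly greater
   than `(σ2/σ1)·I`, and `I` is chosen so the lattice averages about four
   fragments per point.

2. **Batch learning.** Each epoch first assigns *every* fragment to its
   best-matching (minimal Euclidean distance) weight `w_i′j′`, then moves
   each weight toward the (neighborhood-tapered) mean of the fragments
   assigned near it. Training is therefore — exactly, bit for bit —
   independent of the order of the input rows.

Trained maps are annotated with a U-matrix (mean distance to lattice
neighbors, dark = cluster border), per-lattice G+C% in 21 equal-count bins,
per-oligonucleotide observed/expected ratios (expectation from each lattice
point's own mononucleotide composition — this is what exposes CpG
suppression and motif enrichment independently of base content), and
"specific zones": compositionally isolated islands bounded by empty lattice
points or high U-matrix ridges. New, species-unknown fragments can be
mapped onto a trained lattice to predict their category (phylotype-style
assignment).

A seeded Markov-chain genome generator (`blsom.synthdata`) provides
multi-species panels with controllable divergence, G+C content, CpG
suppression, soft-masking and N runs, so the entire pipeline runs and is
tested without any genome downloads.

## Worked example

```
$ blsom generate panel.fa --n-species 3 --divergence 0.5 --length 500000 --seed 7
wrote 3 records to panel.fa
$ blsom fragment panel.fa run --window 5000 --k 5
300 fragments included, 0 excluded
$ blsom train run som --epochs 100
trained 10x8 map; final quantization error 0.012844
$ blsom map som panel.fa pred.tsv --window 5000 --k 5
mapped 300 fragments
$ head -3 pred.tsv
source_id  start  end    i  j  predicted_category
species_A  0      5000   6  3  species_A
species_A  5000   10000  8  3  species_A
$ blsom viz som viz --k 5 --oe-kmer AAAAC
viz/map_umatrix.png
...
```

Three synthetic species (1 Mb-scale genomes, Markov divergence 0.5) are cut
into 100 five-kb fragments each; the 512-dimensional DegPenta vectors train
a 10×8 lattice (≈ 4 fragments per point). The final quantization error
(0.0128) is the mean distance from each fragment vector to its best-match
weight. Re-mapping the fragments recovers their species, and the `viz`
layers show the species territories, the U-matrix borders between them, and
the AAAAC+GTTTT over/under-representation pattern.

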
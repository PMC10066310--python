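# divprof — similarity-scaled diversity profiles for TCR repertoires

`divprof` compares T-cell receptor repertoires through two-parameter
diversity profiles that are sensitive to both **clone size** and **CDR3β
sequence similarity**.  It is aimed at immunologists and computational
biologists who have per-sample clone tables (CDR3β amino-acid sequences with
counts or frequencies) and want to stratify samples — by treatment,
timepoint or disease state — using global repertoire structure rather than
individual shared clones.

## The measure

For a repertoire of S unique clones with frequencies p_i, the naive
diversity of order q is the Hill number

    D(q) = ( Σ_i p_i^q )^(1/(1−q)),

with D(1) = exp(−Σ p_i ln p_i) and D(∞) = 1/max_i p_i as limits.  q tunes
sensitivity to clone size: q = 0 is richness, q = 1 the exponential Shannon
entropy, q = 2 the inverse Simpson index, q = ∞ the reciprocal Berger–Parker
index.

Sequence similarity enters through a kernel Z_ij = exp(−λ d_ij), where d_ij
is a pairwise CDR3β distance and λ ≥ 0 a similarity scale:

    D(q, λ) = ( Σ_i p_i (Zp)_i^(q−1) )^(1/(1−q)),    (Zp)_i = Σ_j Z_ij p_j.

λ = 0 treats all clones as identical (D = 1); λ = identity (Z the identity
matrix) treats them as fully distinct and recovers D(q).  The surface
ln D(q, λ) over a grid of q ∈ {0,…,6, ∞} and
λ ∈ {0.0, 0.1, …, 64.0, identity} is the *diversity profile*; scalar
features of the profile (areas between λ-curves, the mean small-λ spacing —
proportional to the frequency-weighted mean pairwise distance — and q-slopes)
feed PCA, complete-linkage clustering and partitioned leave-one-out
classification at the cohort level.

Two distance metrics are built in: global (Needleman–Wunsch) alignment with
BLOSUM45 and a linear gap cost of 10, normalised by the larger self-score;
and the Euclidean distance between mean Atchley-factor embeddings.

## A worked example

`examples/01_single_repertoire_profile.py` builds a six-row clone table
(two sequence-motif families, one out-of-frame row), filters, subsamples to
depth 500 and evaluates the profile:

```
5 unique in-frame clones after subsampling to depth 500

   q    D(q, 0)   D(q, 1.0)  D(q, identity)
     0     1.000      1.313          5.000
     1     1.000      1.287          4.201
     2     1.000      1.265          3.676
   inf     1.000      1.158          2.463
```

Reading the columns: at λ = 0 every clone is effectively the same clone, so
the effective number is 1 no matter how q weights clone sizes.  The identity
column is the naive profile — 5 clones at q = 0 falling to 2.46 at q = ∞
because one clone carries ~40% of the cells.  At λ = 1 the kernel has merged
the two motif families into roughly 1.3 effective clones: this repertoire is
far less diverse functionally than its clone count suggests.

The other examples reproduce the mock distance experiment (spacing rises,
area falls, as constant pairwise distance grows) and a full cohort
stratification in which classes differing only in sequence similarity are
separated perfectly by profile features but not by naive diversity.

## Command line

```sh
divprof synth  -o cohort/ --clones 100 --n-per-class 3 --seed 1
divprof sample cohort/tight_00.tsv -o runs/ --depth 50000 --seed 1
divprof cohort runs/* --labels cohort/labels.tsv -o cohort_out/
```

`sample` writes the subsampled repertoire, the chunked distance matrix with
a checksummed manifest (interrupted runs resume from completed chunks), the
long-format diversity table and the feature row; `cohort` writes PCA scores
and loadings, the dendrogram and classification reports.

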
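# Methods

## Model

A repertoire is a probability vector p over S unique CDR3β amino-acid
clones.  The package evaluates similarity-sensitive Hill numbers

    D(q, λ) = ( Σ_i p_i (Zp)_i^(q−1) )^(1/(1−q)),   Z_ij = exp(−λ d_ij),

on a fixed grid of orders q and similarity scales λ.  The limits used at the
sentinels are D(q=1, λ) = exp(−Σ p_i ln (Zp)_i) and
D(q=∞, λ) = 1/max_i (Zp)_i; both are verified numerically in the test suite
as limits of the general expression (q = 1 ± 1e−4 and q = 400).  The
λ = identity column (the naive profile) is always computed from the Hill
formula directly, never from exp(−λ d) at large λ — the two coincide exactly
only for strictly positive off-diagonal distances, and the direct form is
exact regardless.

Assumptions: clones are defined by exact amino-acid identity; frequencies
are the only abundance information (no UMI or error modelling); distances
are symmetric with zero diagonal, which both built-in metrics guarantee.

## Distances

**blosum45** (default): global Needleman–Wunsch alignment under the NCBI
BLOSUM45 matrix with a *linear* gap cost of 10 per gap position (opening and
extending cost the same).  The distance is
d(a,b) = 1 − score(a,b)/max(score(a,a), score(b,b)), zero for identical
sequences and floored at 0 (with a logged warning) in the theoretical corner
where a cross-score could exceed the larger self-score.  The matrix is
bundled as package data and pinned by checksum; the tests also verify it
entry-by-entry against the copy shipped with Biopython and verify the
aligner against a hand-rolled dynamic program.  An affine gap model (open ≠
extend) is a plausible alternative reading of "gap penalty of 10"; the
linear model is the minimal one and is fixed here so scores are reproducible
bit-exactly.

**atchley**: each peptide is embedded as the arithmetic mean of the five
Atchley physicochemical factors of its residues (published values used
as-is, no re-standardisation); the distance is the Euclidean norm between
embeddings.  This metric is not injective ("A" vs "AA"), which is
acceptable for its role as a cheap biochemical alternative.

## Pipeline and numerics

Clone tables are filtered to in-frame sequences.  Because input is
amino-acid text, "in frame" is operationalised as: composed solely of the
20 canonical one-letter codes (no `*`, no `X`, no lowercase, non-empty).

Subsampling draws `depth` cells (default 50 000) from the normalised
abundance distribution **with replacement** (multinomial).  This is the only
sampling scheme that remains well-defined when abundances are already
frequencies; when the integer read total is below the depth a warning is
logged and sampling proceeds unchanged.  Duplicate sequences are merged
before sampling.  The seed is a required API argument and is recorded in the
run manifest.

The S×S distance matrix is computed in row chunks (default 100 rows): each
chunk holds one row block against all S columns, so chunks are independent,
embarrassingly parallel, and concatenate to the full matrix regardless of
chunk size or worker count.  Full rows are computed per chunk — each pair is
evaluated twice across a run — keeping the persisted chunk format exactly
reconstructable from any subset of completed chunks; symmetry is exploited
only as a test invariant.  Chunks persist as headerless TSVs (17 significant
digits, which round-trips IEEE doubles exactly) with a manifest recording
row ranges, per-chunk checksums and a checksum of the source repertoire;
resumption reuses intact chunks and refuses corrupted ones.

Grid evaluation streams over chunks once, accumulating (Zp)_i for all finite
λ simultaneously.  The sum Σ p_i (Zp)_i^(q−1) is evaluated through
log-sum-exp so q = 6 cannot underflow with tiny (Zp)_i and q = 0 cannot
overflow with tiny p_i.  Oracle-equivalence tolerance is 1e−9 absolute on
ln D, generous for double accumulation over ≤ 5·10⁴ terms.  ln D values are
clipped at 0 from below to absorb −1e−16-scale float noise in the λ = 0
column.

## Profile features

* **Areas between λ-curves**: composite-trapezoid integrals over the finite
  q axis {0,…,6} (q = ∞ is excluded — the trapezoid rule needs a finite
  abscissa) of the gap between *adjacent* λ-curves.  Adjacent pairs form a
  non-redundant basis: any other area (e.g. identity↔16) is the sum of the
  adjacent areas between them, which the tests assert.  "All pairs" would
  add only linear combinations.
* **Mean small-λ spacing**: mean over adjacent pairs of
  λ ∈ {0.0, 0.1, 0.2, 0.3, 0.4, 0.5} of the q-averaged Δln D.  0.25,
  although on the evaluation grid, is excluded so the set stays evenly
  0.1-spaced; differences are deliberately not divided by Δλ.  A first-order
  expansion of the kernel around λ = 0 gives
  ln D(q, λ) ≈ λ·d̄ with d̄ = Σ_ij p_i p_j d_ij, independent of q, so the
  spacing reads off the frequency-weighted mean pairwise distance; the test
  suite checks the 5 % accuracy of this law for λ·d̄ ≤ 0.1 and its
  q-independence (spread < 1e−6 on uniform mocks).
* **q-slopes**: finite differences ln D(q_b) − ln D(q_a) for (0,1), (1,2),
  (0,2) at every λ.  The analytic derivative of ln D(q) at q = 1 equals
  −Var_p(ln p)/2 (clone-size dispersion); it is kept as a property test and
  not used as a feature, matching the finite-difference definition of the
  feature set.

## Cohort analysis

Features (already on ln scale) are mean-centred but not variance-scaled
before PCA by default (a `scale` flag exists); standardisation is left off
because the features share the ln D unit and rescaling would inflate noisy
near-constant columns.  Clustering is complete linkage on Euclidean
distances (scipy), deterministic under its condensed-index tie-breaking.
Classification splits the cohort into K = 3 label-stratified partitions
(round-robin within label, remainders on the first partitions, mirroring a
design where every treatment×timepoint group appears once per partition);
each partition is predicted by a classifier trained on the rest and the
concatenated predictions give the reported accuracy.  The SVM uses a linear
kernel with default regularisation (no kernel is implied by the feature
geometry and samples are few); the random forest uses scikit-learn defaults
with a fixed seed.  Hyperparameter search is out of scope.

`randomize_clone_sizes` keeps the sequence list (so distance chunks stay
valid) and replaces frequencies with normalised uniform draws — the null
for deciding whether feature correlations are structural or imposed by the
mathematical form of D.

## Synthetic data

The generators define the conditions under which the method is tested:

* `make_uniform_mock(S, d0)` — uniform frequencies, constant pairwise
  distance; the mock distance experiment uses S = 100 and
  d0 ∈ {0.1, 0.2, 0.4}.
* `powerlaw_frequencies` / `dirichlet_frequencies` — clone-size laws;
  power laws are the natural description of expanded repertoires, Dirichlet
  draws give seeded random but normalised vectors.
* `make_sequence_repertoire` — CDR3-like peptides (length 8–18, leading
  'C') generated by seeding motifs and applying point substitutions;
  substitution count controls similarity monotonically (no indels by
  design).  Duplicates collapse by summed frequency, so the tightest
  setting (one motif, zero substitutions) degenerates to a single clone
  with D ≡ 1.
* `make_structured_cohort` — 20 samples along a clonal-expansion gradient
  in which cluster mass rises while the cluster tightens (the coupling an
  immune response produces), with the global spread varying along a stride
  permutation of the sample index so it is rank-orthogonal to the gradient
  by construction.  The gradient makes small-λ spacing and the identity↔16
  area strongly rank-anticorrelated; clone-size randomisation leaves
  spacing following the orthogonal spread and the area following the
  tightness gradient, destroying the correlation.  The cohort itself is
  fully deterministic; only the randomisation draws are seeded.

What the synthetic data does **not** emulate: V(D)J generation
probabilities, sequencing error, UMI structure, length-dependent indel
variation, or realistic inter-sample sharing of public clones.  Passing
tests therefore demonstrate correctness of the computation and the
qualitative mechanics of the features, not biological effect sizes on real
repertoires.

## Problem sizes and determinism

Tests and the acceptance script run on repertoires of S ≈ 15–200 clones and
cohorts of 8–20 samples — sizes at which dense brute-force oracles are exact
and the whole suite completes in well under a minute per module.  Every
stochastic stage takes an explicit seed; generators are pure functions of
their seeds, pipeline reruns are bit-identical, and parallel workers cannot
change any output value (chunks are row-disjoint).

## Known limitations

* Runtime scales with S² alignments; the published-scale default of 50 000
  sequences per sample is intended for multi-core batch machines, not the
  test environment.  No approximate nearest-neighbour shortcut is provided:
  at small λ the kernel sum is genuinely global.
* The gap model (linear) and the unstandardised Atchley averaging are fixed
  interpretive choices, documented above.
* Naive diversity depends on sampling depth; subsampling mitigates but does
  not remove depth effects, and no rarefaction or richness extrapolation is
  attempted.
* Classification with very few samples per class is a demonstration of the
  partitioned protocol, not a validated clinical classifier.
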
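"""Cohort stratification: PCA, clustering and classification of profiles.

Generates a two-class synthetic cohort whose classes differ only in motif
tightness (sequence similarity) while sharing the same clone-size law, runs
the per-sample profiles, extracts features, and stratifies the cohort.
Because the class signal lives purely in the similarity axis, features of
the full similarity-scaled profile separate the classes.
"""

import pandas as pd

from divprof import (
    MockSpec,
    assemble_cohort,
    diversity_grid,
    features_frame,
    hierarchical_cluster,
    iter_distance_chunks,
    make_partition_scheme,
    make_sequence_cohort,
    partitioned_cv_classify,
    run_pca,
)

specs = {
    "tight": MockSpec(S=30, n_motifs=1, mutations_per_step=1, seed=1),
    "loose": MockSpec(S=30, n_motifs=1, mutations_per_step=4, seed=2),
}
reps, labels = make_sequence_cohort(specs, n_per_class=4)
print(f"cohort: {len(reps)} samples, classes {sorted(labels['label'].unique())}")

grids = [
    diversity_grid(rep, iter_distance_chunks(rep, metric="blosum45"))
    for rep in reps
]
table = features_frame(grids)
cm = assemble_cohort(table, labels)

scores, _, explained = run_pca(cm, n_components=2)
print(f"\nPCA explained fractions: PC1 {explained[0]:.2f}, PC2 {explained[1]:.2f}")
print(pd.concat([scores.round(2), labels.set_index('sample_id')], axis=1))

Z = hierarchical_cluster(cm)
print(f"\nfirst dendrogram merge height: {Z[0, 2]:.3f} (complete linkage)")

scheme = make_partition_scheme(cm, k=2)
_, accuracy, fold_acc = partitioned_cv_classify(cm, scheme, "svm", seed=0)
print(f"\npartitioned leave-one-out SVM accuracy: {accuracy:.2f} "
      f"(folds: {[f'{a:.2f}' for a in fold_acc]})")
print(
    "\nThe two classes have indistinguishable naive diversity; the profile"
    "\nfeatures that see sequence similarity separate them."
)
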
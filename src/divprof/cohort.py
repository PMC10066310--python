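"""Cohort-level stratification of diversity profiles.

Once every sample has a diversity grid (or an extracted feature vector),
samples become rows of a feature matrix and standard multivariate machinery
applies: mean-centred PCA, complete-linkage hierarchical clustering on
Euclidean distances, and partitioned leave-one-out classification (the cohort
is split into K label-stratified partitions; each partition is predicted once
by a classifier trained on the other K-1, the predictions are concatenated
and an overall accuracy reported).

Features are already on a natural-log scale, so columns are mean-centred but
not variance-scaled by default (``scale=True`` is available).

:func:`randomize_clone_sizes` is the null control for structure-driven
feature correlations: it keeps a repertoire's sequences (hence its distance
matrix) and replaces the clone-size distribution with normalised
pseudo-random draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .errors import ValidationError
from .io import Repertoire

CLASSIFIERS = ("svm", "random_forest")


@dataclass
class CohortMatrix:
    """Row-aligned samples x features matrix with per-sample labels."""

    sample_ids: list[str]
    labels: pd.Series  # categorical, indexed like sample_ids
    X: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            dupes = pd.Series(self.sample_ids).value_counts()
            raise ValidationError(
                f"duplicate sample_id(s): {list(dupes[dupes > 1].index)}"
            )
        if n < 2:
            raise ValidationError("cohort needs at least 2 samples")
        if self.X.shape != (n, len(self.feature_names)):
            raise ValidationError(
                f"matrix shape {self.X.shape} != ({n}, {len(self.feature_names)})"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains non-finite cells")
        if len(self.labels) != n:
            raise ValidationError("labels must cover every sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def assemble_cohort(feature_table: pd.DataFrame, labels: pd.DataFrame) -> CohortMatrix:
    """Align a per-sample feature table with a label table.

    ``feature_table`` is indexed by sample_id (as produced by
    :func:`divprof.features.features_frame`, or a wide ln D grid table);
    ``labels`` has columns ``sample_id`` and ``label``.  Column order of the
    features is preserved and must be identical across samples (a DataFrame
    guarantees that; missing cells are rejected).
    """
    if "sample_id" not in labels.columns or "label" not in labels.columns:
        raise ValidationError("labels need 'sample_id' and 'label' columns")
    if feature_table.isna().any().any():
        bad = feature_table.columns[feature_table.isna().any()].tolist()
        raise ValidationError(f"missing feature cells in columns {bad}")
    label_map = labels.set_index("sample_id")["label"]
    missing = [s for s in feature_table.index if s not in label_map.index]
    if missing:
        raise ValidationError(f"samples without labels: {missing}")
    sample_ids = list(feature_table.index)
    return CohortMatrix(
        sample_ids=sample_ids,
        labels=label_map.loc[sample_ids],
        X=feature_table.to_numpy(dtype=float),
        feature_names=list(feature_table.columns),
    )


def run_pca(
    cm: CohortMatrix, n_components: int | None = None, scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Mean-centred PCA; returns (scores, loadings, explained fractions).

    Explained-variance fractions are sorted descending and sum to at most 1
    (to exactly 1 when all ``min(n_samples - 1, n_features)`` components are
    kept).
    """
    X = cm.X - cm.X.mean(axis=0)
    if np.allclose(X, 0):
        raise ValidationError("feature matrix is constant; PCA is degenerate")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    max_rank = min(cm.n_samples, len(cm.feature_names))
    if n_components is None:
        n_components = min(cm.n_samples - 1, len(cm.feature_names))
    if n_components > max_rank:
        raise ValidationError(
            f"n_components={n_components} exceeds min(samples, features)={max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=cm.sample_ids, columns=comp_names),
        pd.DataFrame(pca.components_, index=comp_names, columns=cm.feature_names),
        pca.explained_variance_ratio_,
    )


def hierarchical_cluster(cm: CohortMatrix) -> np.ndarray:
    """Complete-linkage dendrogram on Euclidean distances between samples.

    Returns the scipy linkage matrix (merge pair indices + heights).  Ties in
    merge distance are resolved deterministically by the ordering of the
    condensed distance vector (lowest sample index first).
    """
    if not np.all(np.isfinite(cm.X)):
        raise ValidationError("NaN features")
    return linkage(cm.X, method="complete", metric="euclidean")


def make_partition_scheme(cm: CohortMatrix, k: int = 3) -> np.ndarray:
    """Stratified round-robin assignment of samples to K partitions.

    Samples are grouped by label; within each group (ordered by sample_id)
    they are dealt out 1, 2, ..., K, 1, 2, ... so every label is represented
    in each partition whenever its count allows, and any remainder is spread
    across the first partitions.
    """
    if k < 2:
        raise ValidationError("need at least 2 partitions")
    assignment = np.empty(cm.n_samples, dtype=int)
    order = pd.DataFrame(
        {"sample_id": cm.sample_ids, "label": cm.labels.to_numpy()}
    ).sort_values(["label", "sample_id"])
    for _, group in order.groupby("label", sort=True):
        for pos, idx in enumerate(group.index):
            assignment[idx] = pos % k
    return assignment


def _make_classifier(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValidationError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def partitioned_cv_classify(
    cm: CohortMatrix,
    scheme: np.ndarray,
    classifier: str = "svm",
    seed: int = 0,
) -> tuple[pd.DataFrame, float, list[float]]:
    """Leave-one-partition-out classification.

    Each partition is held out once, a fresh classifier is trained on the
    remaining partitions, and the held-out predictions are concatenated.
    Returns (predictions table, overall accuracy of the concatenated
    predictions, per-partition accuracies).  Deterministic given
    (cm, scheme, classifier, seed).
    """
    scheme = np.asarray(scheme, dtype=int)
    if scheme.shape != (cm.n_samples,):
        raise ValidationError("partition scheme must assign every sample")
    y = cm.labels.to_numpy()
    all_classes = set(y)
    if len(all_classes) < 2:
        raise ValidationError("classification needs at least 2 classes")
    rows = []
    fold_acc = []
    for part in sorted(set(scheme.tolist())):
        test = scheme == part
        train = ~test
        if set(y[train]) != all_classes:
            missing = sorted(all_classes - set(y[train]))
            raise ValidationError(
                f"class(es) {missing} absent from the training folds of partition {part}"
            )
        clf = _make_classifier(classifier, seed)
        clf.fit(cm.X[train], y[train])
        pred = clf.predict(cm.X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        for sid, truth, p in zip(
            np.array(cm.sample_ids)[test], y[test], pred
        ):
            rows.append(
                {"sample_id": sid, "partition": part, "label": truth, "predicted": p}
            )
    predictions = pd.DataFrame(rows)
    accuracy = float((predictions["label"] == predictions["predicted"]).mean())
    return predictions, accuracy, fold_acc


def randomize_clone_sizes(rep: Repertoire, seed: int) -> Repertoire:
    """Replace frequencies with normalised pseudo-random draws, same sequences.

    The support (and therefore any distance matrix or chunk manifest computed
    from it) is unchanged; only the clone-size distribution is destroyed.
    """
    rng = np.random.default_rng(seed)
    draws = rng.uniform(1e-12, 1.0, size=len(rep))
    return Repertoire(
        sequences=list(rep.sequences),
        frequencies=draws / draws.sum(),
        sample_id=rep.sample_id,
        subsample_depth=rep.subsample_depth,
        seed=seed,
    )
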
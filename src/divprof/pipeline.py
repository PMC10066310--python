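"""Per-sample and cohort pipeline orchestration.

``run_sample`` chains the per-sample stages — read, in-frame filter,
subsample, chunked distance matrix, diversity grid, feature extraction — and
persists every artifact together with a run manifest (resolved configuration,
seed, checksums).  Reruns with an identical configuration are bit-identical,
and an interrupted run resumes from the distance chunks already on disk (the
chunk manifest records per-chunk checksums, so a truncated chunk is detected
and reported rather than silently reused).

``run_cohort`` collects per-sample diversity tables, extracts features,
and writes PCA scores/loadings, the complete-linkage dendrogram, and
partitioned leave-one-out classification reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .distance import DEFAULT_CHUNK_SIZE, write_distance_chunks
from .diversity import (
    DEFAULT_LAMBDA,
    DEFAULT_Q,
    ParameterGrid,
    diversity_grid,
    read_diversity_table,
    write_diversity_table,
)
from .errors import ValidationError
from .features import extract_features, features_frame
from .io import (
    DEFAULT_DEPTH,
    filter_in_frame,
    read_repertoire,
    subsample,
    write_repertoire,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one per-sample run.

    Defaults reproduce the published grids: subsampling depth 50 000,
    BLOSUM45 metric, chunk size 100, q in {0..6, inf} and
    lambda in {0.0 ... 64.0, identity}.
    """

    input_path: str
    out_dir: str
    sample_id: str | None = None
    depth: int = DEFAULT_DEPTH
    metric: str = "blosum45"
    chunk_size: int = DEFAULT_CHUNK_SIZE
    q_values: tuple[float, ...] = DEFAULT_Q
    lambda_values: tuple[float, ...] = DEFAULT_LAMBDA
    workers: int = 1
    seed: int = 0

    def grid(self) -> ParameterGrid:
        return ParameterGrid(q_values=self.q_values, lambda_values=self.lambda_values)


def _config_json(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    # inf does not survive strict JSON; use the serialization tokens
    d["q_values"] = ["inf" if np.isinf(q) else q for q in config.q_values]
    d["lambda_values"] = [
        "identity" if np.isinf(l) else l for l in config.lambda_values
    ]
    return d


def run_sample(config: RunConfig) -> Path:
    """Run the full per-sample pipeline; returns the sample output directory.

    Artifacts written under ``out_dir/<sample_id>/``:

    - ``repertoire.tsv`` — the filtered, subsampled, normalised clone table
    - ``<sample>_chunk_<row_start>.tsv`` + ``..._manifest.tsv`` — distances
    - ``diversity.tsv`` — the long-format ln D(q, lambda) table
    - ``features.tsv`` — the scalar feature row
    - ``run_manifest.json`` — resolved config, seed and artifact checksums
    """
    raw = read_repertoire(config.input_path, sample_id=config.sample_id)
    sample_id = raw.sample_id
    sample_dir = Path(config.out_dir) / sample_id
    sample_dir.mkdir(parents=True, exist_ok=True)
    logger.info("sample %s: %d input rows", sample_id, len(raw))

    rep = subsample(filter_in_frame(raw), depth=config.depth, seed=config.seed)
    logger.info("sample %s: %d unique clones after subsampling to %d",
                sample_id, rep.richness, config.depth)
    write_repertoire(rep, sample_dir / "repertoire.tsv")

    manifest = write_distance_chunks(
        rep,
        sample_dir,
        metric=config.metric,
        chunk_size=config.chunk_size,
        workers=config.workers,
        resume=True,
    )
    dg = diversity_grid(rep, manifest, config.grid())
    write_diversity_table(dg, sample_dir / "diversity.tsv")

    fv = extract_features(dg)
    fv.to_series().to_frame().T.rename_axis("sample_id").to_csv(
        sample_dir / "features.tsv", sep="\t", float_format="%.17g"
    )

    run_manifest = {
        "config": _config_json(config),
        "sample_id": sample_id,
        "n_clones": rep.richness,
        "repertoire_checksum": rep.checksum(),
        "chunk_manifest": manifest.name,
    }
    with open(sample_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return sample_dir


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a cohort run over completed sample directories."""

    sample_dirs: tuple[str, ...]
    labels_path: str
    out_dir: str
    classifiers: tuple[str, ...] = ("svm", "random_forest")
    n_partitions: int = 3
    seed: int = 0


def run_cohort(config: CohortConfig) -> Path:
    """Cohort stratification from per-sample diversity tables.

    Writes ``features.tsv``, ``pca_scores.tsv``, ``pca_loadings.tsv``,
    ``pca_explained.tsv``, ``linkage.tsv`` and per-classifier
    ``predictions_<name>.tsv`` / ``classification_report.tsv`` under
    ``out_dir``.
    """
    if len(config.sample_dirs) < 2:
        raise ValidationError("cohort needs at least 2 completed samples")
    grids = [
        read_diversity_table(Path(d) / "diversity.tsv") for d in config.sample_dirs
    ]
    ref = grids[0].grid
    for dg in grids[1:]:
        if dg.grid != ref:
            raise ValidationError(
                f"sample {dg.sample_id} was computed on a different (q, lambda) grid"
            )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = features_frame(grids)
    table.to_csv(out_dir / "features.tsv", sep="\t", float_format="%.17g")

    labels = pd.read_csv(config.labels_path, sep="\t", dtype=str)
    cm = cohort_mod.assemble_cohort(table, labels)

    scores, loadings, explained = cohort_mod.run_pca(cm)
    scores.rename_axis("sample_id").to_csv(out_dir / "pca_scores.tsv", sep="\t")
    loadings.rename_axis("component").to_csv(out_dir / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        {"component": scores.columns, "explained_fraction": explained}
    ).to_csv(out_dir / "pca_explained.tsv", sep="\t", index=False)

    Z = cohort_mod.hierarchical_cluster(cm)
    pd.DataFrame(Z, columns=["left", "right", "height", "size"]).to_csv(
        out_dir / "linkage.tsv", sep="\t", index=False
    )

    scheme = cohort_mod.make_partition_scheme(cm, k=config.n_partitions)
    report_rows = []
    for name in config.classifiers:
        predictions, accuracy, fold_acc = cohort_mod.partitioned_cv_classify(
            cm, scheme, classifier=name, seed=config.seed
        )
        predictions.to_csv(out_dir / f"predictions_{name}.tsv", sep="\t", index=False)
        row = {"classifier": name, "mean_accuracy": accuracy}
        for k, acc in enumerate(fold_acc):
            row[f"fold_{k}_accuracy"] = acc
        report_rows.append(row)
    pd.DataFrame(report_rows).to_csv(
        out_dir / "classification_report.tsv", sep="\t", index=False
    )
    return out_dir
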
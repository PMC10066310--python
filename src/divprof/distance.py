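"""Pairwise CDR3beta distances, computed and persisted in row chunks.

Two metrics are provided:

``blosum45``
    Global (Needleman–Wunsch) alignment of the two peptides with a linear
    gap cost of 10 per gap position, scored with the NCBI BLOSUM45
    substitution matrix; the score is turned into a distance by

        d(a, b) = 1 - score(a, b) / max(score(a, a), score(b, b))

    which is 0 for identical sequences and grows as alignment quality
    drops relative to the better self-alignment.

``atchley``
    Each peptide is embedded as the arithmetic mean of the five Atchley
    physicochemical factors of its residues; the distance is the Euclidean
    norm between embeddings.  Note this embedding is not injective
    (e.g. "A" and "AA" coincide).

The S x S matrix is computed in contiguous row blocks ("chunks"): each chunk
holds the distances of a slice of sequences against *all* S sequences, so
chunks are embarrassingly parallel and concatenate, in row order, to the full
matrix.  Chunks can be persisted as headerless TSV files plus a manifest that
records row ranges, the metric, and a checksum of the repertoire they were
computed from.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist

from .errors import FormatError, ValidationError
from .io import CANONICAL_AA, Repertoire

logger = logging.getLogger(__name__)

DEFAULT_GAP_PENALTY = 10
DEFAULT_CHUNK_SIZE = 100

METRICS = ("blosum45", "atchley")

_CANONICAL_SET = frozenset(CANONICAL_AA)


def _check_peptide(seq: str) -> None:
    if not seq:
        raise ValidationError("empty peptide")
    bad = set(seq) - _CANONICAL_SET
    if bad:
        raise ValidationError(f"non-canonical residue(s) {sorted(bad)} in {seq!r}")


# ---------------------------------------------------------------------------
# substitution scoring


def _load_matrix_tsv() -> pd.DataFrame:
    with resources.files("divprof.data").joinpath("blosum45.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def bundled_blosum45_checksum() -> str:
    """sha256 of the bundled BLOSUM45 table (guards against matrix drift)."""
    data = resources.files("divprof.data").joinpath("blosum45.tsv").read_bytes()
    return hashlib.sha256(data).hexdigest()


@dataclass
class SubstitutionScorer:
    """A symmetric 20x20 substitution matrix plus a linear gap penalty."""

    matrix: pd.DataFrame
    gap_penalty: int = DEFAULT_GAP_PENALTY
    _aligner: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.gap_penalty <= 0:
            raise ValidationError("gap penalty must be positive")
        m = self.matrix.to_numpy()
        if not np.array_equal(m, m.T):
            raise ValidationError("substitution matrix must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValidationError("diagonal substitution scores must be positive")

    @classmethod
    def blosum45(cls, gap_penalty: int = DEFAULT_GAP_PENALTY) -> "SubstitutionScorer":
        """The default scorer: bundled NCBI BLOSUM45, gap penalty 10."""
        return cls(matrix=_load_matrix_tsv(), gap_penalty=gap_penalty)

    @property
    def aligner(self) -> Align.PairwiseAligner:
        """Lazily constructed global aligner with linear gap cost."""
        if self._aligner is None:
            letters = "".join(self.matrix.index)
            sub = substitution_matrices.Array(alphabet=letters, dims=2)
            for a in letters:
                for b in letters:
                    sub[a, b] = float(self.matrix.loc[a, b])
            aligner = Align.PairwiseAligner()
            aligner.mode = "global"
            aligner.substitution_matrix = sub
            aligner.open_gap_score = -float(self.gap_penalty)
            aligner.extend_gap_score = -float(self.gap_penalty)
            self._aligner = aligner
        return self._aligner


def global_alignment_score(a: str, b: str, scorer: SubstitutionScorer | None = None) -> int:
    """Optimal global alignment score of two peptides under the scorer."""
    if scorer is None:
        scorer = SubstitutionScorer.blosum45()
    _check_peptide(a)
    _check_peptide(b)
    return int(scorer.aligner.score(a, b))


def blosum_distance(a: str, b: str, scorer: SubstitutionScorer | None = None) -> float:
    """Alignment-score distance d = 1 - score(a,b)/max(self scores), floored at 0."""
    if scorer is None:
        scorer = SubstitutionScorer.blosum45()
    if a == b:
        _check_peptide(a)
        return 0.0
    self_a = global_alignment_score(a, a, scorer)
    self_b = global_alignment_score(b, b, scorer)
    return _score_to_distance(
        global_alignment_score(a, b, scorer), self_a, self_b
    )


def _score_to_distance(cross: float, self_a: float, self_b: float) -> float:
    denom = max(self_a, self_b)
    if denom <= 0:
        raise ValidationError("max self-score must be positive (degenerate scorer)")
    d = 1.0 - cross / denom
    if d < 0:
        logger.warning("cross score %s exceeds max self score %s; flooring distance at 0",
                       cross, denom)
        return 0.0
    return d


# ---------------------------------------------------------------------------
# Atchley embedding


def load_atchley_table() -> pd.DataFrame:
    """The five Atchley factors for the 20 canonical residues (rows=residues)."""
    with resources.files("divprof.data").joinpath("atchley_factors.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", index_col=0)
    if table.shape != (20, 5):
        raise FormatError(f"Atchley table has shape {table.shape}, expected (20, 5)")
    return table


def atchley_embed(seq: str, table: pd.DataFrame | None = None) -> np.ndarray:
    """Mean of the per-residue 5-factor vectors."""
    if table is None:
        table = load_atchley_table()
    _check_peptide(seq)
    return table.loc[list(seq)].to_numpy().mean(axis=0)


def atchley_distance(a: str, b: str, table: pd.DataFrame | None = None) -> float:
    """Euclidean distance between mean Atchley embeddings."""
    if table is None:
        table = load_atchley_table()
    return float(np.linalg.norm(atchley_embed(a, table) - atchley_embed(b, table)))


# ---------------------------------------------------------------------------
# chunked all-against-all computation


@dataclass
class DistanceChunk:
    """Rows [row_start, row_start+row_count) of the S x S distance matrix."""

    row_start: int
    values: np.ndarray  # shape (row_count, S)
    metric_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("chunk values must be 2-D")
        if np.any(self.values < 0):
            raise ValidationError("distances must be non-negative")
        if self.metric_tag not in METRICS:
            raise ValidationError(f"unknown metric tag {self.metric_tag!r}")

    @property
    def row_count(self) -> int:
        return self.values.shape[0]


def _blosum_rows(sequences: list[str], lo: int, hi: int,
                 matrix: pd.DataFrame, gap_penalty: int,
                 self_scores: np.ndarray) -> np.ndarray:
    """One chunk of BLOSUM distances; rebuilds the aligner (picklable args)."""
    aligner = SubstitutionScorer(matrix=matrix, gap_penalty=gap_penalty).aligner
    S = len(sequences)
    out = np.empty((hi - lo, S))
    for r, i in enumerate(range(lo, hi)):
        si = sequences[i]
        for j in range(S):
            if i == j:
                out[r, j] = 0.0
            else:
                out[r, j] = _score_to_distance(
                    aligner.score(si, sequences[j]), self_scores[i], self_scores[j]
                )
    return out


def _chunk_bounds(S: int, chunk_size: int) -> list[tuple[int, int]]:
    if chunk_size <= 0:
        raise ValidationError(f"chunk_size must be >= 1, got {chunk_size}")
    return [(lo, min(lo + chunk_size, S)) for lo in range(0, S, chunk_size)]


class _ChunkComputer:
    """Computes arbitrary row blocks of the distance matrix for one repertoire."""

    def __init__(self, rep: Repertoire, metric: str,
                 scorer: SubstitutionScorer | None = None):
        if metric not in METRICS:
            raise ValidationError(
                f"unknown metric {metric!r}; expected one of {METRICS}"
            )
        self.sequences = rep.sequences
        self.metric = metric
        if metric == "atchley":
            table = load_atchley_table()
            self.embeddings = np.stack(
                [atchley_embed(s, table) for s in self.sequences]
            )
        else:
            self.scorer = scorer if scorer is not None else SubstitutionScorer.blosum45()
            aligner = self.scorer.aligner
            self.self_scores = np.array(
                [aligner.score(s, s) for s in self.sequences]
            )

    def rows(self, lo: int, hi: int) -> np.ndarray:
        if self.metric == "atchley":
            vals = cdist(self.embeddings[lo:hi], self.embeddings)
            vals[np.arange(lo, hi) - lo, np.arange(lo, hi)] = 0.0
            return vals
        return _blosum_rows(self.sequences, lo, hi, self.scorer.matrix,
                            self.scorer.gap_penalty, self.self_scores)

    def compute(self, bounds: list[tuple[int, int]], workers: int = 1
                ) -> Iterator[DistanceChunk]:
        if workers > 1 and self.metric == "blosum45":
            results = Parallel(n_jobs=workers)(
                delayed(_blosum_rows)(
                    self.sequences, lo, hi, self.scorer.matrix,
                    self.scorer.gap_penalty, self.self_scores,
                )
                for lo, hi in bounds
            )
            for (lo, _), vals in zip(bounds, results):
                yield DistanceChunk(row_start=lo, values=vals, metric_tag=self.metric)
        else:
            for lo, hi in bounds:
                yield DistanceChunk(
                    row_start=lo, values=self.rows(lo, hi), metric_tag=self.metric
                )


def iter_distance_chunks(
    rep: Repertoire,
    metric: str = "blosum45",
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    workers: int = 1,
    scorer: SubstitutionScorer | None = None,
) -> Iterator[DistanceChunk]:
    """Yield the row chunks of the full distance matrix, in row order.

    The concatenated result is independent of both ``chunk_size`` and
    ``workers`` (each chunk covers full rows, so the work partition cannot
    change any value).
    """
    computer = _ChunkComputer(rep, metric, scorer)
    bounds = _chunk_bounds(len(rep.sequences), chunk_size)
    yield from computer.compute(bounds, workers=workers)


def dense_distance_matrix(
    rep: Repertoire, metric: str = "blosum45", **kwargs
) -> np.ndarray:
    """Full S x S distance matrix in memory (concatenation of all chunks)."""
    return np.vstack([c.values for c in iter_distance_chunks(rep, metric, **kwargs)])


# ---------------------------------------------------------------------------
# persistence: chunk TSVs plus a manifest


def _chunk_checksum(values: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(values).tobytes())
    return h.hexdigest()


def write_distance_chunks(
    rep: Repertoire,
    out_dir: str | Path,
    metric: str = "blosum45",
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    workers: int = 1,
    resume: bool = True,
) -> Path:
    """Compute and persist all chunks; return the manifest path.

    One headerless TSV per chunk, named ``<sample>_chunk_<row_start>.tsv``.
    When ``resume`` is true and an existing manifest for the same repertoire
    (checksum), metric and chunk layout lists chunk files that are present
    and intact, those chunks are reused without recomputation; a listed chunk
    file whose contents no longer match its recorded checksum aborts the run
    with an error instructing regeneration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / f"{rep.sample_id}_{metric}_manifest.tsv"
    rep_sum = rep.checksum()
    bounds = _chunk_bounds(rep.richness, chunk_size)

    done: dict[int, dict] = {}
    if resume and manifest_path.exists():
        old = pd.read_csv(manifest_path, sep="\t")
        compatible = (
            not old.empty
            and (old["repertoire_checksum"] == rep_sum).all()
            and (old["metric"] == metric).all()
            and sorted(zip(old["row_start"], old["row_count"]))
            == [(lo, hi - lo) for lo, hi in bounds]
        )
        if compatible:
            for row in old.itertuples():
                path = Path(row.path)
                if not path.exists():
                    continue
                values = np.loadtxt(path, delimiter="\t", ndmin=2)
                if (
                    values.shape != (row.row_count, row.n_sequences)
                    or _chunk_checksum(values) != row.checksum
                ):
                    raise ValidationError(
                        f"{path}: existing chunk does not match its manifest "
                        "checksum; delete the chunk files and rerun to regenerate"
                    )
                done[int(row.row_start)] = {
                    k: getattr(row, k)
                    for k in ("path", "row_start", "row_count", "metric",
                              "n_sequences", "repertoire_checksum", "checksum")
                }

    todo = [(lo, hi) for lo, hi in bounds if lo not in done]
    records = list(done.values())
    if todo:
        computer = _ChunkComputer(rep, metric)
        for chunk in computer.compute(todo, workers=workers):
            path = out_dir / f"{rep.sample_id}_chunk_{chunk.row_start}.tsv"
            np.savetxt(path, chunk.values, delimiter="\t", fmt="%.17g")
            records.append(
                {
                    "path": str(path),
                    "row_start": chunk.row_start,
                    "row_count": chunk.row_count,
                    "metric": metric,
                    "n_sequences": rep.richness,
                    "repertoire_checksum": rep_sum,
                    "checksum": _chunk_checksum(chunk.values),
                }
            )
    pd.DataFrame(records).sort_values("row_start")[
        ["path", "row_start", "row_count", "metric", "n_sequences",
         "repertoire_checksum", "checksum"]
    ].to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_distance_chunks(
    manifest_path: str | Path, rep: Repertoire | None = None
) -> Iterator[DistanceChunk]:
    """Stream persisted chunks back, validating shapes (and the repertoire)."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    if manifest.empty:
        raise FormatError(f"{manifest_path}: empty manifest")
    if rep is not None:
        rep_sum = rep.checksum()
        if not (manifest["repertoire_checksum"] == rep_sum).all():
            raise ValidationError(
                "manifest was computed from a different repertoire "
                f"(checksum mismatch in {manifest_path})"
            )
    for row in manifest.sort_values("row_start").itertuples():
        values = np.loadtxt(row.path, delimiter="\t", ndmin=2)
        if values.shape != (row.row_count, row.n_sequences):
            raise ValidationError(
                f"{row.path}: chunk shape {values.shape} does not match manifest "
                f"({row.row_count}, {row.n_sequences}); regenerate the chunks"
            )
        if _chunk_checksum(values) != row.checksum:
            # values round-trip through %.17g text exactly, so a mismatch
            # means truncation or tampering
            raise ValidationError(f"{row.path}: checksum mismatch; regenerate the chunks")
        yield DistanceChunk(row_start=row.row_start, values=values, metric_tag=row.metric)
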
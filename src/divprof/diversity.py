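"""Naive and similarity-scaled diversity profiles.

The naive diversity of order q (Hill number) of a frequency vector p is

    D(q) = (sum_i p_i^q)^(1/(1-q)),

with the limits D(1) = exp(-sum p_i ln p_i) (exponential Shannon entropy)
and D(inf) = 1/max_i p_i (reciprocal Berger-Parker).  q tunes sensitivity
to clone size: q=0 counts every clone equally (richness), large q sees only
the dominant clones.

The similarity-scaled diversity additionally weighs clones by how similar
they are to the rest of the repertoire.  With a distance matrix d_ij and a
scaling parameter lambda, the similarity kernel is Z_ij = exp(-lambda d_ij)
and

    D(q, lambda) = (sum_i p_i (Zp)_i^(q-1))^(1/(1-q)),   (Zp)_i = sum_j Z_ij p_j,

with limits exp(-sum p_i ln (Zp)_i) at q=1 and 1/max_i (Zp)_i at q=inf.
lambda interpolates between two extremes: lambda=0 makes all clones
identical (D=1) and lambda="identity" (Z the identity matrix) recovers the
naive diversity.  The identity column is always evaluated from the naive
formula directly, never through exp(-lambda d) at large lambda.

Evaluation streams over :class:`~divprof.distance.DistanceChunk` row blocks,
so the full S x S matrix never has to be in memory; per chunk, (Zp) rows are
accumulated for every lambda at once.  Accumulation of sum p_i (Zp)_i^(q-1)
is done in log space (log-sum-exp) so that large q with tiny (Zp)_i cannot
underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .distance import DistanceChunk, read_distance_chunks
from .errors import FormatError, ValidationError
from .io import FREQ_TOL, Repertoire

#: Sentinel for the naive column: the similarity kernel is the identity matrix.
IDENTITY = math.inf

DEFAULT_Q = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, math.inf)
DEFAULT_LAMBDA = (
    0.0, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.75, 1.0,
    1.5, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, IDENTITY,
)


@dataclass(frozen=True)
class ParameterGrid:
    """The ordered (q, lambda) evaluation points.

    ``q_values`` ends with the q=inf sentinel; ``lambda_values`` ends with
    the identity sentinel (represented as math.inf and serialized as the
    token ``identity``).
    """

    q_values: tuple[float, ...] = DEFAULT_Q
    lambda_values: tuple[float, ...] = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if not self.q_values or not self.lambda_values:
            raise ValidationError("parameter grid must be non-empty")
        object.__setattr__(self, "q_values", tuple(float(q) for q in self.q_values))
        object.__setattr__(
            self, "lambda_values", tuple(float(l) for l in self.lambda_values)
        )
        if list(self.q_values) != sorted(self.q_values):
            raise ValidationError("q values must be sorted ascending (inf last)")
        if list(self.lambda_values) != sorted(self.lambda_values):
            raise ValidationError("lambda values must be sorted ascending (identity last)")
        if any(q < 0 for q in self.q_values):
            raise ValidationError("q values must be non-negative")
        if any(l < 0 for l in self.lambda_values):
            raise ValidationError("lambda values must be non-negative")

    @property
    def finite_q(self) -> tuple[float, ...]:
        return tuple(q for q in self.q_values if math.isfinite(q))

    @property
    def finite_lambdas(self) -> tuple[float, ...]:
        return tuple(l for l in self.lambda_values if math.isfinite(l))

    def q_index(self, q: float) -> int:
        try:
            return self.q_values.index(float(q))
        except ValueError:
            raise KeyError(f"q={q} not on grid") from None

    def lambda_index(self, lam: float) -> int:
        try:
            return self.lambda_values.index(float(lam))
        except ValueError:
            raise KeyError(f"lambda={lam} not on grid") from None


def _validate_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValidationError("frequencies must be a non-empty 1-D vector")
    if np.any(freqs <= 0):
        raise ValidationError("frequencies must be strictly positive")
    if abs(freqs.sum() - 1.0) > FREQ_TOL:
        raise ValidationError(f"frequencies sum to {freqs.sum()!r}, not 1")
    return freqs


def ln_naive_diversity(freqs: np.ndarray, q: float) -> float:
    """ln D(q) of a frequency vector (log-space evaluation)."""
    freqs = _validate_freqs(freqs)
    logp = np.log(freqs)
    if math.isinf(q):
        return float(-logp.max())
    if q == 1.0:
        return float(-np.dot(freqs, logp))
    return float(logsumexp(q * logp) / (1.0 - q))


def naive_diversity(freqs: np.ndarray, q: float) -> float:
    """Hill number D(q); 1 <= D <= S."""
    return math.exp(ln_naive_diversity(freqs, q))


def kernel_weighted_abundance(
    chunk: DistanceChunk, freqs: np.ndarray, lam: float
) -> np.ndarray:
    """(Zp)_i = sum_j exp(-lambda d_ij) p_j for the rows of one chunk."""
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")
    freqs = np.asarray(freqs, dtype=float)
    if chunk.values.shape[1] != freqs.size:
        raise ValidationError(
            f"chunk has {chunk.values.shape[1]} columns but there are "
            f"{freqs.size} frequencies"
        )
    if math.isinf(lam):  # identity sentinel: Z = I
        return freqs[chunk.row_start : chunk.row_start + chunk.row_count].copy()
    return np.exp(-lam * chunk.values) @ freqs


def ln_similarity_scaled_diversity(
    freqs: np.ndarray, zp: np.ndarray, q: float
) -> float:
    """ln D(q, lambda) given the kernel-weighted abundances (Zp)."""
    freqs = _validate_freqs(freqs)
    zp = np.asarray(zp, dtype=float)
    if zp.shape != freqs.shape:
        raise ValidationError("zp and freqs must have the same shape")
    if np.any(zp < freqs - 1e-9) or np.any(zp > 1.0 + 1e-9):
        raise ValidationError("(Zp)_i must lie in [p_i, 1]")
    log_zp = np.log(np.minimum(zp, 1.0))
    if math.isinf(q):
        return float(-log_zp.max())
    if q == 1.0:
        return float(-np.dot(freqs, log_zp))
    return float(logsumexp(np.log(freqs) + (q - 1.0) * log_zp) / (1.0 - q))


def similarity_scaled_diversity(freqs: np.ndarray, zp: np.ndarray, q: float) -> float:
    """D(q, lambda); satisfies 1 <= D(q, lambda) <= D(q, identity)."""
    return math.exp(ln_similarity_scaled_diversity(freqs, zp, q))


# ---------------------------------------------------------------------------
# grid evaluation


@dataclass
class DiversityGrid:
    """ln D(q, lambda) for one sample over a :class:`ParameterGrid`."""

    sample_id: str
    grid: ParameterGrid
    log_values: np.ndarray  # shape (len(q_values), len(lambda_values))

    def __post_init__(self) -> None:
        self.log_values = np.asarray(self.log_values, dtype=float)
        expected = (len(self.grid.q_values), len(self.grid.lambda_values))
        if self.log_values.shape != expected:
            raise ValidationError(
                f"log_values shape {self.log_values.shape} != grid shape {expected}"
            )
        if not np.all(np.isfinite(self.log_values)):
            raise ValidationError("ln D contains non-finite values")
        if np.any(self.log_values < -1e-9):
            raise ValidationError("ln D must be >= 0")

    def ln_D(self, q: float, lam: float) -> float:
        return float(self.log_values[self.grid.q_index(q), self.grid.lambda_index(lam)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(self.grid.q_values):
            for j, lam in enumerate(self.grid.lambda_values):
                ln_d = self.log_values[i, j]
                rows.append(
                    {
                        "sample_id": self.sample_id,
                        "q": q,
                        "lambda": lam,
                        "ln_D": ln_d,
                        "D": math.exp(ln_d),
                    }
                )
        return pd.DataFrame(rows)


def _zp_matrix_from_chunks(
    chunks: Iterable[DistanceChunk], freqs: np.ndarray, lambdas: tuple[float, ...]
) -> np.ndarray:
    """(S, n_lambda) matrix of (Zp)_i for every finite lambda, one chunk pass."""
    S = freqs.size
    zp = np.full((S, len(lambdas)), np.nan)
    seen = 0
    for chunk in chunks:
        lo, hi = chunk.row_start, chunk.row_start + chunk.row_count
        if hi > S:
            raise ValidationError("chunk rows exceed repertoire size")
        for k, lam in enumerate(lambdas):
            zp[lo:hi, k] = kernel_weighted_abundance(chunk, freqs, lam)
        seen += chunk.row_count
    if seen != S or np.any(np.isnan(zp)):
        raise ValidationError(f"chunks cover {seen} rows of {S}")
    return zp


def _grid_log_values(
    freqs: np.ndarray, zp: np.ndarray, grid: ParameterGrid
) -> np.ndarray:
    """Assemble ln D(q, lambda); identity columns from the naive formula."""
    finite = grid.finite_lambdas
    out = np.empty((len(grid.q_values), len(grid.lambda_values)))
    for j, lam in enumerate(grid.lambda_values):
        for i, q in enumerate(grid.q_values):
            if math.isinf(lam):
                out[i, j] = ln_naive_diversity(freqs, q)
            else:
                out[i, j] = ln_similarity_scaled_diversity(
                    freqs, zp[:, finite.index(lam)], q
                )
    # clip the tiny negative float noise allowed by the invariant
    return np.maximum(out, 0.0)


def diversity_grid(
    rep: Repertoire,
    chunks: str | Path | Iterable[DistanceChunk],
    grid: ParameterGrid | None = None,
) -> DiversityGrid:
    """Evaluate ln D over the whole grid, streaming over distance chunks.

    ``chunks`` is either a manifest path (chunks are read back and validated
    against ``rep``) or an in-memory iterable of chunks.  All finite lambdas
    are accumulated in a single pass over the chunks.
    """
    if grid is None:
        grid = ParameterGrid()
    freqs = np.asarray(rep.frequencies, dtype=float)
    if isinstance(chunks, (str, Path)):
        chunks = read_distance_chunks(chunks, rep)
    zp = _zp_matrix_from_chunks(chunks, freqs, grid.finite_lambdas)
    return DiversityGrid(
        sample_id=rep.sample_id,
        grid=grid,
        log_values=_grid_log_values(freqs, zp, grid),
    )


def diversity_grid_dense(
    freqs: np.ndarray,
    dist: np.ndarray,
    grid: ParameterGrid | None = None,
    sample_id: str = "",
) -> DiversityGrid:
    """Grid evaluation from an explicit dense distance matrix.

    Convenience path for mock repertoires whose distance structure is given
    directly rather than derived from sequences.
    """
    if grid is None:
        grid = ParameterGrid()
    freqs = _validate_freqs(np.asarray(freqs, dtype=float))
    dist = np.asarray(dist, dtype=float)
    S = freqs.size
    if dist.shape != (S, S):
        raise ValidationError(f"distance matrix shape {dist.shape} != ({S}, {S})")
    chunk = DistanceChunk(row_start=0, values=dist, metric_tag="blosum45")
    zp = _zp_matrix_from_chunks([chunk], freqs, grid.finite_lambdas)
    return DiversityGrid(
        sample_id=sample_id, grid=grid, log_values=_grid_log_values(freqs, zp, grid)
    )


# ---------------------------------------------------------------------------
# long-format table I/O


def _token(value: float, identity_token: bool) -> str:
    if math.isinf(value):
        return "identity" if identity_token else "inf"
    return f"{value:.17g}"


def _parse_token(tok: str, identity_token: bool) -> float:
    expected = "identity" if identity_token else "inf"
    if tok == expected:
        return math.inf
    if tok in ("identity", "inf"):
        raise FormatError(f"sentinel token {tok!r} not valid in this column")
    try:
        return float(tok)
    except ValueError:
        raise FormatError(f"cannot parse grid token {tok!r}") from None


def write_diversity_table(dg: DiversityGrid, path: str | Path) -> Path:
    """Long-format TSV: sample_id, q, lambda, ln_D, D (sentinels as tokens)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tq\tlambda\tln_D\tD\n")
        for i, q in enumerate(dg.grid.q_values):
            for j, lam in enumerate(dg.grid.lambda_values):
                ln_d = dg.log_values[i, j]
                fh.write(
                    f"{dg.sample_id}\t{_token(q, False)}\t{_token(lam, True)}"
                    f"\t{ln_d:.17g}\t{math.exp(ln_d):.17g}\n"
                )
    return path


def read_diversity_table(path: str | Path) -> DiversityGrid:
    """Read back a table written by :func:`write_diversity_table` (exact)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "q", "lambda", "ln_D"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    qs = [_parse_token(t, False) for t in df["q"]]
    lams = [_parse_token(t, True) for t in df["lambda"]]
    grid = ParameterGrid(
        q_values=tuple(dict.fromkeys(qs)), lambda_values=tuple(dict.fromkeys(lams))
    )
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise FormatError(f"{path}: expected one sample, found {len(sample_ids)}")
    log_values = np.full((len(grid.q_values), len(grid.lambda_values)), np.nan)
    for q, lam, ln_d in zip(qs, lams, df["ln_D"].astype(float)):
        log_values[grid.q_index(q), grid.lambda_index(lam)] = ln_d
    if np.any(np.isnan(log_values)):
        raise FormatError(f"{path}: incomplete grid")
    return DiversityGrid(sample_id=sample_ids[0], grid=grid, log_values=log_values)
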
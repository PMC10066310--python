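"""Clone-table input/output and repertoire normalisation.

A repertoire arrives as a plain TSV with one row per clone: an amino-acid
CDR3beta sequence and an abundance (integer count or real frequency).  This
module reads and validates such tables, removes sequences that are not
plausible in-frame peptides, subsamples to a fixed depth so repertoires of
different sequencing depth become comparable, and produces the normalised
:class:`Repertoire` (unique sequences, frequencies summing to 1) consumed by
every downstream stage.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_IN_FRAME_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

#: Default subsampling depth (cell-level draws per repertoire).
DEFAULT_DEPTH = 50_000

#: Tolerance on sum(frequencies) == 1.
FREQ_TOL = 1e-9


@dataclass
class RawRepertoire:
    """A clone table as read from disk: sequences with raw abundances.

    Sequences may repeat and abundances are kept verbatim (counts or
    frequencies); no normalisation has happened yet.
    """

    sequences: list[str]
    abundances: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.sequences) != len(self.abundances):
            raise ValidationError("sequences and abundances differ in length")
        if len(self.sequences) == 0:
            raise ValidationError("repertoire has no rows")
        neg = np.nonzero(self.abundances < 0)[0]
        if neg.size:
            raise ValidationError(
                f"negative abundance at row {neg[0]}: {self.abundances[neg[0]]}"
            )
        if not np.any(self.abundances > 0):
            raise ValidationError("no row with positive abundance")

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class Repertoire:
    """A normalised repertoire: unique clones with frequencies summing to 1."""

    sequences: list[str]
    frequencies: np.ndarray
    sample_id: str = ""
    subsample_depth: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.sequences) != len(self.frequencies):
            raise ValidationError("sequences and frequencies differ in length")
        if len(self.sequences) == 0:
            raise ValidationError("repertoire has no clones")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValidationError("sequences are not pairwise distinct")
        if np.any(self.frequencies <= 0):
            raise ValidationError("all frequencies must be strictly positive")
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > FREQ_TOL:
            raise ValidationError(f"frequencies sum to {total!r}, not 1")
        if self.subsample_depth is not None and len(self.sequences) > self.subsample_depth:
            raise ValidationError("more unique clones than subsample depth")

    @property
    def richness(self) -> int:
        """Number of unique clones S."""
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def checksum(self) -> str:
        """Stable sha256 digest of (sequence, frequency) content.

        Used by the distance-chunk manifest to detect that chunks were
        computed from a different repertoire.
        """
        h = hashlib.sha256()
        for seq, p in zip(self.sequences, self.frequencies):
            h.update(f"{seq}\t{p:.17g}\n".encode())
        return h.hexdigest()


def read_repertoire(
    path: str | Path,
    seq_column: str = "sequence",
    abundance_column: str | None = None,
    sample_id: str | None = None,
) -> RawRepertoire:
    """Read a clone table TSV into a :class:`RawRepertoire`.

    Parameters
    ----------
    path
        Tab-delimited UTF-8 file with a header row.
    seq_column
        Name of the sequence column.
    abundance_column
        Name of the abundance column.  When ``None``, ``count`` is tried
        first and then ``frequency``.
    sample_id
        Defaults to the file stem.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    if seq_column not in df.columns:
        raise FormatError(f"{path}: missing column {seq_column!r}")
    if abundance_column is None:
        for cand in ("count", "frequency"):
            if cand in df.columns:
                abundance_column = cand
                break
        else:
            raise FormatError(f"{path}: no 'count' or 'frequency' column")
    elif abundance_column not in df.columns:
        raise FormatError(f"{path}: missing column {abundance_column!r}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    try:
        abund = df[abundance_column].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric abundance: {exc}") from None
    return RawRepertoire(
        sequences=df[seq_column].astype(str).tolist(),
        abundances=abund,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def filter_in_frame(rep: RawRepertoire) -> RawRepertoire:
    """Keep only rows whose sequence is a non-empty canonical peptide.

    Input tables are amino-acid text, so "in frame" is operationalised as:
    the sequence consists solely of the 20 canonical letters — no ``*``
    (stop), no ``X`` (ambiguous), no lowercase, not empty.  Row order is
    preserved and the operation is idempotent.
    """
    keep = [i for i, s in enumerate(rep.sequences) if _IN_FRAME_RE.match(s)]
    if not keep:
        raise ValidationError("no in-frame sequences after filtering")
    return RawRepertoire(
        sequences=[rep.sequences[i] for i in keep],
        abundances=rep.abundances[keep],
        sample_id=rep.sample_id,
        metadata=dict(rep.metadata),
    )


def _collapse(rep: RawRepertoire) -> tuple[list[str], np.ndarray]:
    """Merge rows with identical sequence, summing abundances; drop zero rows."""
    totals: dict[str, float] = {}
    for seq, a in zip(rep.sequences, rep.abundances):
        totals[seq] = totals.get(seq, 0.0) + float(a)
    seqs = [s for s, a in totals.items() if a > 0]
    return seqs, np.array([totals[s] for s in seqs], dtype=float)


def subsample(rep: RawRepertoire, depth: int = DEFAULT_DEPTH, *, seed: int) -> Repertoire:
    """Draw ``depth`` cells from the clone-size distribution and renormalise.

    Duplicate sequences are merged first.  Sampling is multinomial (with
    replacement) over the normalised abundances: this is the only sampling
    scheme that stays well-defined when the input abundances are already
    frequencies rather than read counts.  Clones absent from the draw are
    dropped, so the result has at most ``depth`` unique clones and its
    frequencies sum to exactly 1 (counts / depth).

    The same ``(rep, depth, seed)`` always yields the same output.
    """
    if depth <= 0:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    seqs, abund = _collapse(rep)
    probs = abund / abund.sum()
    total = abund.sum()
    if float(total).is_integer() and total < depth:
        logger.warning(
            "sample %s: total abundance %d below depth %d; multinomial sampling "
            "proceeds with replacement", rep.sample_id, int(total), depth,
        )
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs)
    keep = np.nonzero(counts)[0]
    return Repertoire(
        sequences=[seqs[i] for i in keep],
        frequencies=counts[keep] / depth,
        sample_id=rep.sample_id,
        subsample_depth=depth,
        seed=seed,
    )


def normalize(raw: RawRepertoire, sample_id: str | None = None) -> Repertoire:
    """Collapse duplicates and convert abundances to frequencies, no sampling."""
    seqs, abund = _collapse(raw)
    freqs = abund
    # divide only when needed: frequencies that already sum to 1 (e.g. a
    # re-read table) must round-trip bit-identically
    while abs(freqs.sum() - 1.0) > FREQ_TOL:
        freqs = freqs / freqs.sum()
    return Repertoire(
        sequences=seqs,
        frequencies=freqs,
        sample_id=sample_id if sample_id is not None else raw.sample_id,
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> Path:
    """Write a normalised repertoire as TSV (columns sequence, frequency).

    Frequencies are serialized with 17 significant digits so the table
    round-trips bit-identically through :func:`read_repertoire` +
    :func:`normalize`.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\tfrequency\n")
        for seq, p in zip(rep.sequences, rep.frequencies):
            fh.write(f"{seq}\t{p:.17g}\n")
    return path
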
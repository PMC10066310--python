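"""Synthetic repertoires with controlled clone sizes and similarity structure.

Two families of mocks are provided, mirroring the two knobs of a diversity
profile:

* **explicit-distance mocks** (:func:`make_uniform_mock`,
  :func:`make_cluster_mock`) carry a dense distance matrix directly, so the
  effect of the distance scale on profile features can be dialled exactly
  without going through an alignment metric;
* **sequence mocks** (:func:`make_sequence_repertoire`,
  :func:`make_sequence_cohort`) generate CDR3-like peptides (length 8-18,
  canonical alphabet, leading 'C') by seeding random motifs and expanding
  each by point substitutions — motif tightness (substitutions per clone)
  controls pairwise similarity, while the clone-size law (uniform, power
  law, Dirichlet) controls clonality.  Substitution-only expansion (no
  indels) keeps distances a monotone function of the mutation count.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CANONICAL_AA, Repertoire, write_repertoire

_AA = np.array(list(CANONICAL_AA))


# ---------------------------------------------------------------------------
# frequency laws


def uniform_frequencies(S: int) -> np.ndarray:
    """p_i = 1/S."""
    if S < 1:
        raise ValidationError("S must be >= 1")
    return np.full(S, 1.0 / S)


def powerlaw_frequencies(S: int, exponent: float) -> np.ndarray:
    """Zipf-like clone sizes p_i proportional to i^(-exponent), i = 1..S.

    Deterministic given (S, exponent); exponent -> 0 recovers the uniform
    law.  Power laws are the natural null for clone-size distributions of
    expanded repertoires.
    """
    if S < 1:
        raise ValidationError("S must be >= 1")
    if exponent < 0:
        raise ValidationError("exponent must be >= 0")
    ranks = np.arange(1, S + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def dirichlet_frequencies(S: int, concentration: float, seed: int) -> np.ndarray:
    """A random frequency vector from a symmetric Dirichlet.

    Small concentration gives spiky (clonal) repertoires, large gives nearly
    uniform ones.
    """
    if concentration <= 0:
        raise ValidationError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(S, concentration))
    # Dirichlet can return exact zeros at tiny concentration; nudge and renorm
    p = np.maximum(p, 1e-15)
    return p / p.sum()


# ---------------------------------------------------------------------------
# explicit-distance mocks


def _placeholder_sequences(S: int) -> list[str]:
    return [f"MOCK{i:05d}" for i in range(S)]


def make_uniform_mock(
    S: int, d0: float, seed: int = 0, sample_id: str | None = None
) -> tuple[Repertoire, np.ndarray]:
    """Uniform S-clone repertoire with constant pairwise distance d0.

    The frequency-weighted mean distance is d-bar = d0 * (1 - 1/S)
    (the zero diagonal removes 1/S of the mass).  The ``seed`` only names
    the sample; the construction is deterministic.
    """
    if S < 2:
        raise ValidationError("uniform mock needs S >= 2")
    if d0 < 0:
        raise ValidationError("d0 must be >= 0")
    dist = np.full((S, S), float(d0))
    np.fill_diagonal(dist, 0.0)
    rep = Repertoire(
        sequences=_placeholder_sequences(S),
        frequencies=uniform_frequencies(S),
        sample_id=sample_id if sample_id is not None else f"uniform_mock_d{d0:g}_s{seed}",
    )
    return rep, dist


def make_cluster_mock(
    S: int,
    cluster_size: int,
    d_within: float,
    d_between: float,
    cluster_mass: float,
    sample_id: str = "cluster_mock",
) -> tuple[Repertoire, np.ndarray]:
    """A two-scale mock: a tight cluster inside an otherwise spread repertoire.

    The first ``cluster_size`` clones are mutually close (distance
    ``d_within``), all other pairs sit at ``d_between``; a frequency mass of
    ``cluster_mass`` is spread evenly over the cluster and the rest over the
    remaining clones.  Moving mass into the cluster simultaneously lowers the
    weighted mean distance (hence the small-lambda spacing) and deepens the
    similarity-driven diversity drop at large lambda (hence the area between
    the upper lambda curves) — the coupling that clone-size randomisation is
    meant to destroy.
    """
    if not 0 < cluster_size < S:
        raise ValidationError("need 0 < cluster_size < S")
    if not 0 < cluster_mass < 1:
        raise ValidationError("cluster_mass must be in (0, 1)")
    if d_within < 0 or d_between < 0:
        raise ValidationError("distances must be >= 0")
    dist = np.full((S, S), float(d_between))
    dist[:cluster_size, :cluster_size] = d_within
    np.fill_diagonal(dist, 0.0)
    freqs = np.empty(S)
    freqs[:cluster_size] = cluster_mass / cluster_size
    freqs[cluster_size:] = (1.0 - cluster_mass) / (S - cluster_size)
    rep = Repertoire(
        sequences=_placeholder_sequences(S),
        frequencies=freqs / freqs.sum(),
        sample_id=sample_id,
    )
    return rep, dist


def mean_pairwise_distance(freqs: np.ndarray, dist: np.ndarray) -> float:
    """d-bar = sum_ij p_i p_j d_ij, the frequency-weighted mean distance."""
    freqs = np.asarray(freqs, dtype=float)
    return float(freqs @ np.asarray(dist, dtype=float) @ freqs)


def make_structured_cohort(
    n_samples: int = 20, S: int = 60, cluster_size: int = 12
) -> list[tuple[Repertoire, np.ndarray]]:
    """A cohort emulating progressive expansion of sequence-similar clones.

    Sample k moves along a clonal-expansion gradient: the frequency mass on
    the tight cluster rises (0.05 -> 0.9) while the cluster simultaneously
    tightens (within-cluster distance 0.08 -> 0.02), the coupling seen when
    an immune response expands similar clones.  The global spread of each
    sample (between-cluster distance, 0.75-0.85) varies along a fixed stride
    permutation of the sample index, so it is rank-orthogonal to the
    expansion gradient by construction.

    Consequence: the small-lambda spacing and the area between the identity
    and lambda=16 curves are strongly rank-anticorrelated across the cohort,
    and replacing the clone sizes with pseudo-random numbers (keeping each
    distance matrix fixed, :func:`divprof.cohort.randomize_clone_sizes`)
    destroys the correlation — spacing then follows the orthogonal global
    spread while the area follows the tightness gradient.

    Fully deterministic: no random draws are involved.
    """
    ks = np.arange(n_samples)
    masses = np.linspace(0.05, 0.9, n_samples)
    tightness = np.linspace(0.08, 0.02, n_samples)
    stride = 9 if n_samples == 20 else max(2, n_samples // 2 - 1)
    spread = 0.75 + 0.1 * ((stride * ks) % n_samples) / max(n_samples - 1, 1)
    return [
        make_cluster_mock(
            S, cluster_size, tightness[k], spread[k], masses[k],
            sample_id=f"structured_{k:02d}",
        )
        for k in ks
    ]


# ---------------------------------------------------------------------------
# sequence mocks


@dataclass(frozen=True)
class MockSpec:
    """Recipe for one class of motif-expanded synthetic repertoires.

    Parameters
    ----------
    S
        Number of clones drawn per sample (unique count can be lower if
        expansion produces duplicate peptides, which are merged).
    size_law
        ``("uniform",)``, ``("powerlaw", exponent)`` or
        ``("dirichlet", concentration)``.
    n_motifs
        Number of independent seed motifs.
    mutations_per_step
        Point substitutions applied to the motif for each derived clone;
        0 collapses the motif's clones into one (tightest possible class).
    length_range
        Inclusive CDR3 length bounds (leading 'C' included).
    """

    S: int = 100
    size_law: tuple = ("uniform",)
    n_motifs: int = 3
    mutations_per_step: int = 2
    length_range: tuple[int, int] = (8, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValidationError("S must be >= 1")
        if self.n_motifs < 1:
            raise ValidationError("n_motifs must be >= 1")
        if self.mutations_per_step < 0:
            raise ValidationError("mutations_per_step must be >= 0")
        lo, hi = self.length_range
        if not 2 <= lo <= hi:
            raise ValidationError("length_range must satisfy 2 <= lo <= hi")
        if self.n_motifs > self.S:
            raise ValidationError("more motifs than requested clones")


def random_cdr3(rng: np.random.Generator, length_range: tuple[int, int] = (8, 18)) -> str:
    """A CDR3-like peptide: leading 'C', random canonical tail."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "C" + "".join(rng.choice(_AA, size=length - 1))


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply n point substitutions (positions after the leading 'C')."""
    chars = list(seq)
    for _ in range(n_subs):
        pos = int(rng.integers(1, len(chars)))
        current = chars[pos]
        choices = [a for a in CANONICAL_AA if a != current]
        chars[pos] = str(rng.choice(choices))
    return "".join(chars)


def _law_frequencies(size_law: tuple, S: int, rng: np.random.Generator) -> np.ndarray:
    kind = size_law[0]
    if kind == "uniform":
        return uniform_frequencies(S)
    if kind == "powerlaw":
        return powerlaw_frequencies(S, size_law[1])
    if kind == "dirichlet":
        return dirichlet_frequencies(S, size_law[1], int(rng.integers(2**31)))
    raise ValidationError(f"unknown size law {size_law!r}")


def make_sequence_repertoire(
    spec: MockSpec, seed: int | None = None, sample_id: str = "seq_mock"
) -> Repertoire:
    """One motif-expanded repertoire; duplicates are merged (summed).

    Clones are assigned to motifs round-robin; each clone is its motif with
    ``mutations_per_step`` random substitutions, so a smaller value gives a
    tighter (more similar) repertoire.  Frequencies follow ``size_law`` in
    generation order, then merge with duplicates.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    motifs = [random_cdr3(rng, spec.length_range) for _ in range(spec.n_motifs)]
    rows = [
        _mutate(motifs[i % spec.n_motifs], spec.mutations_per_step, rng)
        for i in range(spec.S)
    ]
    freqs = _law_frequencies(spec.size_law, spec.S, rng)
    merged: dict[str, float] = {}
    for seq, p in zip(rows, freqs):
        merged[seq] = merged.get(seq, 0.0) + float(p)
    seqs = list(merged)
    p = np.array([merged[s] for s in seqs])
    return Repertoire(sequences=seqs, frequencies=p / p.sum(), sample_id=sample_id)


def make_sequence_cohort(
    class_specs: dict[str, MockSpec],
    n_per_class: int,
    out_dir: str | Path | None = None,
) -> tuple[list[Repertoire], pd.DataFrame]:
    """A labelled cohort of motif-expanded repertoires, one spec per class.

    Per-sample seeds are derived from each spec's seed, so the cohort is a
    pure function of the specs.  When ``out_dir`` is given, each sample is
    written as a clone-table TSV alongside a ``labels.tsv`` manifest.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    reps: list[Repertoire] = []
    rows = []
    for label, spec in class_specs.items():
        seed_seq = np.random.SeedSequence(entropy=spec.seed)
        child_seeds = seed_seq.generate_state(n_per_class)
        for k in range(n_per_class):
            sid = f"{label}_{k:02d}"
            rep = make_sequence_repertoire(
                spec, seed=int(child_seeds[k] % 2**31), sample_id=sid
            )
            reps.append(rep)
            rows.append({"sample_id": sid, "label": label})
    labels = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep in reps:
            write_repertoire(rep, out_dir / f"{rep.sample_id}.tsv")
        labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    return reps, labels
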
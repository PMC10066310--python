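"""Scalar features of a diversity profile.

A diversity grid ln D(q, lambda) is reduced to a small feature vector:

* **areas between lambda curves** — for each adjacent pair of lambdas in the
  sorted grid (identity last), the composite-trapezoid integral over the
  finite q axis of the gap between the two curves.  Because ln D is
  non-decreasing in lambda, every adjacent-pair area is non-negative, and the
  area between any two non-adjacent lambdas (e.g. identity and 16) is the sum
  of the adjacent areas between them.
* **mean small-lambda spacing** — the mean over adjacent pairs of
  lambda in {0.0, 0.1, 0.2, 0.3, 0.4, 0.5} of the q-averaged increment
  Delta ln D.  For small lambda the profile curves are nearly flat and evenly
  spaced; perturbation of the kernel around lambda=0 shows the spacing is
  proportional to the frequency-weighted mean pairwise distance
  d-bar = sum_ij p_i p_j d_ij, independent of q — so this feature reads off
  the overall sequence similarity of the repertoire.
* **q-slopes** — finite differences ln D(q_b) - ln D(q_a) for
  (0,1), (1,2), (0,2) at every lambda including identity; more negative
  slopes mean a clone-size distribution dominated by few large clones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import IDENTITY, DiversityGrid
from .errors import ValidationError

#: Lambdas over which the small-lambda spacing is averaged (0.25 deliberately
#: excluded: the spacing set is the evenly 0.1-spaced prefix of the grid).
SMALL_LAMBDAS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

#: (q_a, q_b) pairs for the slope features.
SLOPE_PAIRS = ((0.0, 1.0), (1.0, 2.0), (0.0, 2.0))


def _lambda_label(lam: float) -> str:
    return "identity" if math.isinf(lam) else f"{lam:g}"


def area_between_lambda_curves(
    dg: DiversityGrid, lambda_low: float, lambda_high: float
) -> float:
    """Trapezoid integral over finite q of ln D(q, high) - ln D(q, low).

    The integration axis is the finite q grid (q=inf is excluded: the
    trapezoid rule needs a finite abscissa).  Non-negative whenever
    ``lambda_high > lambda_low`` by monotonicity of ln D in lambda.
    """
    j_lo = dg.grid.lambda_index(lambda_low)
    j_hi = dg.grid.lambda_index(lambda_high)
    finite_q = [i for i, q in enumerate(dg.grid.q_values) if math.isfinite(q)]
    if len(finite_q) < 2:
        raise ValidationError("need at least two finite q values to integrate")
    qs = np.array([dg.grid.q_values[i] for i in finite_q])
    gap = dg.log_values[finite_q, j_hi] - dg.log_values[finite_q, j_lo]
    return float(np.trapezoid(gap, qs))


def mean_small_lambda_spacing(
    dg: DiversityGrid, small_lambdas: tuple[float, ...] = SMALL_LAMBDAS
) -> float:
    """Mean over adjacent small-lambda pairs of the q-averaged Delta ln D.

    Differences are not normalised by Delta lambda (the default set is
    evenly spaced at 0.1, so the spacing approximates 0.1 * d-bar).
    """
    if len(small_lambdas) < 2:
        raise ValidationError("need at least two lambdas for a spacing")
    finite_q = [i for i, q in enumerate(dg.grid.q_values) if math.isfinite(q)]
    cols = [dg.grid.lambda_index(l) for l in small_lambdas]
    deltas = []
    for j_a, j_b in zip(cols[:-1], cols[1:]):
        deltas.append(
            float(np.mean(dg.log_values[finite_q, j_b] - dg.log_values[finite_q, j_a]))
        )
    return float(np.mean(deltas))


def q_slope(dg: DiversityGrid, lam: float, q_a: float, q_b: float) -> float:
    """Finite difference ln D(q_b, lam) - ln D(q_a, lam), q_a < q_b finite.

    Negative for non-uniform repertoires (ln D falls as q rises); reported
    as-is, not divided by q_b - q_a.
    """
    if math.isinf(q_a) or math.isinf(q_b):
        raise ValidationError("q slopes are finite differences; q=inf not allowed")
    if not q_a < q_b:
        raise ValidationError(f"need q_a < q_b, got {q_a}, {q_b}")
    return dg.ln_D(q_b, lam) - dg.ln_D(q_a, lam)


@dataclass
class FeatureVector:
    """Named scalar features of one sample's diversity profile."""

    sample_id: str
    values: dict[str, float]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.sample_id)


def extract_features(dg: DiversityGrid) -> FeatureVector:
    """All adjacent-pair areas, the small-lambda spacing, and the q-slopes.

    Feature names are stable: ``area_l<low>_l<high>``, ``dln_small_lambda``,
    ``slope_q<a>_<b>_l<lambda>`` with ``identity`` as the lambda token.
    Any non-adjacent area is recoverable as a sum of adjacent ones.
    """
    lams = dg.grid.lambda_values
    values: dict[str, float] = {}
    for lo, hi in zip(lams[:-1], lams[1:]):
        name = f"area_l{_lambda_label(lo)}_l{_lambda_label(hi)}"
        values[name] = area_between_lambda_curves(dg, lo, hi)
    values["dln_small_lambda"] = mean_small_lambda_spacing(dg)
    for q_a, q_b in SLOPE_PAIRS:
        for lam in lams:
            name = f"slope_q{q_a:g}_{q_b:g}_l{_lambda_label(lam)}"
            values[name] = q_slope(dg, lam, q_a, q_b)
    bad = [k for k, v in values.items() if not math.isfinite(v)]
    if bad:
        raise ValidationError(f"non-finite features: {bad}")
    return FeatureVector(sample_id=dg.sample_id, values=values)


def features_frame(grids: list[DiversityGrid]) -> pd.DataFrame:
    """One row per sample, one column per feature (deterministic order)."""
    series = [extract_features(dg).to_series() for dg in grids]
    df = pd.DataFrame(series)
    df.index.name = "sample_id"
    return df


def area_to_identity(dg: DiversityGrid, lambda_low: float) -> float:
    """Area between the lambda_low curve and the naive (identity) curve."""
    return area_between_lambda_curves(dg, lambda_low, IDENTITY)
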
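"""Profile one repertoire: from clone table to D(q, lambda) grid.

Builds a small synthetic clone table, runs the per-sample pipeline stages in
memory (filter, subsample, distances, diversity), and prints a slice of the
profile.  ln D falls as q rises (large clones dominate) and rises with
lambda (clones are merged less aggressively), between the floor D=1 at
lambda=0 and the naive Hill number at lambda=identity.
"""

import math

import numpy as np

from divprof import (
    IDENTITY,
    RawRepertoire,
    diversity_grid,
    filter_in_frame,
    iter_distance_chunks,
    subsample,
)

# a clone table as it might arrive from upstream processing: sequences with
# read counts, including one out-of-frame entry that the filter removes
rng = np.random.default_rng(0)
sequences = ["CASSLGQAYEQYF", "CASSLGQSYEQYF", "CASSLGQAYEQFF",
             "CAWSVGTGGTNEKLFF", "CAWSVGTGATNEKLFF", "CASS*GQAYEQYF"]
counts = [400, 250, 150, 120, 75, 33]
raw = RawRepertoire(sequences, counts, sample_id="demo")

rep = subsample(filter_in_frame(raw), depth=500, seed=7)
print(f"{rep.richness} unique in-frame clones after subsampling to depth 500")

dg = diversity_grid(rep, iter_distance_chunks(rep, metric="blosum45"))

print("\n   q    D(q, 0)   D(q, 1.0)  D(q, identity)")
for q in (0.0, 1.0, 2.0, math.inf):
    row = [math.exp(dg.ln_D(q, lam)) for lam in (0.0, 1.0, IDENTITY)]
    q_label = "inf" if math.isinf(q) else f"{q:g}"
    print(f"  {q_label:>4}  {row[0]:8.3f}  {row[1]:9.3f}  {row[2]:13.3f}")

print(
    "\nAt lambda=0 every clone is treated as identical (D=1); at identity the"
    "\ncolumn reproduces the naive Hill numbers; at lambda=1 the two motif"
    "\nfamilies are partially merged, so D sits between the two extremes."
)
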
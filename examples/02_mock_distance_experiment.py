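"""The mock distance experiment: profile features track sequence similarity.

Three uniform 100-clone repertoires differ only in their constant pairwise
distance (I: 0.1, II: 0.2, III: 0.4).  The mean small-lambda spacing of the
profile (approximately 0.1 * mean pairwise distance) rises from I to III,
while the area between the identity and lambda=16 curves falls — the two
features are inversely related when clone sizes are uniform.
"""

from divprof import (
    IDENTITY,
    area_between_lambda_curves,
    diversity_grid_dense,
    make_uniform_mock,
    mean_pairwise_distance,
    mean_small_lambda_spacing,
)

print(" rep   d0    d-bar   spacing  0.1*d-bar  area(16, identity)")
for name, d0 in (("I", 0.1), ("II", 0.2), ("III", 0.4)):
    rep, dist = make_uniform_mock(100, d0)
    dg = diversity_grid_dense(rep.frequencies, dist, None, rep.sample_id)
    dbar = mean_pairwise_distance(rep.frequencies, dist)
    spacing = mean_small_lambda_spacing(dg)
    area = area_between_lambda_curves(dg, 16.0, IDENTITY)
    print(f" {name:>3}  {d0:.2f}  {dbar:.4f}  {spacing:.5f}   {0.1 * dbar:.5f}"
          f"     {area:8.4f}")

print(
    "\nThe spacing column matches 0.1*d-bar (the perturbation prediction for"
    "\nthe 0.1-spaced small-lambda set) and rises with distance; the area"
    "\ncolumn falls: more similar repertoires lose more diversity when the"
    "\nkernel starts merging clones near lambda=16."
)
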
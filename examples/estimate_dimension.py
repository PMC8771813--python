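"""Estimate the intrinsic dimension of a sampled manifold.

Samples 1000 points uniformly from the unit square with torus (periodic)
distances — the setting where the local two-scale estimator's assumptions
hold exactly — and compares the three global aggregates across
neighborhood sizes.
"""

import fsadim as fd

cloud = fd.sample_hypercube(
    fd.ManifoldSpec("hypercube", D=2, n=1000, seed=0, boundary="periodic_unit")
)

print("n = 1000 points uniform on the unit torus square (true D = 2)\n")
print(" k   median (mFSA)    mean (FSA)      max likelihood")
for k in (1, 2, 5, 10, 20):
    radii = fd.knn_radii(cloud, k)
    local = fd.local_fsa(radii)
    med = fd.fsa_median(local).value
    mean = fd.fsa_mean(local).value
    ml = fd.ml_dimension(local, k).value
    print(f"{k:2d}   {med:12.3f}   {mean:12.3f}   {ml:12.3f}")

print(
    "\nThe median sits at 2 for every k (its population value is exactly D);"
    "\nthe mean is biased high at small k, following D + 0.685 D/(k-1), and"
    "\nthe likelihood solution tracks the truth once k is moderate."
)
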
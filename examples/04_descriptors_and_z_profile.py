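"""Per-cluster descriptors and the axial (z) profile of clustering.

After analysis, `summarize` output carries one record per detected
cluster (size, MAP radius, RMS radius, precision-weighted centroid) and
`z_profile` bins the ROI into 30 nm z slabs to show where along the
optical axis the clustered fraction lives.

Run:  python examples/04_descriptors_and_z_profile.py
"""

import numpy as np

from bayescluster3d import analyze_roi, simulate_roi, standard_condition

spec = standard_condition(seed=7)
table, _ = simulate_roi(spec)
result = analyze_roi(table, spec.roi)

print("per-cluster descriptors:")
for c in result.descriptors["clusters"]:
    cx, cy, cz = c["x"], c["y"], c["z"]
    print(f"  cluster {c['id']:2d}: n = {c['n_points']:3d}, "
          f"MAP radius = {c['map_radius']:5.1f} nm, "
          f"RMS radius = {c['rms_radius']:5.1f} nm, "
          f"centroid = ({cx:6.0f}, {cy:6.0f}, {cz:5.0f})")

prof = result.profile
print("\nz profile (30 nm bins): localizations and clustered % per bin")
for lo, hi, n, pct in zip(prof.edges[:-1], prof.edges[1:],
                          prof.locs_per_bin, prof.percent_in_clusters):
    bar = "#" * int(round(pct / 5))
    print(f"  z {lo:4.0f}-{hi:4.0f} nm: {int(n):3d} locs, {pct:5.1f}% {bar}")

pooled = (np.sum(prof.percent_in_clusters * prof.locs_per_bin)
          / prof.locs_per_bin.sum())
print(f"\npooled clustered fraction: {pooled:.1f}%")
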
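"""Specificity check: the pipeline on completely random (CSR) data.

On a homogeneous Poisson point cloud there are no true clusters, so the
fraction of points the MAP proposal labels as clustered is the method's
false-positive rate.  It should stay in the low single-digit percent range.

Run:  python examples/02_csr_specificity.py
"""

from bayescluster3d import analyze_roi, csr_condition, simulate_roi

clustered = total = 0
for seed in range(3):
    spec = csr_condition(n_total=1000, seed=seed)
    table, _ = simulate_roi(spec)
    d = analyze_roi(table, spec.roi).descriptors
    fp = d["n_total"] - d["n_background"]
    clustered += fp
    total += d["n_total"]
    print(f"seed {seed}: K = {d['K']:2d}, "
          f"{fp}/{d['n_total']} points labelled clustered")

print(f"\npooled false-positive rate: {100.0 * clustered / total:.2f}% of points")
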
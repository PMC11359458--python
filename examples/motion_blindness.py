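"""Why motion-based detectors miss attached colloids.

Simulates two short sequences — one where every colloid is attached to a
grain (stationary) and one where half are mobile — and compares the
recall of the frame-differencing detectors (FDBS, MFD) with k-means.
A stationary colloid produces zero intensity change between frames, so
differencing methods cannot see it at all.
"""

import colloidspot as cs

for frac_attached, label in [(1.0, "all colloids attached"), (0.5, "half mobile")]:
    cfg = cs.SceneConfig.ci_scale(seed=5, frac_attached=frac_attached, n_frames=9)
    seq, truth = cs.generate_scene(cfg)
    res = cs.run_benchmark(seq, truth, methods=("fdbs", "mfd", "kmeans"))
    rec = res.metrics.summary["recall_mean"]
    print(f"{label}:")
    for m in ("fdbs", "mfd", "kmeans"):
        print(f"  {m:<8} recall = {rec[m]:.3f}")
    print()

print(
    "With every colloid stationary the differencing detectors find nothing\n"
    "(recall 0); with mobile colloids they recover roughly the fraction\n"
    "that moved, while intensity-based k-means sees all colloids either way."
)
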
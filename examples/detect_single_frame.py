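"""Run each static detector on one synthetic micromodel frame.

Renders the 256x256 reference frame (20 colloids, noise-free), applies
the single-frame detectors and prints, per method, how many objects were
found and how they match the planted ground truth.  TP = colloids found,
FP = spurious detections, FN = colloids missed.
"""

import colloidspot as cs

cfg = cs.SceneConfig.ci_scale(seed=42)
frame, truth = cs.render_reference_frame(cfg)
print(f"frame {frame.height}x{frame.width}, {truth.n_targets(0)} planted colloids\n")

detectors = {
    "kmeans": lambda f: cs.kmeans_detect(f, k=3, seed=0),
    "otsu": cs.otsu_detect,
    "laplacian": cs.laplacian_detect,
    "dog": cs.dog_detect,
    "dilation": cs.dilation_detect,
    "tophat": cs.tophat_detect,
}

print(f"{'method':<10}{'objects':>8}{'TP':>6}{'FP':>6}{'FN':>6}")
for name, fn in detectors.items():
    mask = fn(frame)
    dets = cs.extract_detections(mask, method=name, max_area=200)
    c = cs.match_detections(dets, truth.centers(0), tol=3.0)
    print(f"{name:<10}{len(dets):>8}{c.tp:>6}{c.fp:>6}{c.fn:>6}")

print(
    "\nk-means and top-hat isolate exactly the colloid pixels; DoG and the"
    "\nLaplacian add a few small grain-boundary responses (false positives);"
    "\nOtsu and dilation split grain from pore instead, so the whole pore"
    "\nnetwork passes the threshold and is rejected by the area filter."
)
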
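# colloidspot

Detection of micrometre-scale colloids in micromodel image sequences.

Colloids — here, ~4 µm fluorescent microspheres standing in for pathogens
and engineered nanoparticles transported in groundwater — are imaged as
1–2 px bright spots moving through a microfluidic replica of a porous
medium (a *micromodel*: dark solid grains, lighter pore space, bright
particles). Counting and localizing them frame by frame is the
prerequisite for every downstream pore-scale transport analysis, and doing
it by hand over hundreds of 1684×1688 frames is not practical.

`colloidspot` implements eight classical spot detectors in four families,
fuses the three best with a majority vote, and ships the evaluation and
ranking machinery plus a synthetic micromodel generator so the whole
pipeline is testable end to end with no external data:

* **segmentation**: 1-D k-means on the intensity histogram (k = 3 for
  grain / pore / colloid; highest-centre cluster = colloids), and Otsu
  thresholding at the `T` maximizing the between-class variance
  `Var(T) = P₀(T)·P₁(T)·(m₀(T) − m₁(T))²`;
* **background / motion**: two- and three-frame differencing
  (`|fₙ − fₙ₋₁| > T`), FDBS (frame difference AND background subtraction
  against a temporal-median background), and MFD (mean of the three
  pairwise absolute differences of `fₜ₋₁, fₜ, fₜ₊₁`, thresholded);
* **linear filters**: a centre-positive 4-neighbour Laplacian stencil, and
  a 3×3 Difference-of-Gaussians kernel (σ₁ = 0.5, σ₂ = 2, each truncated
  Gaussian renormalized so the kernel is exactly zero-sum) with a
  threshold-plus-zero-crossing detection rule;
* **morphology**: grayscale dilation (disk r = 4) and white top-hat
  `T_w(A) = A − (A ∘ B)` (disk r = 2), each followed by Otsu binarization;
* **ensemble**: object-level majority vote — detections from top-hat, DoG
  and k-means within a 5-px radius are one candidate colloid, kept iff at
  least 2 of 3 methods detected it.

Scoring uses greedy one-to-one matching of detections to ground-truth
centres (tolerance 3 px; duplicates → FP, merged detections → 1 TP + FN),
the standard Precision / Recall / F-measure and the Target-to-Clutter
Ratio `TCR = DT/(DT + MT + FA)`, and method comparison via the Friedman
rank test with Holm-corrected pairwise post-hocs.

## Worked example

```python
import colloidspot as cs

cfg = cs.SceneConfig.ci_scale(seed=42)        # 256x256, 20 colloids, noise-free
frame, truth = cs.render_reference_frame(cfg)
seq = cs.FrameSequence((frame,))
dets = cs.benchmark.ensemble_detections(seq, 0, cs.DetectorConfig())
print(cs.match_detections(dets, truth.centers(0), tol=3.0))
# ConfusionCounts(tp=20, fp=0, fn=0)
```

`python examples/detect_single_frame.py` compares all detectors on that
frame:

```
method     objects    TP    FP    FN
kmeans          20    20     0     0
otsu             3     0     3    20
laplacian       25    20     5     0
dog             24    20     4     0
dilation         2     0     2    20
tophat          20    20     0     0
```

k-means and top-hat isolate exactly the colloid pixels. DoG and the
Laplacian find every colloid but also a few small grain-boundary
responses; those false positives are uncorrelated across methods, so the
majority vote removes them (`examples/ensemble_vote.py`) and the ensemble
scores TP = 20, FP = 0, FN = 0. Otsu and dilation+Otsu split grain from
pore instead of pore from colloid on this trimodal scene — a documented
failure mode, see `docs/methods.md`. `examples/benchmark_ranking.py` runs
the full 25-frame benchmark and prints the metric table and Friedman
ranks; `examples/motion_blindness.py` shows why frame-differencing
detectors miss attached (stationary) colloids.

The same pipeline is available from the shell:

```bash
colloidspot simulate --out scene/ --n-colloids 20 --height 256 --width 256
colloidspot detect --input scene/frames.tif --method ensemble --out dets.csv
colloidspot evaluate --detections dets.csv --truth scene/ground_truth.csv
colloidspot benchmark --out bench/ --ci-scale
```

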
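"""Full benchmark with Friedman ranking on a small synthetic sequence.

Runs all eight single detectors plus the ensemble over the 25 interior
frames of a 256x256 scene, prints the average-metrics table (mean ± std
per method), the Friedman mean ranks computed on the per-frame F-measures
(rank 1 = best), and the number of Holm-significant pairwise differences.
"""

import colloidspot as cs

cfg = cs.SceneConfig.ci_scale(seed=42)
seq, truth = cs.generate_scene(cfg)
result = cs.run_benchmark(seq, truth)

print(result.metrics.to_text())
ranks = result.ranks
print(f"\nFriedman chi-square = {ranks.statistic:.2f}, p = {ranks.pvalue:.3g} "
      f"over {ranks.n_blocks} frames")
print("\nmean ranks (1 = best):")
print(ranks.mean_ranks.round(2).to_string())
n_sig = int(ranks.pairwise["reject"].sum())
print(f"\nHolm post hoc: {n_sig} of {len(ranks.pairwise)} pairwise "
      f"differences significant at alpha = {ranks.alpha}")
print(
    "\nThe ensemble scores 1.0 on every metric; the top-hat, k-means and DoG"
    "\ndetectors occupy the best Friedman ranks, and the motion-based methods"
    "\ntrail because attached colloids are invisible to them."
)
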
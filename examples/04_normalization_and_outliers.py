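"""Compare normalization factors and screen counts for influential outliers.

Builds a dataset where one sample was sequenced twice as deeply and a few
counts were corrupted, then shows that TMM and median-of-ratios both
recover the depth difference, and that Cook's distance flags the corrupted
cells.
"""

import numpy as np

from decombine import SimConfig, cooks_distance, inject_outliers, median_of_ratios, run_nb_wald, simulate_dataset, tmm_factors

cfg = SimConfig.from_preset(1, n_per_group=10, seed=11, n_genes=1000)
cm, sheet, truth = simulate_dataset(cfg, 0)
cm, truth = inject_outliers(cm, truth, "single", np.random.default_rng(11))

tmm = tmm_factors(cm)
mor = median_of_ratios(cm)
print("per-sample normalization factors:")
print(f"  {'sample':8s} {'lib size':>10s} {'TMM':>8s} {'med-ratios':>11s}")
for i, s in enumerate(cm.sample_ids):
    print(f"  {s:8s} {tmm.library_sizes[i]:10.0f} {tmm.factors[i]:8.3f} {mor.factors[i]:11.3f}")

fit = run_nb_wald(cm, sheet)
# screen against the trend dispersion: a gross outlier inflates its own
# gene's dispersion estimate and would otherwise mask itself
ct = cooks_distance(cm, mor, fit.extras["dispersion_trend"], sheet)
flagged = ct.flagged()
injected = {(g, s) for g, s, _ in truth.outlier_cells}
hits = sum(flagged.loc[g, s] for g, s in injected)
print(f"\nCook's distance threshold (99th pct of F(2, {cm.n_samples - 2})): {ct.threshold:.2f}")
print(f"injected outlier cells: {len(injected)}; flagged by Cook's screen: {hits}")
print(
    "corrupted cells on low-count genes stay within negative-binomial noise\n"
    "and are legitimately not flagged; flags are reported for inspection,\n"
    "never silently removed."
)
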
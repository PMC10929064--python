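"""Robustness of the optimised models to sample size and age composition.

Two analyses: (1) refit the optimised model by 5-fold CV in random subsets
of increasing size and watch the MAE curve flatten; (2) re-estimate each
pretrained model's accuracy inside nine age bins and correlate the
region-wise error vectors with the full-sample ones.
"""

import warnings

import morphonorm as mn
from morphonorm.sensitivity import (
    age_bin_analysis,
    sample_size_curve,
    sample_size_grid,
)

warnings.filterwarnings("ignore")

MEASURES = ["lh_medialorbitofrontal_thickness", "Left-Thalamus",
            "lh_superiorfrontal_area", "rh_precentral_thickness"]
cfg = mn.SyntheticConfig(n_per_sex=2500, measures=MEASURES, seed=4)
table, _ = mn.generate_cohort(cfg)
females = table.by_sex("F")

full_grid = sample_size_grid()  # 200..15000 step 200
print(f"full sample-size grid: {len(full_grid)} sizes "
      f"({full_grid[0]}-{full_grid[-1]})")

sizes = [200, 600, 1200, 1800, 2400]
rep = sample_size_curve(females, sizes, MEASURES, seed=0)
curve = rep.per_size.groupby("size")["mae"].mean()
print("\nmean MAE by subset size (demo grid):")
for size, mae in curve.items():
    print(f"  n={size:5d}  MAE={mae:.4f}")
print(f"plateau estimate: n={rep.plateau_estimate}")

bundles = [mn.train_normative_model(table, m, "F") for m in MEASURES]
bins = age_bin_analysis(table, bundles, seed=0)
mae_r = bins.bin_full_r.query("metric == 'mae'")
print(f"\nage-bin robustness ({len(bundles)} models, "
      f"{bins.per_bin['bin'].nunique()} bins): "
      f"bin-vs-full MAE correlation min={mae_r['pearson_r'].min():.3f}, "
      f"median={mae_r['pearson_r'].median():.3f}")
# High correlations mean the region-to-region error ordering is preserved in
# every age group, so one reference model serves the whole lifespan.
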
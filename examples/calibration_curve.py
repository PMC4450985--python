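"""Fit and inspect a probability-calibration curve.

The ensemble's averaged leaf proportions only loosely track true signal
frequencies. This example builds the calibration corpus from out-of-bag
estimates, fits the two-parameter sigmoid, and prints the mapping at the
eleven bin centers.
"""

import numpy as np
import pandas as pd

import spotcount as sc

cfg = sc.SimulationConfig(shape=(15, 160, 160), n_spots=30, seed=5, stack_id="cal")
stack, truth = sc.simulate_stack(cfg)
table, _ = sc.detect_and_featurize(stack)
truth_df = pd.DataFrame(
    [{"stack_id": truth.stack_id, "z": z, "y": y, "x": x}
     for z, y, x, _ in truth.sources]
)
training = sc.label_candidates(table, truth_df)

model = sc.train_forest(training, n_trees=200, seed=17)
p_oob, y_oob, _ = sc.oob_probabilities(model, training)
curve = sc.build_calibration(p_oob, y_oob)

if curve.method == "sigmoid":
    print(f"fit method: sigmoid   a={curve.a:.2f}  b={curve.b:.2f}")
else:
    # Cleanly separated corpora push the sigmoid slope to infinity; the
    # builder then falls back to a monotone clamp of the bin proportions.
    print("fit method: monotone_bins (corpus separated too cleanly for a sigmoid)")
print(f"weighted rms residual: {curve.residual:.4f}")
print()
print("bin center | corpus n | observed true frac | calibrated g(p)")
for c, n, prop in zip(curve.bin_centers, curve.bin_counts, curve.bin_proportions):
    obs = f"{prop:18.3f}" if not np.isnan(prop) else "        (empty)   "
    print(f"   {c:.1f}     | {int(n):7d}  |{obs}  | {sc.apply_calibration(curve, c):.3f}")
print()
print("g maps a preliminary ensemble probability to the empirical fraction")
print("of true spots among curated candidates that scored the same; the")
print("hard signal/noise call is g(p) > 0.5.")
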
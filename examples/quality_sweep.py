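"""Sweep image quality and watch classification and intervals degrade.

Simulates stacks at four emitter magnitudes over three backgrounds, trains
on the first background only, and reports per-level AUROC and count-interval
width on the held-out backgrounds.
"""

import pandas as pd

import spotcount as sc

base = sc.SimulationConfig(shape=(15, 160, 160), n_spots=40)
table = sc.quality_sweep(
    [8000, 4000, 2400, 1600],
    base,
    background_seeds=(1, 2, 3),
    n_trees=150,
    seed=2,
)

ok = table[table["status"] == "ok"]
summary = (
    ok.groupby("magnitude")
    .agg(
        signal_intensity=("signal_intensity", "mean"),
        auroc=("auroc", "mean"),
        ci_width=("ci_width", "mean"),
        missed=("fn", "sum"),
    )
    .sort_index(ascending=False)
)
pd.set_option("display.float_format", lambda v: f"{v:0.3f}")
print(summary)
print()
print("As emitter magnitude (hence signal intensity) falls, classification")
print("gets harder (AUROC down) and the count interval widens: the interval")
print("width doubles as a built-in image-quality readout.")
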
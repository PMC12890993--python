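"""Run the end-to-end experiment at a small raster scale.

Simulates three slides per condition (A-D + blank control), quantifies
them through oracle masks, simulates the replicate morphine measurements,
and writes the report tables under ./scratch_experiment/.
"""

import pandas as pd

from partiquant import validate_config
from partiquant.pipeline import run_experiment

config = validate_config({})
config.slide_size_px = (384, 384)
config.mpp = 2.0
config.seed = 11

manifest = run_experiment(config, "scratch_experiment")
print("stage status:", {k: v.get("status") for k, v in manifest.stages.items() if "status" in v})

densities = pd.read_csv("scratch_experiment/densities.csv")
mean_density = densities.pivot_table(
    index="condition", columns="bin", values="density_per_mm2", aggfunc="mean"
)
print("\nmean particle density (per mm^2 valid fluid):")
print(mean_density.round(2))
print("\nrecovery table (mg, % of 45 mg label content):")
print(pd.read_csv("scratch_experiment/recovery.csv").to_string(index=False))
print("\nthe blank row should be ~zero in every bin; A peaks in <100 um,")
print("B in >500 um, C in the mid bins, and D is sparsest overall.")
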
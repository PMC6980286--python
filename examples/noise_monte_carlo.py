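"""Monte-Carlo noise analysis: does q-sparse projection bias the fits?

Adds concentration-domain Gaussian noise (sigma = 0.005 mM) to Patlak
profiles over a small parameter grid and compares the bias of fitting
the raw noisy profiles against fitting their q-sparse dictionary
projections.  With q = 2 (matching the model's two degrees of freedom)
the projection is statistically transparent; q = 1 introduces a clear
systematic bias.
"""

import numpy as np

from tkdce import (
    NoiseSpec,
    ParamGrid,
    TimeGrid,
    build_library,
    ksvd_learn,
    mc_bias_uncertainty,
    parker_aif,
)

grid = TimeGrid(n_frames=50, dt=5.0)
aif = parker_aif(grid)
library = build_library("patlak", ParamGrid.patlak_default(), aif, grid)
dictionary, _ = ksvd_learn(library, r=100, q=2, n_iters=10, seed=0)

kt_vals = np.array([0.1, 0.3, 0.6])
vp_vals = np.array([0.05, 0.2, 0.5])
noise = NoiseSpec(sigma=0.005, n_realizations=200, seed=7)

raw = mc_bias_uncertainty("patlak", kt_vals, vp_vals, aif, grid, noise, pipeline="raw")
print("raw noisy profiles:      max |ktrans bias| = "
      f"{np.abs(raw.bias_ktrans).max():.2e} min^-1, "
      f"median uncertainty = {np.median(raw.std_ktrans):.2e}")
for q in (2, 1):
    proj = mc_bias_uncertainty(
        "patlak", kt_vals, vp_vals, aif, grid, noise,
        pipeline="q_sparse", q=q, dictionary=dictionary,
    )
    excess = np.abs(proj.bias_ktrans - raw.bias_ktrans).max()
    print(f"q = {q} sparse projection: max excess |ktrans bias| = {excess:.2e} min^-1")
print("q = 2 adds no bias beyond Monte-Carlo noise; q = 1 is systematically biased.")
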
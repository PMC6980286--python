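"""Under-sampled reconstruction of a synthetic brain-tumor phantom.

Builds a small digital reference object, simulates a 6-coil acquisition
with 20-fold golden-angle Cartesian under-sampling at SNR 30, runs the
dictionary-constrained multiscale reconstruction, and reports tumor-ROI
errors of the recovered concentration profiles and ktrans map.
"""

import numpy as np

from tkdce import (
    KTData,
    ParamGrid,
    ReconConfig,
    SPGRConstants,
    TimeGrid,
    add_noise,
    apply_forward,
    bland_altman,
    build_dro,
    build_library,
    etk_fit,
    gocart_mask,
    ksvd_learn,
    nrmse,
    parker_aif,
    reconstruct_dictionary,
    synthetic_coil_maps,
)

grid = TimeGrid(n_frames=50, dt=5.0)
aif = parker_aif(grid)
spgr = SPGRConstants()

# temporal dictionary from a grid-subsampled ETK library (desk scale)
train = build_library("etk", ParamGrid.etk_default().strided(4), aif, grid)
dictionary, _ = ksvd_learn(train, r=100, q=3, n_iters=30, seed=0)

dro = build_dro(aif, shape=(64, 64), seed=0)
coils = synthetic_coil_maps((64, 64), n_coils=6)
full = gocart_mask((64, 64), grid.n_frames, R=1, seed=0)
kt = add_noise(apply_forward(dro.conc, dro.tissue, coils, full, spgr), snr=30.0, seed=2)

# retrospective 20-fold under-sampling
mask20 = gocart_mask((64, 64), grid.n_frames, R=20, seed=1)
kt20 = KTData(b=kt.b * mask20.mask[None], mask=mask20, noise_sigma=kt.noise_sigma)
print(f"sampled fraction per frame: {mask20.mask[1].mean():.3f} (frame 0 fully sampled)")

res = reconstruct_dictionary(
    kt20, dro.tissue, coils, ReconConfig(dictionary=dictionary, q=3), k=spgr
)
rim = dro.roi_masks["tumor_rim"]
print(f"reconstruction: {res.n_iters} iterations, "
      f"tumor-rim concentration nRMSE {nrmse(res.C, dro.conc, roi=rim):.1f}%")

ktrans = np.array(
    [etk_fit(res.C[iy, ix], aif, grid).params.ktrans for iy, ix in np.argwhere(rim)]
)
ba = bland_altman(ktrans, dro.ktrans_map[rim])
print(f"tumor ktrans: bias {ba.mu:+.4f} min^-1, "
      f"limits of agreement [{ba.loa[0]:+.4f}, {ba.loa[1]:+.4f}]")
print("(ground-truth rim ktrans spans "
      f"{dro.ktrans_map[rim].min():.3f}-{dro.ktrans_map[rim].max():.3f} min^-1)")
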
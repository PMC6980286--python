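"""Shared fixtures: time grid, population AIF, libraries, dictionaries,
and a desk-scale digital reference object with simulated acquisitions.

Expensive artifacts (k-SVD dictionaries, the DRO, k-t data) are session
scoped; everything is generated programmatically with fixed seeds.
"""

import numpy as np
import pytest

from tkdce import (
    KTData,
    ParamGrid,
    SPGRConstants,
    TimeGrid,
    add_noise,
    apply_forward,
    build_dro,
    build_library,
    gocart_mask,
    ksvd_learn,
    parker_aif,
    synthetic_coil_maps,
)


@pytest.fixture(scope="session")
def grid():
    return TimeGrid(n_frames=50, dt=5.0)


@pytest.fixture(scope="session")
def aif(grid):
    return parker_aif(grid, bolus_arrival=10.0, hct=0.4)


@pytest.fixture(scope="session")
def patlak_library(grid, aif):
    return build_library("patlak", ParamGrid.patlak_default(), aif, grid)


@pytest.fixture(scope="session")
def patlak_dictionary(patlak_library):
    dct, _ = ksvd_learn(patlak_library, r=100, q=2, n_iters=10, seed=0)
    return dct


@pytest.fixture(scope="session")
def etk_dictionary_coarse(grid, aif):
    """ETK dictionary trained on a 4x-strided grid (desk scale)."""
    lib = build_library("etk", ParamGrid.etk_default().strided(4), aif, grid)
    dct, _ = ksvd_learn(lib, r=100, q=3, n_iters=30, seed=0)
    return dct


@pytest.fixture(scope="session")
def etk_dictionary_stride2(grid, aif):
    """ETK dictionary trained on the 2x-strided grid."""
    lib = build_library("etk", ParamGrid.etk_default().strided(2), aif, grid)
    dct, _ = ksvd_learn(lib, r=100, q=3, n_iters=30, seed=0)
    return dct


@pytest.fixture(scope="session")
def spgr():
    return SPGRConstants()


@pytest.fixture(scope="session")
def dro64(aif):
    return build_dro(aif, shape=(64, 64), seed=0)


@pytest.fixture(scope="session")
def coils64():
    return synthetic_coil_maps((64, 64), n_coils=6)


@pytest.fixture(scope="session")
def kt_full_noisy(dro64, coils64, spgr, grid):
    """Fully sampled noisy acquisition (SNR 30) of the DRO."""
    mask = gocart_mask((64, 64), grid.n_frames, 1, seed=0)
    kt = apply_forward(dro64.conc, dro64.tissue, coils64, mask, spgr)
    return add_noise(kt, 30.0, seed=2)


@pytest.fixture(scope="session")
def kt_r20(kt_full_noisy, grid):
    """Retrospective 20-fold under-sampling of the noisy acquisition."""
    mask = gocart_mask((64, 64), grid.n_frames, 20, seed=1)
    return KTData(
        b=kt_full_noisy.b * mask.mask[None],
        mask=mask,
        noise_sigma=kt_full_noisy.noise_sigma,
    )


@pytest.fixture(scope="session")
def reference_conc(kt_full_noisy, dro64, coils64, spgr):
    """Fully sampled inverse-Fourier reference concentration series."""
    from tkdce.acquisition import adjoint_linear
    from tkdce.signal_model import signal_to_conc

    S = np.real(adjoint_linear(kt_full_noisy.b, coils64, kt_full_noisy.mask))
    C, _ = signal_to_conc(np.maximum(S, 0.0), dro64.tissue, spgr)
    return C
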
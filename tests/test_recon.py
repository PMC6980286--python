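"""Multiscale dictionary-constrained reconstruction and the tFD baseline."""

import numpy as np
import pytest

from tkdce import (
    ReconConfig,
    TFDConfig,
    apply_forward,
    build_dro,
    gaussian_kspace_filter,
    gocart_mask,
    reconstruct_dictionary,
    reconstruct_tfd,
    synthetic_coil_maps,
    tune_tfd_lambda,
)
from tkdce.acquisition import KTData, adjoint_linear, fft2c, ifft2c
from tkdce.recon import MultiscaleSchedule


@pytest.fixture(scope="module")
def small_scene(aif, spgr, grid):
    dro = build_dro(aif, shape=(32, 32), seed=1)
    coils = synthetic_coil_maps((32, 32), 4)
    mask = gocart_mask((32, 32), grid.n_frames, 4, seed=0)
    kt = apply_forward(dro.conc, dro.tissue, coils, mask, spgr)
    return dro, coils, kt


class TestGaussianFilter:
    def test_dc_weight_is_one(self):
        k = np.zeros((1, 16, 16))
        k[0, 8, 8] = 1.0
        for pct in (0.1, 1.0, 50.0, 100.0):
            assert gaussian_kspace_filter(k, pct)[0, 8, 8] == 1.0

    def test_weights_monotone_in_radius(self):
        k = np.ones((16, 16))
        w = gaussian_kspace_filter(k, 20.0)
        r = np.hypot(*np.meshgrid(np.arange(16) - 8, np.arange(16) - 8, indexing="ij"))
        order = np.argsort(r.ravel())
        # weight never increases as radius grows (ties allowed)
        ws = w.ravel()[order]
        rs = r.ravel()[order]
        for i in range(1, len(ws)):
            if rs[i] > rs[i - 1]:
                assert ws[i] <= ws[i - 1] + 1e-15

    def test_full_width_keeps_sampled_frequencies_above_half_exp(self):
        k = np.ones((16, 16))
        w = gaussian_kspace_filter(k, 100.0)
        # on-axis frequencies up to kmax keep weight >= e^{-1/2}
        assert w[8, :].min() >= np.exp(-0.5) - 1e-12
        assert w[:, 8].min() >= np.exp(-0.5) - 1e-12

    def test_tiny_width_acts_like_spatial_mean(self, small_scene):
        dro, _, _ = small_scene
        frame = dro.tissue.s0
        k = fft2c(frame[None])
        low = np.real(ifft2c(gaussian_kspace_filter(k, 0.1)))[0]
        mean_img = np.full_like(frame, frame.mean())
        corr = np.corrcoef(low.ravel() + 1e-18, mean_img.ravel() + 1e-18)
        # the filtered image is spatially flat at the global mean level
        assert np.abs(low - low.mean()).max() <= 1e-3 * abs(frame.mean())
        assert abs(low.mean() - frame.mean()) <= 1e-6 * abs(frame.mean())

    def test_invalid_width_raises(self):
        with pytest.raises(ValueError):
            gaussian_kspace_filter(np.ones((4, 4)), 0.0)


class TestDictionaryRecon:
    def test_output_is_exactly_q_sparse_combination(
        self, small_scene, etk_dictionary_coarse, spgr
    ):
        dro, coils, kt = small_scene
        cfg = ReconConfig(dictionary=etk_dictionary_coarse, q=3, max_iters=20)
        res = reconstruct_dictionary(kt, dro.tissue, coils, cfg, k=spgr)
        assert res.codes.max_row_nnz() <= 3
        UV = (res.codes.U @ etk_dictionary_coarse.V).reshape(res.C.shape)
        assert np.array_equal(res.C, UV)

    def test_hard_data_consistency_enforcement(self, small_scene):
        # the data-consistency step replaces sampled entries with b exactly
        dro, coils, kt = small_scene
        rng = np.random.default_rng(0)
        kc = rng.standard_normal(kt.b.shape) + 1j * rng.standard_normal(kt.b.shape)
        enforced = np.where(kt.mask.mask[None], kt.b, kc)
        assert np.array_equal(enforced[:, kt.mask.mask], kt.b[:, kt.mask.mask])
        assert np.array_equal(enforced[:, ~kt.mask.mask], kc[:, ~kt.mask.mask])

    def test_level_progression_and_cost_trace(
        self, small_scene, etk_dictionary_coarse, spgr
    ):
        dro, coils, kt = small_scene
        cfg = ReconConfig(dictionary=etk_dictionary_coarse, q=3, max_iters=60)
        res = reconstruct_dictionary(kt, dro.tissue, coils, cfg, k=spgr)
        assert res.cost_trace.shape == (res.n_iters,)
        assert len(res.level_change_iters) == len(cfg.schedule.k_sigma_levels) - 1
        # within each level the tracked relative change fell below the level
        # threshold (or the per-level budget elapsed) before advancing
        bounds = [0, *res.level_change_iters]
        for lo, hi in zip(bounds, bounds[1:]):
            assert (
                res.rel_change_trace[hi - 1] < cfg.level_tol
                or hi - lo >= cfg.schedule.iters_per_level
            )

    def test_time_axis_mismatch_raises(self, small_scene, etk_dictionary_coarse, spgr):
        dro, coils, kt = small_scene
        from tkdce.dictionary import Dictionary

        bad = Dictionary(V=etk_dictionary_coarse.V[:, :40], source_model="etk", q_recommended=3)
        with pytest.raises(ValueError):
            reconstruct_dictionary(
                kt, dro.tissue, coils, ReconConfig(dictionary=bad, q=3), k=spgr
            )

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            MultiscaleSchedule(k_sigma_levels=(10.0, 5.0, 100.0))


class TestTFDRecon:
    def test_lambda_zero_full_sampling_matches_zero_filled(
        self, aif, spgr, grid
    ):
        dro = build_dro(aif, shape=(24, 24), seed=2)
        coils = synthetic_coil_maps((24, 24), 3)
        full = gocart_mask((24, 24), grid.n_frames, 1, seed=0)
        kt = apply_forward(dro.conc, dro.tissue, coils, full, spgr)
        C, info = reconstruct_tfd(
            kt, dro.tissue, coils, TFDConfig(lam=0.0, max_iters=200, tol=1e-12), k=spgr
        )
        # with lambda = 0 and full sampling the solution is the direct
        # inverse-transform reconstruction
        S_ref = np.real(adjoint_linear(kt.b, coils, full))
        from tkdce.signal_model import signal_to_conc

        C_ref, _ = signal_to_conc(np.maximum(S_ref, 0.0), dro.tissue, spgr)
        denom = max(np.abs(C_ref).max(), 1e-12)
        assert np.abs(C - C_ref).max() / denom <= 1e-6

    def test_large_lambda_flattens_time(self, small_scene, spgr):
        dro, coils, kt = small_scene
        C, _ = reconstruct_tfd(
            kt, dro.tissue, coils, TFDConfig(lam=1e3, max_iters=60), k=spgr
        )
        sup = dro.tissue.support
        var_t = C[sup].std(axis=-1)
        clean_var = dro.conc[sup].std(axis=-1)
        assert var_t.max() <= 0.05 * max(clean_var.max(), 1e-12)

    def test_primal_residuals_shrink(self, small_scene, spgr):
        dro, coils, kt = small_scene
        C, info = reconstruct_tfd(
            kt, dro.tissue, coils, TFDConfig(lam=1e-3, max_iters=80), k=spgr
        )
        assert info["rel_change_trace"][-1] < info["rel_change_trace"][0]
        assert np.isfinite(info["primal_residual_v"])
        assert info["primal_residual_z"] < 1.0


class TestTuneLambda:
    def test_single_element_grid(self, small_scene, dro64, spgr):
        dro, coils, kt = small_scene
        lam, errs = tune_tfd_lambda(
            kt,
            dro.tissue,
            coils,
            dro.conc,
            dro.roi_masks["tumor_rim"],
            [2e-3],
            k=spgr,
            base_cfg=TFDConfig(max_iters=30),
        )
        assert lam == 2e-3 and errs.shape == (1,)

    def test_returns_grid_argmin(self, small_scene, spgr):
        dro, coils, kt = small_scene
        lambdas = [1e-4, 2e-3, 5e-2]
        lam, errs = tune_tfd_lambda(
            kt,
            dro.tissue,
            coils,
            dro.conc,
            dro.roi_masks["tumor_rim"],
            lambdas,
            k=spgr,
            base_cfg=TFDConfig(max_iters=40),
        )
        assert lam == lambdas[int(np.argmin(errs))]
        assert errs[lambdas.index(lam)] <= errs.min() + 1e-12

    def test_empty_grid_raises(self, small_scene, spgr):
        dro, coils, kt = small_scene
        with pytest.raises(ValueError):
            tune_tfd_lambda(
                kt, dro.tissue, coils, dro.conc, dro.roi_masks["tumor_rim"], [], k=spgr
            )
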
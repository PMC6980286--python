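"""Kinetic models: Parker AIF, Patlak/ETK forwards and their inverses."""

import numpy as np
import pytest

from tkdce import TimeGrid, aif_from_plasma, parker_aif
from tkdce.kinetics import (
    InvalidParameterError,
    ParkerParams,
    SingularDesignError,
    TKParams,
    _parker_cb,
    etk_fit,
    etk_forward,
    patlak_fit,
    patlak_forward,
)


@pytest.fixture(scope="module")
def box_aif(grid):
    """Boxcar plasma input, Cp = 1 mM over the whole scan."""
    return aif_from_plasma(lambda t: np.ones_like(t), grid, hct=0.4)


class TestParkerAIF:
    def test_pre_bolus_baseline_is_zero(self, grid):
        aif = parker_aif(grid, bolus_arrival=10.0)
        pre = aif.cb_fine[aif.t_fine < 10.0]
        assert np.all(np.abs(pre) < 1e-6)

    def test_plasma_is_blood_over_one_minus_hct(self, grid):
        aif = parker_aif(grid, hct=0.4)
        assert np.allclose(aif.cp, aif.cb / 0.6, rtol=0, atol=1e-14)

    def test_peak_matches_fine_grid_evaluation(self):
        # peak of the sampled curve vs direct evaluation on a 10x finer grid
        grid = TimeGrid(n_frames=2500, dt=0.1)
        aif = parker_aif(grid, bolus_arrival=10.0)
        t_ref = np.arange(0, 250, 0.01)
        cb_ref = _parker_cb(t_ref, 10.0, ParkerParams())
        assert abs(aif.cb.max() - cb_ref.max()) / cb_ref.max() < 0.005
        assert abs(grid.t[np.argmax(aif.cb)] - t_ref[np.argmax(cb_ref)]) < 0.1

    def test_invalid_hct_raises(self, grid):
        with pytest.raises(InvalidParameterError):
            parker_aif(grid, hct=1.0)

    def test_invalid_arrival_raises(self, grid):
        with pytest.raises(InvalidParameterError):
            parker_aif(grid, bolus_arrival=grid.total_time + 1)

    def test_nonnegative(self, grid):
        aif = parker_aif(grid)
        assert np.all(aif.cb_fine >= -1e-12)


class TestPatlakForward:
    def test_zero_params_zero_profile(self, aif, grid):
        assert np.all(patlak_forward(TKParams(0.0, 0.0), aif, grid) == 0)

    def test_vp_only_scales_cp(self, aif, grid):
        c = patlak_forward(TKParams(0.0, 0.1), aif, grid)
        assert np.allclose(c, 0.1 * aif.cp, atol=1e-15)

    def test_boxcar_closed_form(self, box_aif, grid):
        c = patlak_forward(TKParams(0.1, 0.05), box_aif, grid)
        expected = 0.1 * grid.t / 60.0 + 0.05
        assert np.abs(c - expected).max() < 1e-12

    def test_linearity_in_parameters(self, aif, grid):
        c1 = patlak_forward(TKParams(0.3, 0.1), aif, grid)
        c2 = patlak_forward(TKParams(0.1, 0.4), aif, grid)
        mix = patlak_forward(TKParams(0.5 * 0.3 + 0.1, 0.5 * 0.1 + 0.4), aif, grid)
        assert np.allclose(mix, 0.5 * c1 + c2, atol=1e-12)

    def test_negative_params_raise(self, aif, grid):
        with pytest.raises(InvalidParameterError):
            patlak_forward(TKParams(-0.1, 0.05), aif, grid)


class TestETKForward:
    def test_ktrans_zero_reduces_to_vp_cp(self, aif, grid):
        c = etk_forward(TKParams(0.0, 0.3, 0.6), aif, grid)
        assert np.allclose(c, 0.3 * aif.cp, atol=1e-15)

    def test_ve_zero_limit_convention(self, aif, grid):
        c = etk_forward(TKParams(0.2, 0.3, 0.0), aif, grid)
        assert np.allclose(c, 0.3 * aif.cp, atol=1e-15)

    def test_boxcar_closed_form(self, grid, box_aif):
        p = TKParams(0.2, 0.1, 0.4)
        c = etk_forward(p, box_aif, grid)
        expected = 0.1 + 0.4 * (1 - np.exp(-0.2 * grid.t / (60 * 0.4)))
        assert np.abs(c - expected).max() / expected.max() < 1e-3

    def test_approaches_patlak_for_large_ve(self, aif, grid):
        # backflux vanishes as ktrans/ve -> 0, uniformly over the scan
        pat = patlak_forward(TKParams(0.05, 0.1), aif, grid)
        diffs = [
            np.abs(etk_forward(TKParams(0.05, 0.1, ve), aif, grid) - pat).max()
            for ve in (0.5, 0.9, 0.99)
        ]
        assert diffs[2] < diffs[1] < diffs[0]
        assert diffs[2] < 0.05 * np.abs(pat).max()

    def test_nonnegative_output(self, aif, grid):
        for p in [TKParams(0.8, 0.6, 0.01), TKParams(0.01, 0.0, 1.0)]:
            assert np.all(etk_forward(p, aif, grid) >= -1e-12)


class TestPatlakFit:
    def test_round_trip_exact(self, aif, grid):
        fit = patlak_fit(patlak_forward(TKParams(0.12, 0.04), aif, grid), aif, grid)
        assert abs(fit.params.ktrans - 0.12) < 1e-10
        assert abs(fit.params.vp - 0.04) < 1e-10
        assert fit.converged

    def test_round_trip_over_grid(self, aif, grid):
        for kt in (0.0, 0.01, 0.4, 0.8):
            for vp in (0.0, 0.05, 0.6):
                fit = patlak_fit(patlak_forward(TKParams(kt, vp), aif, grid), aif, grid)
                assert abs(fit.params.ktrans - kt) <= 1e-10 * max(kt, 1)
                assert abs(fit.params.vp - vp) <= 1e-10 * max(vp, 1)

    def test_zero_profile(self, aif, grid):
        fit = patlak_fit(np.zeros(grid.n_frames), aif, grid)
        assert fit.params.ktrans == 0 and fit.params.vp == 0
        assert fit.residual_norm == 0

    def test_zero_aif_raises(self, grid):
        dead = aif_from_plasma(lambda t: np.zeros_like(t), grid)
        with pytest.raises(SingularDesignError):
            patlak_fit(np.zeros(grid.n_frames), dead, grid)

    def test_monte_carlo_unbiased(self, aif, grid):
        # 500 noisy replicates, sigma = 0.005 mM: mean estimate within 3 SE
        rng = np.random.default_rng(42)
        clean = patlak_forward(TKParams(0.1, 0.05), aif, grid)
        ests = np.array(
            [
                [
                    (f := patlak_fit(clean + 0.005 * rng.standard_normal(50), aif, grid))
                    .params.ktrans,
                    f.params.vp,
                ]
                for _ in range(500)
            ]
        )
        se = ests.std(axis=0) / np.sqrt(500)
        assert abs(ests[:, 0].mean() - 0.1) < 3 * se[0]
        assert abs(ests[:, 1].mean() - 0.05) < 3 * se[1]


class TestETKFit:
    @pytest.mark.parametrize(
        "p",
        [
            TKParams(0.2, 0.05, 0.4),
            TKParams(0.01, 0.01, 0.1),
            TKParams(0.8, 0.3, 0.9),
        ],
    )
    def test_noiseless_round_trip(self, aif, grid, p):
        fit = etk_fit(etk_forward(p, aif, grid), aif, grid)
        assert fit.converged
        assert abs(fit.params.ktrans - p.ktrans) / p.ktrans < 1e-3
        assert abs(fit.params.vp - p.vp) / p.vp < 1e-3
        assert abs(fit.params.ve - p.ve) / p.ve < 1e-3

    def test_degenerate_ktrans_zero_flags_ve(self, aif, grid):
        fit = etk_fit(0.07 * aif.cp, aif, grid)
        assert fit.params.ktrans < 1e-4
        assert abs(fit.params.vp - 0.07) < 1e-3
        assert "ve_unidentifiable" in fit.identifiability_flags

    def test_reproducible_under_fixed_seed(self, aif, grid):
        clean = etk_forward(TKParams(0.3, 0.08, 0.6), aif, grid)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            noisy = clean + 0.005 * rng.standard_normal(grid.n_frames)
            f = etk_fit(noisy, aif, grid)
            outs.append((f.params.ktrans, f.params.vp, f.params.ve))
        assert outs[0] == outs[1]
        assert np.all(np.isfinite(outs[0]))
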
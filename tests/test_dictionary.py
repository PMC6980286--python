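"""Library generation, k-SVD learning and OMP sparse projection."""

import itertools

import numpy as np
import pytest

from tkdce import (
    Dictionary,
    ParamGrid,
    TimeGrid,
    approximation_errors,
    build_library,
    ksvd_learn,
    omp_project,
)
from tkdce.dictionary import Library, _omp_batch
from tkdce.kinetics import TKParams, etk_forward, patlak_forward


def brute_force_best_subset(z, V, q):
    """Exhaustive best-q-subset least squares residual norm (oracle)."""
    best = np.linalg.norm(z)
    for subset in itertools.combinations(range(V.shape[0]), q):
        A = V[list(subset)].T
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        best = min(best, np.linalg.norm(z - A @ coef))
    return best


class TestBuildLibrary:
    def test_patlak_default_count(self, patlak_library, grid):
        assert patlak_library.Z.shape == (4941, grid.n_frames)
        assert patlak_library.params.shape == (4941, 3)

    def test_zero_row_for_zero_params(self, patlak_library):
        i = np.flatnonzero(
            (patlak_library.params[:, 0] == 0) & (patlak_library.params[:, 1] == 0)
        )[0]
        assert np.all(patlak_library.Z[i] == 0)

    def test_rows_reproduce_forward_models(self, aif, grid):
        pgrid = ParamGrid(ktrans=(0.0, 0.2, 0.1), vp=(0.0, 0.2, 0.1), ve=(0.3, 0.7))
        lib = build_library("etk", pgrid, aif, grid)
        assert lib.l == 3 * 3 * 2
        rng = np.random.default_rng(0)
        for i in rng.choice(lib.l, size=5, replace=False):
            p = lib.row_params(int(i))
            assert np.allclose(lib.Z[i], etk_forward(p, aif, grid), atol=1e-12)
        plib = build_library("patlak", ParamGrid(ktrans=(0.0, 0.2, 0.1), vp=(0.0, 0.2, 0.1)), aif, grid)
        for i in range(plib.l):
            assert np.allclose(
                plib.Z[i], patlak_forward(plib.row_params(i), aif, grid), atol=1e-12
            )

    def test_patlak_library_has_rank_two(self, patlak_library):
        s = np.linalg.svd(patlak_library.Z, compute_uv=False)
        assert s[2] / s[0] <= 1e-12

    def test_empty_grid_raises(self, aif, grid):
        with pytest.raises(ValueError):
            build_library("etk", ParamGrid(ve=()), aif, grid)

    def test_strided_counts(self):
        g = ParamGrid.etk_default()
        assert g.n_combinations == 494100
        g2 = g.strided(2)
        assert g2.n_combinations == 41 * 31 * 50


class TestKSVD:
    def test_recovers_rank_two_subspace(self, grid):
        rng = np.random.default_rng(3)
        u = np.linalg.qr(rng.standard_normal((50, 2)))[0].T
        Z = rng.uniform(0.1, 1.0, size=(400, 2)) @ u
        lib = Library(
            Z=Z, grid=ParamGrid(), params=np.zeros((400, 3)), time=grid, model="patlak"
        )
        dct, codes = ksvd_learn(lib, r=10, q=2, n_iters=10, seed=0)
        approx = codes.U @ dct.V
        rel = np.sum((Z - approx) ** 2, axis=1) / np.sum(Z**2, axis=1)
        assert rel.max() <= 1e-20

    def test_atoms_unit_norm(self, patlak_dictionary):
        norms = np.linalg.norm(patlak_dictionary.V, axis=1)
        assert np.abs(norms - 1).max() <= 1e-12

    def test_objective_decreases_overall(self, patlak_dictionary, etk_dictionary_coarse):
        # greedy OMP re-coding makes k-SVD only approximately monotone:
        # the objective must fall substantially overall and never jump
        # by more than a small fraction between iterations
        etk_obj = np.asarray(etk_dictionary_coarse.training_objective)
        assert etk_obj[-1] <= 0.5 * etk_obj[0]
        # atom recycling can bump individual iterations; no large jumps
        assert np.all(np.diff(etk_obj) <= 0.25 * etk_obj[:-1])
        # the Patlak library is rank 2, so the objective starts at the
        # machine-precision floor and must stay there
        pat_obj = np.asarray(patlak_dictionary.training_objective)
        assert pat_obj[-1] <= 1.1 * pat_obj[0] + 1e-30

    def test_deterministic_for_fixed_seed(self, patlak_library):
        d1, c1 = ksvd_learn(patlak_library, r=20, q=2, n_iters=3, seed=5)
        d2, c2 = ksvd_learn(patlak_library, r=20, q=2, n_iters=3, seed=5)
        assert np.array_equal(d1.V, d2.V)
        assert (c1.U != c2.U).nnz == 0

    def test_q_larger_than_r_raises(self, patlak_library):
        with pytest.raises(ValueError):
            ksvd_learn(patlak_library, r=5, q=6, n_iters=1, seed=0)


class TestOMP:
    def test_single_atom_signal(self, patlak_dictionary):
        z = 3.7 * patlak_dictionary.V[13]
        codes, approx = omp_project(z, patlak_dictionary, q=2)
        row = codes.U.getrow(0)
        assert row.indices.tolist() == [13]
        assert abs(row.data[0] - 3.7) < 1e-10
        assert np.abs(approx[0] - z).max() < 1e-10

    def test_zero_profile_zero_code(self, patlak_dictionary):
        codes, approx = omp_project(np.zeros(50), patlak_dictionary, q=2)
        assert codes.U.nnz == 0
        assert np.all(approx == 0)

    def test_residual_orthogonal_to_selected_atoms(self, patlak_dictionary, patlak_library):
        Z = patlak_library.Z[::500]
        codes, approx = omp_project(Z, patlak_dictionary, q=2)
        resid = Z - approx
        for i in range(Z.shape[0]):
            for j in codes.U.getrow(i).indices:
                assert abs(resid[i] @ patlak_dictionary.V[j]) <= 1e-10

    def test_matches_exhaustive_best_subset_small(self):
        rng = np.random.default_rng(17)
        base = np.linalg.qr(rng.standard_normal((8, 8)))[0][:, :5].T
        V = base + 1e-3 * rng.standard_normal(base.shape)
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        dct = Dictionary(V=V, source_model="patlak", q_recommended=2)
        for _ in range(20):
            z = rng.standard_normal(8)
            _, approx = omp_project(z, dct, q=2)
            omp_res = np.linalg.norm(z - approx[0])
            assert abs(omp_res - brute_force_best_subset(z, V, 2)) <= 1e-10

    def test_residual_non_increasing_in_q(self, patlak_dictionary, patlak_library):
        Z = patlak_library.Z[::700]
        prev = None
        for q in (1, 2, 3):
            _, approx = omp_project(Z, patlak_dictionary, q)
            res = np.linalg.norm(Z - approx, axis=1)
            if prev is not None:
                assert np.all(res <= prev + 1e-12)
            prev = res


class TestApproximationErrors:
    def test_exact_combinations_have_zero_error(self, grid):
        rng = np.random.default_rng(1)
        V = np.linalg.qr(rng.standard_normal((50, 6)))[0].T
        dct = Dictionary(V=V, source_model="etk", q_recommended=2)
        coef = rng.standard_normal((30, 2))
        atoms = rng.integers(0, 6, size=(30, 2))
        Z = coef[:, :1] * V[atoms[:, 0]] + coef[:, 1:] * V[atoms[:, 1]]
        lib = Library(
            Z=Z, grid=ParamGrid(), params=np.zeros((30, 3)), time=grid, model="etk"
        )
        stats = approximation_errors(lib, dct, q=2)
        assert stats.max_err <= 1e-24

    def test_zero_rows_excluded_and_counted(self, patlak_library, patlak_dictionary):
        stats = approximation_errors(patlak_library, patlak_dictionary, q=2)
        assert stats.n_excluded_zero_rows == 1
        assert stats.per_row.size == patlak_library.l - 1
        assert 0 <= stats.mu_err <= stats.max_err

    def test_patlak_q1_much_worse_than_q2(self, patlak_library, patlak_dictionary):
        q1 = approximation_errors(patlak_library, patlak_dictionary, q=1)
        q2 = approximation_errors(patlak_library, patlak_dictionary, q=2)
        assert q1.max_err > 0.01  # well above machine precision: real bias
        assert q2.max_err < 1e-20
        assert q1.mu_err >= q2.mu_err

    def test_errors_monotone_in_q(self, patlak_library, patlak_dictionary):
        stats = [
            approximation_errors(patlak_library, patlak_dictionary, q=q)
            for q in (1, 2, 3)
        ]
        for a, b in zip(stats, stats[1:]):
            assert b.mu_err <= a.mu_err + 1e-12
            assert b.max_err <= a.max_err + 1e-12
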
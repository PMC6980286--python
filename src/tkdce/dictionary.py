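"""Kinetic-model libraries and learned temporal dictionaries.

A *library* is the matrix Z (l x N) of concentration-vs-time profiles
generated by evaluating a kinetic model over a uniform grid of
parameters.  k-SVD reduces the library to a small *dictionary* V
(r x N) of temporal basis functions such that every profile is well
approximated by a q-sparse linear combination of atoms; orthogonal
matching pursuit (OMP) computes those sparse codes.

Approximation errors are reported per profile as the normalized squared
residual in percent, 100 * ||z - z_qsp||^2 / ||z||^2; zero-norm rows
are excluded (and counted) since the normalization is undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .kinetics import AIFCurve, TimeGrid, TKParams, patlak_design_matrix, _exp_conv_fine

__all__ = [
    "ParamGrid",
    "Library",
    "Dictionary",
    "SparseCodes",
    "ApproxErrorStats",
    "build_library",
    "ksvd_learn",
    "omp_project",
    "approximation_errors",
]

# Early-stop threshold for OMP: once the (recursively tracked) squared
# residual falls below this fraction of the row's squared norm the row
# is treated as exactly represented and no further atoms are selected.
# The recursion ||r||^2 = ||z||^2 - c'rhs bottoms out near machine
# epsilon times ||z||^2 from cancellation, so the threshold must sit
# above that floor; below it the correlations are pure round-off and
# atom selection would be arbitrary (and can pick collinear atoms).
_OMP_REL_TOL = 1e-14


def _axis_values(start: float, stop: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("grid step must be > 0")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class ParamGrid:
    """Uniform kinetic-parameter grid.

    ``ktrans`` and ``vp`` are (start, stop, step) triples; ``ve`` is an
    explicit tuple of levels, or ``None`` for the Patlak model.  The
    defaults reproduce the standard brain-tumor ranges: ktrans 0-0.8
    min^-1 in steps of 0.01 and vp 0-60% in steps of 1% (81 x 61 = 4941
    Patlak combinations); the ETK grid adds 100 ve levels of 1%-100%.
    """

    ktrans: tuple[float, float, float] = (0.0, 0.8, 0.01)
    vp: tuple[float, float, float] = (0.0, 0.60, 0.01)
    ve: tuple[float, ...] | None = None

    @classmethod
    def patlak_default(cls) -> "ParamGrid":
        return cls()

    @classmethod
    def etk_default(cls) -> "ParamGrid":
        return cls(ve=tuple(np.round(np.arange(1, 101) * 0.01, 10)))

    @property
    def ktrans_values(self) -> np.ndarray:
        return _axis_values(*self.ktrans)

    @property
    def vp_values(self) -> np.ndarray:
        return _axis_values(*self.vp)

    @property
    def ve_values(self) -> np.ndarray | None:
        return None if self.ve is None else np.asarray(self.ve, dtype=float)

    @property
    def n_combinations(self) -> int:
        n = len(self.ktrans_values) * len(self.vp_values)
        if self.ve is not None:
            n *= len(self.ve)
        return n

    def strided(self, stride: int) -> "ParamGrid":
        """Subsampled grid taking every ``stride``-th level per axis."""
        kv = self.ktrans_values[::stride]
        vv = self.vp_values[::stride]
        ve = None if self.ve is None else tuple(self.ve[::stride])
        return ParamGrid(
            ktrans=(float(kv[0]), float(kv[-1]), self.ktrans[2] * stride),
            vp=(float(vv[0]), float(vv[-1]), self.vp[2] * stride),
            ve=ve,
        )


@dataclass(frozen=True, eq=False)
class Library:
    """Model-generated profile library Z (l x N, mM) plus its provenance.

    ``params`` holds one (ktrans, vp, ve) triple per row (ve is NaN for
    Patlak).  Row order is deterministic: ktrans slowest, then vp, then
    ve fastest.
    """

    Z: np.ndarray
    grid: ParamGrid
    params: np.ndarray
    time: TimeGrid
    model: str

    @property
    def l(self) -> int:  # noqa: E743 - field name from the domain
        return self.Z.shape[0]

    def row_params(self, i: int) -> TKParams:
        k, v, e = self.params[i]
        return TKParams(ktrans=float(k), vp=float(v), ve=None if np.isnan(e) else float(e))


@dataclass(frozen=True, eq=False)
class Dictionary:
    """Learned temporal basis V (r x N); every atom has unit l2 norm."""

    V: np.ndarray
    source_model: str
    q_recommended: int
    #: k-SVD training objective (sum of squared residuals) per iteration
    training_objective: tuple[float, ...] = ()

    @property
    def r(self) -> int:
        return self.V.shape[0]


@dataclass(frozen=True, eq=False)
class SparseCodes:
    """Row-sparse coefficient matrix U (m x r), each row <= q nonzeros."""

    U: sparse.csr_matrix
    q: int

    def max_row_nnz(self) -> int:
        return int(np.diff(self.U.indptr).max(initial=0))


@dataclass(frozen=True, eq=False)
class ApproxErrorStats:
    """Normalized q-sparse approximation errors, in percent."""

    mu_err: float
    max_err: float
    per_row: np.ndarray
    n_excluded_zero_rows: int


def build_library(
    model: str, grid: ParamGrid, aif: AIFCurve, time: TimeGrid
) -> Library:
    """Generate the concentration-profile library for a kinetic model.

    Vectorized over the parameter grid: Patlak rows are linear
    combinations of [int Cp, Cp]; ETK rows add one exponential
    convolution per (ktrans, ve) pair.
    """
    if model not in ("patlak", "etk"):
        raise ValueError(f"unknown model {model!r}")
    kt = grid.ktrans_values
    vp = grid.vp_values
    if kt.size == 0 or vp.size == 0:
        raise ValueError("empty parameter grid")
    if np.any(kt < 0) or np.any(vp < 0) or np.any(vp > 1):
        raise ValueError("grid outside the model's parameter set")
    X = patlak_design_matrix(aif, time)  # columns [int Cp (mM*min), Cp]
    n = time.n_frames
    if model == "patlak":
        if grid.ve is not None:
            raise ValueError("Patlak grid must not specify ve levels")
        Z = (kt[:, None, None] * X[:, 0] + vp[None, :, None] * X[:, 1]).reshape(-1, n)
        kk, vv = np.meshgrid(kt, vp, indexing="ij")
        params = np.column_stack(
            [kk.ravel(), vv.ravel(), np.full(kk.size, np.nan)]
        )
        return Library(Z=Z, grid=grid, params=params, time=time, model=model)

    ve = grid.ve_values
    if ve is None or ve.size == 0:
        raise ValueError("ETK grid requires ve levels")
    if np.any(ve < 0) or np.any(ve > 1):
        raise ValueError("ve levels outside [0, 1]")
    dtf = time.dt / aif.oversample
    idx = time.frame_indices(aif.oversample)
    cp = aif.cp_fine[idx]
    # Leakage term ktrans/60 * conv(kep) sampled at frames, per (ktrans, ve).
    leak = np.zeros((kt.size, ve.size, n))
    for i, k in enumerate(kt):
        if k == 0.0:
            continue
        for j, e in enumerate(ve):
            if e == 0.0:
                continue
            leak[i, j] = (k / 60.0) * _exp_conv_fine(aif.cp_fine, dtf, k / e)[idx]
    Z = (
        leak[:, None, :, :] + vp[None, :, None, None] * cp
    ).reshape(-1, n)
    kk, vv, ee = np.meshgrid(kt, vp, ve, indexing="ij")
    params = np.column_stack([kk.ravel(), vv.ravel(), ee.ravel()])
    return Library(Z=Z, grid=grid, params=params, time=time, model=model)


def _omp_batch(
    Z: np.ndarray,
    V: np.ndarray,
    q: int,
    gram: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched OMP of the rows of Z onto the atoms (rows) of V.

    Returns ``(sel, coef, res_norm2, n_sel)`` where ``sel``/``coef`` are
    (m, q) atom indices (-1 where unused) and least-squares
    coefficients, ``res_norm2`` the squared residual norms and ``n_sel``
    the number of atoms actually used per row.  Coefficients solve the
    exact least-squares problem on the selected support, so the residual
    is orthogonal to the selected atoms.  Ties in the correlation step
    break toward the lowest atom index; rows whose residual is already
    negligible (including all-zero rows) select nothing further.
    """
    m = Z.shape[0]
    r = V.shape[0]
    if q > r:
        raise ValueError("sparsity q cannot exceed the number of atoms")
    G = V @ V.T if gram is None else gram
    A0 = Z @ V.T
    norms2 = np.einsum("ij,ij->i", Z, Z)
    sel = np.full((m, q), -1, dtype=np.int64)
    coef = np.zeros((m, q))
    res2 = norms2.copy()
    n_sel = np.zeros(m, dtype=np.int64)
    active = res2 > 0.0
    corr = A0.copy()
    for j in range(q):
        if not active.any():
            break
        rows = np.nonzero(active)[0]
        # argmax returns the first (lowest-index) maximizer on ties
        idx = np.argmax(np.abs(corr[rows]), axis=1)
        sel[rows, j] = idx
        n_sel[rows] = j + 1
        s = sel[rows, : j + 1]
        Gs = G[s[:, :, None], s[:, None, :]]  # (m_act, j+1, j+1)
        rhs = np.take_along_axis(A0[rows], s, axis=1)
        try:
            c = np.linalg.solve(Gs, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            c = np.array(
                [np.linalg.lstsq(Gs[i], rhs[i], rcond=None)[0] for i in range(len(rows))]
            )
        coef[rows, : j + 1] = c
        res2[rows] = np.maximum(norms2[rows] - np.einsum("ij,ij->i", c, rhs), 0.0)
        if j + 1 < q:
            corr[rows] = A0[rows] - np.einsum("ij,ijr->ir", c, G[s])
        active[rows] = res2[rows] > _OMP_REL_TOL * norms2[rows]
    return sel, coef, res2, n_sel


def _codes_to_csr(
    sel: np.ndarray, coef: np.ndarray, n_sel: np.ndarray, r: int
) -> sparse.csr_matrix:
    m, q = sel.shape
    keep = np.arange(q)[None, :] < n_sel[:, None]
    rows = np.repeat(np.arange(m), n_sel)
    cols = sel[keep]
    data = coef[keep]
    return sparse.csr_matrix((data, (rows, cols)), shape=(m, r))


def omp_project(
    profiles: np.ndarray,
    dictionary: Dictionary,
    q: int,
    chunk: int = 20000,
) -> tuple[SparseCodes, np.ndarray]:
    """q-sparse OMP projection of profiles onto a dictionary.

    Returns the sparse codes and the approximated profiles (the
    least-squares fit on each row's selected atoms).
    """
    Z = np.atleast_2d(np.asarray(profiles, dtype=float))
    V = dictionary.V
    if q > min(V.shape[0], V.shape[1]):
        raise ValueError("q must not exceed min(r, N)")
    G = V @ V.T
    m = Z.shape[0]
    approx = np.zeros_like(Z)
    blocks = []
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        sel, coef, _, n_sel = _omp_batch(Z[lo:hi], V, q, gram=G)
        U = _codes_to_csr(sel, coef, n_sel, V.shape[0])
        approx[lo:hi] = U @ V
        blocks.append(U)
    U_all = sparse.vstack(blocks, format="csr") if blocks else sparse.csr_matrix((0, V.shape[0]))
    return SparseCodes(U=U_all, q=q), approx


def approximation_errors(
    lib: Library, dictionary: Dictionary, q: int, chunk: int = 50000
) -> ApproxErrorStats:
    """Normalized per-profile q-sparse approximation errors (percent)."""
    if lib.Z.shape[1] != dictionary.V.shape[1]:
        raise ValueError("library and dictionary time axes differ")
    V = dictionary.V
    G = V @ V.T
    per_row = []
    n_zero = 0
    for lo in range(0, lib.Z.shape[0], chunk):
        Z = lib.Z[lo : lo + chunk]
        norms2 = np.einsum("ij,ij->i", Z, Z)
        nz = norms2 > 0
        n_zero += int((~nz).sum())
        if nz.any():
            Znz = Z[nz]
            sel, coef, _, n_sel = _omp_batch(Znz, V, q, gram=G)
            # explicit residual: the norms2 - c'rhs shortcut loses the
            # machine-precision floor to cancellation
            resid = Znz - _codes_to_csr(sel, coef, n_sel, V.shape[0]) @ V
            # one step of iterative refinement of the per-support
            # least-squares coefficients
            safe_sel = np.where(sel >= 0, sel, 0)
            rhs = np.einsum("ij,ikj->ik", resid, V[safe_sel])
            Gs = G[safe_sel[:, :, None], safe_sel[:, None, :]]
            # decouple unused slots so the batched solve stays regular
            unused = sel < 0
            rhs[unused] = 0.0
            Gs[unused[:, :, None] | unused[:, None, :]] = 0.0
            diag = np.arange(sel.shape[1])
            Gs[:, diag, diag] = np.where(unused, 1.0, Gs[:, diag, diag])
            delta = np.linalg.solve(Gs, rhs[..., None])[..., 0]
            coef = coef + delta
            resid = Znz - _codes_to_csr(sel, coef, n_sel, V.shape[0]) @ V
            res2 = np.einsum("ij,ij->i", resid, resid)
            per_row.append(100.0 * res2 / norms2[nz])
    if not per_row:
        raise ValueError("all library rows are zero")
    per_row_arr = np.concatenate(per_row)
    return ApproxErrorStats(
        mu_err=float(per_row_arr.mean()),
        max_err=float(per_row_arr.max()),
        per_row=per_row_arr,
        n_excluded_zero_rows=n_zero,
    )


def _normalize_rows(V: np.ndarray) -> np.ndarray:
    return V / np.linalg.norm(V, axis=1, keepdims=True)


def ksvd_learn(
    lib: Library,
    r: int = 100,
    q: int | None = None,
    n_iters: int = 30,
    seed: int = 0,
    tol: float = 1e-10,
) -> tuple[Dictionary, SparseCodes]:
    """k-SVD dictionary learning on a profile library.

    Alternates batched OMP sparse coding with sequential rank-1 SVD atom
    updates (coefficients of the rows using each atom are refreshed
    together with the atom).  Atoms are initialized from ``r`` distinct
    non-zero library rows drawn with a seeded generator; unused or
    near-duplicate atoms are replaced by the currently worst-represented
    profile.  Zero rows are dropped before learning and re-attached with
    zero codes.  Bit-for-bit reproducible for a fixed seed.

    Returns the learned dictionary and the q-sparse codes of *all*
    library rows.
    """
    if q is None:
        q = 2 if lib.model == "patlak" else 3
    Z_all = lib.Z
    norms = np.linalg.norm(Z_all, axis=1)
    nz_idx = np.nonzero(norms > 0)[0]
    Z = Z_all[nz_idx]
    m = Z.shape[0]
    if r >= m:
        raise ValueError("r must be smaller than the number of non-zero profiles")
    if q > r:
        raise ValueError("q must not exceed r")
    rng = np.random.default_rng(seed)
    # farthest-point initialization: starting from a seeded random row,
    # greedily add the profile least correlated with the atoms chosen so
    # far.  Spreads the initial atoms over the library's geometry, which
    # makes the learned dictionary's worst-case error much less
    # sensitive to the seed than uniform row sampling.
    Zn = _normalize_rows(Z)
    init_rows = [int(rng.integers(m))]
    max_corr = np.abs(Zn @ Zn[init_rows[0]])
    for _ in range(r - 1):
        nxt = int(np.argmin(max_corr))
        init_rows.append(nxt)
        np.maximum(max_corr, np.abs(Zn @ Zn[nxt]), out=max_corr)
    V = Zn[init_rows].copy()

    objective = []
    for _ in range(n_iters):
        G = V @ V.T
        sel, coef, res2, n_sel = _omp_batch(Z, V, q, gram=G)
        objective.append(float(res2.sum()))
        approx = _codes_to_csr(sel, coef, n_sel, r) @ V
        E_res = Z - approx
        for k in range(r):
            use = np.nonzero((sel == k).any(axis=1))[0]
            if use.size == 0:
                worst = int(np.argmax(np.einsum("ij,ij->i", E_res, E_res)))
                V[k] = Z[worst] / np.linalg.norm(Z[worst])
                continue
            cols = np.argmax(sel[use] == k, axis=1)
            ck = coef[use, cols]
            Ek = E_res[use] + np.outer(ck, V[k])
            # rank-1 update via the dominant singular pair
            _, s, vt = np.linalg.svd(Ek, full_matrices=False)
            v_new = vt[0]
            if v_new[np.argmax(np.abs(v_new))] < 0:
                v_new = -v_new
            ck_new = Ek @ v_new
            V[k] = v_new
            coef[use, cols] = ck_new
            E_res[use] = Ek - np.outer(ck_new, v_new)
        # replace highly coherent (redundant) atoms with poorly
        # represented profiles
        G = V @ V.T
        np.fill_diagonal(G, 0.0)
        dup = np.nonzero(np.triu(np.abs(G) > 0.999).any(axis=0))[0]
        if dup.size:
            err = np.einsum("ij,ij->i", E_res, E_res)
            order = np.argsort(err)[::-1]
            for pos, k in enumerate(dup):
                row = Z[order[pos % m]]
                V[k] = row / np.linalg.norm(row)
        if len(objective) > 1 and objective[-2] > 0:
            if abs(objective[-1] - objective[-2]) < tol * objective[-2]:
                break
    # final coding of the full library (zero rows -> zero codes)
    dictionary = Dictionary(
        V=V,
        source_model=lib.model,
        q_recommended=q,
        training_objective=tuple(objective),
    )
    codes, _ = omp_project(Z_all, dictionary, q)
    return dictionary, codes
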
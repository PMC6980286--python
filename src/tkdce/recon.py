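"""Iterative reconstructions of under-sampled DCE-MRI.

Two reconstructions are provided:

* :func:`reconstruct_dictionary` — the kinetic-model-constrained
  approach.  Concentration profiles are constrained to q-sparse linear
  combinations of a model-derived temporal dictionary; the algorithm
  alternates hard k-space data consistency with OMP sparse projection,
  embedded in an iterative multiscale scheme that low-pass filters
  k-space with a Gaussian of growing width (0.1% to 100% of k_max) to
  avoid poor local minima of the non-convex l0-constrained objective.
  No regularization weight needs tuning: the sparsity level q is fixed
  a priori by the kinetic model (2 for Patlak, 3 for ETK).

* :func:`reconstruct_tfd` — a compressed-sensing baseline with a
  temporal finite-difference (temporal total variation) l1 penalty,
  solved by ADMM.  Its weight lambda must be tuned
  (:func:`tune_tfd_lambda`); the objective is convex, so no multiscale
  heuristic is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import CoilMaps, KTData, adjoint_linear, fft2c, ifft2c
from .dictionary import Dictionary, SparseCodes, _codes_to_csr, _omp_batch
from .signal_model import SPGRConstants, TissueMaps, conc_to_signal, signal_to_conc

__all__ = [
    "MultiscaleSchedule",
    "ReconConfig",
    "TFDConfig",
    "ReconResult",
    "gaussian_kspace_filter",
    "reconstruct_dictionary",
    "reconstruct_tfd",
    "tune_tfd_lambda",
]


@dataclass(frozen=True)
class MultiscaleSchedule:
    """Gaussian k-space filter widths in percent of k_max, visited in
    order.  The final level (100%) runs at full resolution, i.e. no
    filter is applied there, so hard data consistency is exact."""

    k_sigma_levels: tuple[float, ...] = tuple(
        float(v) for v in np.geomspace(0.1, 100.0, 15)
    )
    iters_per_level: int = 10

    def __post_init__(self) -> None:
        lv = np.asarray(self.k_sigma_levels)
        if lv.size == 0 or np.any(np.diff(lv) <= 0):
            raise ValueError("k_sigma_levels must be strictly increasing")
        if not (lv[0] >= 0.1 - 1e-9 and abs(lv[-1] - 100.0) < 1e-6):
            raise ValueError("levels must run from 0.1 to 100 percent of kmax")


@dataclass(frozen=True)
class ReconConfig:
    """Configuration of the dictionary-constrained reconstruction."""

    dictionary: Dictionary
    q: int = 3
    epsilon: float = 0.01
    max_iters: int = 150
    schedule: MultiscaleSchedule = field(default_factory=MultiscaleSchedule)
    level_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.q > self.dictionary.r:
            raise ValueError("q cannot exceed the dictionary atom count")


@dataclass(frozen=True)
class TFDConfig:
    """Configuration of the temporal-finite-difference ADMM baseline."""

    lam: float = 1e-3
    admm_rho: float = 1.0
    tol: float = 1e-7
    max_iters: int = 150

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass(frozen=True, eq=False)
class ReconResult:
    """Output of the dictionary-constrained reconstruction.

    ``C`` (rows, cols, N) equals exactly U @ V row-wise for the
    support pixels; ``cost_trace`` records the data-consistency cost
    ||AC - b||^2 at the start of every iteration."""

    C: np.ndarray
    codes: SparseCodes
    cost_trace: np.ndarray
    level_change_iters: tuple[int, ...]
    n_iters: int
    rel_change_trace: np.ndarray


def gaussian_kspace_filter(
    kspace: np.ndarray, k_sigma_pct: float
) -> np.ndarray:
    """Multiply centered k-space by an isotropic Gaussian window.

    The window is exp(-||k||^2 / (2 k_sigma^2)) with k_sigma given in
    percent of k_max (the maximum on-axis spatial frequency); the DC
    weight is always 1, weights decay monotonically with ||k||, and no
    renormalization is applied.
    """
    if not 0 < k_sigma_pct <= 100:
        raise ValueError("k_sigma_pct must be in (0, 100]")
    rows, cols = kspace.shape[-2:]
    u = (np.arange(rows) - rows // 2) / (rows / 2.0)
    v = (np.arange(cols) - cols // 2) / (cols / 2.0)
    rr = u[:, None] ** 2 + v[None, :] ** 2
    ks = k_sigma_pct / 100.0
    return kspace * np.exp(-rr / (2.0 * ks**2))


def _combine(kc: np.ndarray, coils: CoilMaps) -> np.ndarray:
    """Coil-combine per-coil k-space to a real signal series (rows, cols, N)."""
    imgs = ifft2c(kc)
    combined = np.sum(np.conj(coils.maps)[:, None] * imgs, axis=0)
    sos2 = coils.sos2
    out = np.real(combined) / np.where(sos2 > 0, sos2, 1.0)[None]
    return np.moveaxis(out, 0, -1)


def _project_rows(
    C: np.ndarray, V: np.ndarray, gram: np.ndarray, q: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    shape = C.shape
    Z = C.reshape(-1, shape[-1])
    sel, coef, _, n_sel = _omp_batch(Z, V, q, gram=gram)
    U = _codes_to_csr(sel, coef, n_sel, V.shape[0])
    return np.asarray(U @ V).reshape(shape), sel, coef, n_sel


def _initial_conc(
    kt: KTData,
    maps: TissueMaps,
    coils: CoilMaps,
    k: SPGRConstants,
    init: str | np.ndarray,
) -> np.ndarray:
    if isinstance(init, np.ndarray):
        return init.astype(float).copy()
    b = kt.b
    if init == "zero_filled":
        S = adjoint_linear(b, coils, kt.mask)
    elif init == "low_res":
        rows, cols = b.shape[-2:]
        cy, cx = rows // 2, cols // 2
        win = np.zeros((rows, cols), dtype=bool)
        win[cy - 1 : cy + 2, cx - 1 : cx + 2] = True
        S = adjoint_linear(b * win, coils, kt.mask)
    else:
        raise ValueError(f"unknown init {init!r}")
    sos2 = coils.sos2
    S = np.real(S) / np.where(sos2 > 0, sos2, 1.0)[..., None]
    C, _ = signal_to_conc(np.maximum(S, 0.0), maps, k)
    return C


def reconstruct_dictionary(
    kt: KTData,
    maps: TissueMaps,
    coils: CoilMaps,
    cfg: ReconConfig,
    k: SPGRConstants | None = None,
    init: str | np.ndarray = "zero_filled",
) -> ReconResult:
    """Dictionary-constrained iterative multiscale reconstruction.

    Per iteration: (1) map the current concentration estimate to signal
    via the SPGR equation; (2) form per-coil k-space; (3) overwrite the
    sampled entries with the measured data (hard data consistency) and,
    except at the final full-resolution level, apply the Gaussian
    multiscale filter; (4) coil-combine with conjugate maps; (5) map
    back to concentration; (6) OMP-project every pixel's profile onto
    the dictionary at sparsity q.  A scale level is left once the
    relative change falls below ``level_tol`` or after
    ``iters_per_level`` iterations; the algorithm stops when the
    relative change at the final level falls below ``epsilon`` or after
    ``max_iters`` total iterations.
    """
    k = k or SPGRConstants()
    V = cfg.dictionary.V
    if V.shape[1] != kt.mask.n_frames:
        raise ValueError("dictionary time axis does not match the data")
    gram = V @ V.T
    mask = kt.mask.mask[None]
    b = kt.b
    C = _initial_conc(kt, maps, coils, k, init)
    C, sel, coef, n_sel = _project_rows(C, V, gram, cfg.q)

    levels = list(cfg.schedule.k_sigma_levels)
    n_levels = len(levels)
    cost_trace: list[float] = []
    rel_trace: list[float] = []
    level_changes: list[int] = []
    level = 0
    iters_at_level = 0
    it = 0
    while it < cfg.max_iters:
        S = conc_to_signal(C, maps, k)
        kc = fft2c(coils.maps[:, None] * np.moveaxis(S, -1, 0)[None])
        cost_trace.append(float(np.sum(np.abs((kc - b) * mask) ** 2)))
        kc = np.where(mask, b, kc)
        if level < n_levels - 1:
            kc = gaussian_kspace_filter(kc, levels[level])
        S_new = _combine(kc, coils)
        C_new, _ = signal_to_conc(S_new, maps, k)
        C_new, sel, coef, n_sel = _project_rows(C_new, V, gram, cfg.q)
        num = float(np.linalg.norm(C_new - C))
        den = float(np.linalg.norm(C_new))
        rel = num / den if den > 0 else 0.0
        rel_trace.append(rel)
        C = C_new
        it += 1
        iters_at_level += 1
        at_final = level == n_levels - 1
        if at_final:
            if rel < cfg.epsilon:
                break
        elif rel < cfg.level_tol or iters_at_level >= cfg.schedule.iters_per_level:
            level += 1
            iters_at_level = 0
            level_changes.append(it)
    codes = SparseCodes(
        U=_codes_to_csr(sel, coef, n_sel, V.shape[0]), q=cfg.q
    )
    return ReconResult(
        C=C,
        codes=codes,
        cost_trace=np.asarray(cost_trace),
        level_change_iters=tuple(level_changes),
        n_iters=it,
        rel_change_trace=np.asarray(rel_trace),
    )


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    mag = np.abs(x)
    scale = np.maximum(mag - thr, 0.0) / np.where(mag > 0, mag, 1.0)
    return x * scale


def _dt(S: np.ndarray) -> np.ndarray:
    """Temporal forward difference along the last axis, (…, N) -> (…, N-1)."""
    return S[..., 1:] - S[..., :-1]


def _dt_adj(z: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_dt`."""
    out = np.zeros(z.shape[:-1] + (z.shape[-1] + 1,), dtype=z.dtype)
    out[..., :-1] -= z
    out[..., 1:] += z
    return out


def reconstruct_tfd(
    kt: KTData,
    maps: TissueMaps,
    coils: CoilMaps,
    cfg: TFDConfig,
    k: SPGRConstants | None = None,
) -> tuple[np.ndarray, dict]:
    """Temporal-finite-difference regularized reconstruction via ADMM.

    Minimizes ||Fu Sm S - b||^2 + lambda ||D_t S||_1 over the signal
    image series S (the data-consistency subproblem stays convex and is
    solved exactly in k-space), then converts the result to
    concentration through the SPGR inverse.  Stops when the relative
    change between successive iterates falls below ``tol`` or at
    ``max_iters``.  Returns ``(C, info)``.
    """
    k = k or SPGRConstants()
    mask = kt.mask.mask  # (N, rows, cols)
    b = kt.b
    n = mask.shape[0]
    rho = cfg.admm_rho
    # penalty on the finite-difference split scales with lambda so the
    # soft threshold lam/rho_z stays moderate at extreme weights
    rho_z = max(rho, cfg.lam)
    # initial S: zero-filled coil combine
    S = adjoint_linear(b, coils, kt.mask)  # complex (rows, cols, N)
    sos2 = coils.sos2
    S = S / np.where(sos2 > 0, sos2, 1.0)[..., None]
    m = coils.maps  # (n_coils, rows, cols)

    z = _dt(S)
    uz = np.zeros_like(z)
    v = m[:, None] * np.moveaxis(S, -1, 0)[None]  # (n_coils, N, rows, cols)
    uv = np.zeros_like(v)

    # S-update system: (rho * sos2 * I + rho * Dt' Dt) per pixel; two
    # cases (support / background).  Background pixels are held at zero.
    DtD = np.zeros((n, n))
    idx = np.arange(n)
    DtD[idx, idx] = 2.0
    DtD[0, 0] = DtD[-1, -1] = 1.0
    DtD[idx[:-1], idx[:-1] + 1] = -1.0
    DtD[idx[:-1] + 1, idx[:-1]] = -1.0
    A_sup = rho * np.eye(n) + rho_z * DtD
    A_inv = np.linalg.inv(A_sup)
    support = sos2 > 0.5

    thr = cfg.lam / rho_z if rho_z > 0 else 0.0
    rel_trace = []
    n_iter = 0
    for n_iter in range(1, cfg.max_iters + 1):
        # v-update: exact k-space solve of ||M F v - b||^2 + rho/2 ||v - (mS - uv)||^2
        w = m[:, None] * np.moveaxis(S, -1, 0)[None] - uv
        wk = fft2c(w)
        vk = np.where(mask[None], (2.0 * b + rho * wk) / (2.0 + rho), wk)
        v = ifft2c(vk)
        # z-update
        z = _soft(_dt(S) - uz, thr)
        # S-update
        rhs_v = np.sum(np.conj(m)[:, None] * (v + uv), axis=0)  # (N, rows, cols)
        rhs = rho * np.moveaxis(rhs_v, 0, -1) + rho_z * _dt_adj(z + uz)
        S_new = np.einsum("...n,mn->...m", rhs, A_inv)
        S_new = np.where(support[..., None], S_new, 0.0)
        num = float(np.linalg.norm(S_new - S))
        den = float(np.linalg.norm(S_new))
        rel = num / den if den > 0 else 0.0
        rel_trace.append(rel)
        S = S_new
        # dual updates
        uv = uv + v - m[:, None] * np.moveaxis(S, -1, 0)[None]
        uz = uz + z - _dt(S)
        if rel < cfg.tol:
            break
    S_real = np.maximum(np.real(S), 0.0)
    C, _ = signal_to_conc(S_real, maps, k)
    info = {
        "n_iters": n_iter,
        "rel_change_trace": np.asarray(rel_trace),
        "primal_residual_v": float(
            np.linalg.norm(v - m[:, None] * np.moveaxis(S, -1, 0)[None])
        ),
        "primal_residual_z": float(np.linalg.norm(z - _dt(S))),
    }
    return C, info


def tune_tfd_lambda(
    kt: KTData,
    maps: TissueMaps,
    coils: CoilMaps,
    reference: np.ndarray,
    roi: np.ndarray,
    lambdas,
    k: SPGRConstants | None = None,
    base_cfg: TFDConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the lambda minimizing tumor-ROI nRMSE against a reference.

    Retrospective tuning: reconstructs at each candidate weight and
    returns ``(best_lambda, nrmse_percent_per_lambda)``.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("empty lambda grid")
    base = base_cfg or TFDConfig()
    ref_roi = reference[roi]
    ref_norm = np.linalg.norm(ref_roi)
    if ref_norm == 0:
        raise ValueError("reference has zero norm on the ROI")
    errs = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        cfg = TFDConfig(
            lam=float(lam), admm_rho=base.admm_rho, tol=base.tol, max_iters=base.max_iters
        )
        C, _ = reconstruct_tfd(kt, maps, coils, cfg, k=k)
        errs[i] = 100.0 * np.linalg.norm(C[roi] - ref_roi) / ref_norm
    return float(lambdas[int(np.argmin(errs))]), errs
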
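"""Error statistics: Monte-Carlo bias/uncertainty over the kinetic
parameter space, Bland-Altman agreement, and normalized RMSE.

"Uncertainty" is the population standard deviation of the estimates
across noise realizations; "bias" is the mean estimate minus the truth.
When comparing the raw-noise and q-sparse-projected pipelines, using
the same noise seed yields paired realizations, so differences between
the two pipelines can be judged against the Monte-Carlo standard error
of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary, _omp_batch
from .kinetics import (
    AIFCurve,
    TimeGrid,
    TKParams,
    etk_fit,
    etk_forward,
    patlak_fit_many,
    patlak_forward,
)
from .phantom import NoiseSpec, simulate_noisy_profiles

__all__ = [
    "BiasUncertaintyMaps",
    "BlandAltmanResult",
    "mc_bias_uncertainty",
    "bland_altman",
    "nrmse",
]


@dataclass(frozen=True, eq=False)
class BiasUncertaintyMaps:
    """Per-grid-point bias and uncertainty of (ktrans, vp) estimates.

    Arrays are indexed (i_ktrans, i_vp); ``estimates`` keeps the raw
    per-realization estimates, shape (nk, nv, n_reps, 2), for paired
    comparisons between pipelines sharing a noise seed.
    """

    ktrans_values: np.ndarray
    vp_values: np.ndarray
    bias_ktrans: np.ndarray
    bias_vp: np.ndarray
    std_ktrans: np.ndarray
    std_vp: np.ndarray
    estimates: np.ndarray
    n_reps: int


def mc_bias_uncertainty(
    model: str,
    ktrans_values: np.ndarray,
    vp_values: np.ndarray,
    aif: AIFCurve,
    grid: TimeGrid,
    noise: NoiseSpec,
    pipeline: str = "raw",
    q: int | None = None,
    dictionary: Dictionary | None = None,
    ve_fixed: float = 0.6,
) -> BiasUncertaintyMaps:
    """Monte-Carlo bias/uncertainty of kinetic-parameter estimation.

    For every (ktrans, vp) grid point a clean profile is generated
    (ETK profiles use the fixed ``ve_fixed``), ``noise.n_realizations``
    noisy copies are drawn, optionally replaced by their q-sparse OMP
    projections (``pipeline='q_sparse'``), and fitted with the matching
    model.  Bias and uncertainty are the mean minus truth and the
    population std of the estimates.  Fixed seeds make the result
    reproducible, and the same seed pairs the realizations across
    pipelines.
    """
    if model not in ("patlak", "etk"):
        raise ValueError(f"unknown model {model!r}")
    if pipeline not in ("raw", "q_sparse"):
        raise ValueError(f"unknown pipeline {pipeline!r}")
    if pipeline == "q_sparse":
        if dictionary is None or q is None:
            raise ValueError("q_sparse pipeline needs a dictionary and q")
        V = dictionary.V
        gram = V @ V.T
    kt_vals = np.asarray(ktrans_values, dtype=float)
    vp_vals = np.asarray(vp_values, dtype=float)
    nk, nv = kt_vals.size, vp_vals.size
    n_reps = noise.n_realizations
    est = np.empty((nk, nv, n_reps, 2))
    for i, ktr in enumerate(kt_vals):
        for j, vp in enumerate(vp_vals):
            if model == "patlak":
                clean = patlak_forward(TKParams(ktr, vp), aif, grid)
            else:
                clean = etk_forward(TKParams(ktr, vp, ve_fixed), aif, grid)
            spec = NoiseSpec(
                sigma=noise.sigma,
                n_realizations=n_reps,
                seed=noise.seed + 7919 * i + 104729 * j,
            )
            reps = simulate_noisy_profiles(clean, spec)
            if pipeline == "q_sparse":
                sel, coef, _, n_sel = _omp_batch(reps, V, q, gram=gram)
                approx = np.zeros_like(reps)
                for a in range(q):
                    use = n_sel > a
                    approx[use] += coef[use, a, None] * V[sel[use, a]]
                reps = approx
            if model == "patlak":
                est[i, j] = patlak_fit_many(reps, aif, grid)
            else:
                for rix in range(n_reps):
                    fr = etk_fit(reps[rix], aif, grid)
                    est[i, j, rix] = (fr.params.ktrans, fr.params.vp)
    truth = np.stack(
        np.broadcast_arrays(kt_vals[:, None], vp_vals[None, :]), axis=-1
    )
    mean = est.mean(axis=2)
    std = est.std(axis=2)
    return BiasUncertaintyMaps(
        ktrans_values=kt_vals,
        vp_values=vp_vals,
        bias_ktrans=mean[..., 0] - truth[..., 0],
        bias_vp=mean[..., 1] - truth[..., 1],
        std_ktrans=std[..., 0],
        std_vp=std[..., 1],
        estimates=est,
        n_reps=n_reps,
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, population std and 1.96-sigma limits of agreement."""

    mu: float
    sigma: float
    loa: tuple[float, float]
    n_points: int


def bland_altman(estimates: np.ndarray, reference: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of estimates against a reference.

    Differences are estimate minus reference; the limits of agreement
    are mu +/- 1.96 sigma with sigma the population standard deviation.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if est.size != ref.size:
        raise ValueError("estimates and reference must have equal length")
    if est.size < 2:
        raise ValueError("need at least two points")
    d = est - ref
    mu = float(d.mean())
    sigma = float(d.std())
    return BlandAltmanResult(
        mu=mu, sigma=sigma, loa=(mu - 1.96 * sigma, mu + 1.96 * sigma), n_points=d.size
    )


def nrmse(x: np.ndarray, ref: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Normalized RMSE in percent: 100 ||x - ref||_2 / ||ref||_2 over a ROI."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if roi is not None:
        x = x[roi]
        ref = ref[roi]
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference norm is zero on the ROI")
    return float(100.0 * np.linalg.norm(x - ref) / denom)
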
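"""Synthetic brain-tumor digital reference object (DRO) and noisy-profile
Monte-Carlo generation.

The DRO is a parametric 2-D phantom following the same generative chain
as a measured object: per-pixel ETK kinetic parameters and pre-contrast
tissue maps produce concentration profiles, the SPGR equation produces
dynamic images, which are then coil-weighted, Fourier transformed,
sampled, and optionally corrupted with complex Gaussian noise.

Anatomy: an elliptical "brain" with an off-center ring tumor (enhancing
rim with smooth parameter heterogeneity, non-enhancing necrotic core),
a few high-plasma-volume "vessel" pixels, and normal tissue with intact
blood-brain barrier (ktrans = 0, vp = 0, hence time-constant signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .kinetics import AIFCurve, TimeGrid, _exp_conv_fine
from .signal_model import SPGRConstants, TissueMaps, predicted_baseline

__all__ = ["DRO", "NoiseSpec", "build_dro", "simulate_noisy_profiles"]


@dataclass(frozen=True)
class NoiseSpec:
    """Concentration-domain additive white Gaussian noise: standard
    deviation in mM (default 0.005) and number of Monte-Carlo
    realizations (default 500)."""

    sigma: float = 0.005
    n_realizations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass(frozen=True, eq=False)
class DRO:
    """Digital reference object with ground truth for evaluation."""

    ktrans_map: np.ndarray
    vp_map: np.ndarray
    ve_map: np.ndarray
    tissue: TissueMaps
    roi_masks: dict
    conc: np.ndarray  # ground-truth concentration, (rows, cols, N)
    time: TimeGrid
    aif: AIFCurve
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.ktrans_map.shape


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    lo: float,
    hi: float,
    smoothness: float = 6.0,
) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), smoothness)
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


def _ellipse(shape, center, axes) -> np.ndarray:
    yy, xx = np.indices(shape)
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def _etk_profiles(
    ktrans: np.ndarray,
    vp: np.ndarray,
    ve: np.ndarray,
    aif: AIFCurve,
    time: TimeGrid,
) -> np.ndarray:
    """Vectorized ETK evaluation for flat parameter arrays -> (m, N)."""
    dtf = time.dt / aif.oversample
    idx = time.frame_indices(aif.oversample)
    cp = aif.cp_fine[idx]
    out = vp[:, None] * cp
    leaky = (ktrans > 0) & (ve > 0)
    for i in np.nonzero(leaky)[0]:
        conv = _exp_conv_fine(aif.cp_fine, dtf, ktrans[i] / ve[i])[idx]
        out[i] += (ktrans[i] / 60.0) * conv
    return out


def build_dro(
    aif: AIFCurve,
    shape: tuple[int, int] = (96, 96),
    time: TimeGrid | None = None,
    seed: int = 0,
    k: SPGRConstants | None = None,
    rim_ktrans: tuple[float, float] = (0.05, 0.30),
    rim_vp: tuple[float, float] = (0.02, 0.10),
    rim_ve: tuple[float, float] = (0.2, 0.6),
    vessel_vp: float = 0.5,
    t1_range: tuple[float, float] = (1.0, 1.6),
) -> DRO:
    """Build the synthetic brain-tumor DRO.

    All parameter ranges default to values inside the standard library
    grid (ktrans <= 0.8 min^-1, vp <= 0.6, ve <= 1), so every DRO
    profile is covered by the dictionary's training range.  The result
    is deterministic for a fixed seed.
    """
    if time is None:
        time = aif.grid
    k = k or SPGRConstants()
    if not (0 <= rim_ktrans[0] <= rim_ktrans[1] <= 0.8):
        raise ValueError("rim ktrans range outside library grid")
    if not (0 <= rim_vp[0] <= rim_vp[1] <= 0.6) or not 0 <= vessel_vp <= 0.6:
        raise ValueError("vp range outside library grid")
    if not (0 <= rim_ve[0] <= rim_ve[1] <= 1.0):
        raise ValueError("ve range outside library grid")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    cy, cx = rows / 2.0, cols / 2.0
    brain = _ellipse(shape, (cy, cx), (0.42 * rows, 0.36 * cols))
    tum_c = (cy - 0.15 * rows, cx + 0.14 * cols)
    outer = _ellipse(shape, tum_c, (0.115 * rows, 0.115 * cols)) & brain
    core = _ellipse(shape, tum_c, (0.052 * rows, 0.052 * cols)) & brain
    rim = outer & ~core
    vessel = (
        _ellipse(shape, (cy + 0.22 * rows, cx - 0.18 * cols), (0.02 * rows, 0.02 * cols))
        | _ellipse(shape, (cy - 0.05 * rows, cx - 0.26 * cols), (0.016 * rows, 0.016 * cols))
    ) & brain & ~outer
    normal = brain & ~outer & ~vessel
    background = ~brain

    ktrans = np.zeros(shape)
    vp = np.zeros(shape)
    ve = np.zeros(shape)
    ktrans[rim] = _smooth_field(rng, shape, *rim_ktrans)[rim]
    vp[rim] = _smooth_field(rng, shape, *rim_vp)[rim]
    ve[rim] = _smooth_field(rng, shape, *rim_ve)[rim]
    vp[vessel] = vessel_vp

    t1 = _smooth_field(rng, shape, *t1_range, smoothness=8.0)
    r10 = np.where(brain, 1.0 / t1, 0.0)
    m0 = np.where(brain, _smooth_field(rng, shape, 0.8, 1.2, smoothness=8.0), 0.0)
    tissue_tmp = TissueMaps(m0=m0, r10=r10, s0=np.zeros(shape))
    s0 = np.where(brain, predicted_baseline(tissue_tmp, k), 0.0)
    tissue = TissueMaps(m0=m0, r10=r10, s0=s0)

    conc = np.zeros(shape + (time.n_frames,))
    enh = brain & ((ktrans > 0) | (vp > 0))
    flat = _etk_profiles(ktrans[enh], vp[enh], ve[enh], aif, time)
    conc[enh] = flat

    roi_masks = {
        "tumor_rim": rim,
        "tumor_core": core,
        "vessel": vessel,
        "normal": normal,
        "background": background,
    }
    return DRO(
        ktrans_map=ktrans,
        vp_map=vp,
        ve_map=ve,
        tissue=tissue,
        roi_masks=roi_masks,
        conc=conc,
        time=time,
        aif=aif,
        seed=seed,
    )


def simulate_noisy_profiles(profiles: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Additive i.i.d. Gaussian noise realizations in the concentration
    domain: returns a stack of shape (n_realizations,) + profiles.shape."""
    profiles = np.asarray(profiles, dtype=float)
    rng = np.random.default_rng(noise.seed)
    if noise.sigma == 0.0:
        return np.broadcast_to(
            profiles, (noise.n_realizations,) + profiles.shape
        ).copy()
    return profiles + noise.sigma * rng.standard_normal(
        (noise.n_realizations,) + profiles.shape
    )
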
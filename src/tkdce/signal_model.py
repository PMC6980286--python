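"""Spoiled-gradient-echo (SPGR) signal model and DESPOT1 T1 mapping.

The steady-state SPGR equation links the longitudinal relaxation rate
R1(x, t) = R1(x, 0) + r1 * c(x, t) to the image intensity

    s = M0 sin(a) (1 - E) / (1 - cos(a) E) + [s0 - s0_pred],
    E = exp(-TR * R1),

where the bracketed offset reconciles the measured pre-contrast frame
s0 with the baseline predicted by the (M0, R1_0) maps, so that c = 0
always maps back to s0 exactly.  ``signal_to_conc`` is the exact
algebraic inverse; unphysical signals whose implied E would be
non-positive are clamped to a small epsilon and flagged rather than
producing NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPGRConstants",
    "TissueMaps",
    "ConcSeries",
    "SignalSeries",
    "conc_to_signal",
    "signal_to_conc",
    "predicted_baseline",
    "despot1_fit",
]

_E_CLAMP = 1e-9


@dataclass(frozen=True)
class SPGRConstants:
    """Acquisition constants: TR (s), flip angle (deg), relaxivity r1
    (s^-1 mM^-1).  Defaults: TR = 6 ms, 15 degrees, r1 = 4.5."""

    tr: float = 0.006
    flip_deg: float = 15.0
    r1: float = 4.5

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError("flip_deg must be in (0, 90)")
        if self.r1 <= 0:
            raise ValueError("r1 must be > 0")

    @property
    def flip_rad(self) -> float:
        return np.deg2rad(self.flip_deg)


@dataclass(frozen=True, eq=False)
class TissueMaps:
    """Per-pixel M0 (a.u.), pre-contrast R1 (s^-1) and pre-contrast
    signal s0.  Pixels with m0 == 0 are treated as background."""

    m0: np.ndarray
    r10: np.ndarray
    s0: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.m0 > 0


@dataclass(frozen=True, eq=False)
class ConcSeries:
    """Concentration-vs-time image series, shape (rows, cols, N), mM."""

    C: np.ndarray
    time: "object" = None

    @property
    def n_frames(self) -> int:
        return self.C.shape[-1]


@dataclass(frozen=True, eq=False)
class SignalSeries:
    """Signal-intensity image series, shape (rows, cols, N)."""

    S: np.ndarray
    time: "object" = None


def _spgr(m0, e, sa, ca):
    return m0 * sa * (1.0 - e) / (1.0 - ca * e)


def predicted_baseline(maps: TissueMaps, k: SPGRConstants) -> np.ndarray:
    """Pre-contrast signal predicted by the (m0, r10) maps."""
    e0 = np.exp(-k.tr * maps.r10)
    return _spgr(maps.m0, e0, np.sin(k.flip_rad), np.cos(k.flip_rad))


def conc_to_signal(C: np.ndarray, maps: TissueMaps, k: SPGRConstants) -> np.ndarray:
    """SPGR forward map, elementwise over (..., N) concentration arrays.

    c = 0 yields exactly s0; the output saturates at m0*sin(a) (plus the
    baseline offset) for very large concentrations.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite concentrations")
    sa, ca = np.sin(k.flip_rad), np.cos(k.flip_rad)
    r1t = maps.r10[..., None] + k.r1 * C
    e = np.exp(-k.tr * r1t)
    s_model = _spgr(maps.m0[..., None], e, sa, ca)
    offset = maps.s0 - predicted_baseline(maps, k)
    return s_model + offset[..., None]


def signal_to_conc(
    S: np.ndarray, maps: TissueMaps, k: SPGRConstants
) -> tuple[np.ndarray, np.ndarray]:
    """Exact algebraic inverse of :func:`conc_to_signal`.

    Returns ``(C, clamped)`` where ``clamped`` marks pixels/frames whose
    implied exponential factor fell outside (0, ...] and was clamped to
    epsilon (saturated or otherwise unphysical signal); output there is
    finite, never NaN.  Background pixels (m0 == 0) return 0.
    """
    S = np.asarray(S, dtype=float)
    sa, ca = np.sin(k.flip_rad), np.cos(k.flip_rad)
    support = maps.support
    m0 = np.where(support, maps.m0, 1.0)
    y = S - (maps.s0 - predicted_baseline(maps, k))[..., None]
    denom = m0[..., None] * sa - y * ca
    near_zero = np.abs(denom) < 1e-300
    denom = np.where(near_zero, 1e-300, denom)
    e = (m0[..., None] * sa - y) / denom
    clamped = (e <= 0) | near_zero
    e = np.where(clamped, _E_CLAMP, e)
    r1t = -np.log(e) / k.tr
    C = (r1t - maps.r10[..., None]) / k.r1
    C = np.where(support[..., None], C, 0.0)
    clamped &= support[..., None]
    return C, clamped


def despot1_fit(
    signals: np.ndarray, flips_deg: np.ndarray, tr: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DESPOT1 (variable flip angle) estimation of M0 and R1_0 maps.

    Uses the linearized SPGR regression of s/sin(a) on s/tan(a); the
    slope is E = exp(-TR * R1).  ``signals`` has shape (n_flip, ...).
    Returns ``(m0, r10, valid)``; pixels whose slope falls outside
    (0, 1) (including all-zero pixels) are flagged invalid and their
    maps set to zero.
    """
    signals = np.asarray(signals, dtype=float)
    flips = np.deg2rad(np.asarray(flips_deg, dtype=float))
    if signals.shape[0] != flips.size or flips.size < 2:
        raise ValueError("need one image per flip angle and >= 2 angles")
    shape = signals.shape[1:]
    sa = np.sin(flips).reshape((-1,) + (1,) * len(shape))
    ta = np.tan(flips).reshape((-1,) + (1,) * len(shape))
    y = signals / sa
    x = signals / ta
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    intercept = ym - slope * xm
    valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & (intercept > 0)
    e = np.where(valid, slope, 0.5)
    m0 = np.where(valid, intercept / (1.0 - e), 0.0)
    r10 = np.where(valid, -np.log(e) / tr, 0.0)
    return m0, r10, valid
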
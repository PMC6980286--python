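"""Multicoil Cartesian (k, t) acquisition model and sampling patterns.

The forward model is A C = Fu Sm T C: the SPGR transform T maps
concentration to signal images, Sm multiplies by receiver coil
sensitivities, Fu is a centered unitary 2-D Fourier transform per frame
followed by selection on the (k, t) sampling mask.

The golden-angle Cartesian (GOCART-style) mask samples, per frame,
Cartesian grid points lying along radial spokes whose angles advance by
the golden angle (111.246 deg), with randomized point selection along
each spoke until ceil(M/R) points are collected.  Frame 0 is always
fully sampled and the k-space origin is included in every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_model import SPGRConstants, TissueMaps, conc_to_signal

__all__ = [
    "CoilMaps",
    "SamplingMask",
    "KTData",
    "fft2c",
    "ifft2c",
    "gocart_mask",
    "synthetic_coil_maps",
    "apply_forward",
    "forward_linear",
    "adjoint_linear",
    "estimate_coil_maps",
    "add_noise",
    "estimate_bolus_arrival",
    "correct_delay",
]

GOLDEN_ANGLE_DEG = 111.246


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D FFT over the trailing two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass(frozen=True, eq=False)
class CoilMaps:
    """Complex coil sensitivities, shape (n_coils, rows, cols);
    sum-of-squares magnitude is 1 on the support."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def sos2(self) -> np.ndarray:
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass(frozen=True, eq=False)
class SamplingMask:
    """Boolean (k, t) sampling pattern, shape (N, rows, cols)."""

    mask: np.ndarray
    R_nominal: float
    seed: int

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    def fraction(self, frame: int) -> float:
        return float(self.mask[frame].mean())


@dataclass(frozen=True, eq=False)
class KTData:
    """Sampled multicoil k-t data, shape (n_coils, N, rows, cols),
    zero at unsampled locations."""

    b: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0

    @property
    def n_coils(self) -> int:
        return self.b.shape[0]


def gocart_mask(
    shape: tuple[int, int], n_frames: int, R: float, seed: int = 0
) -> SamplingMask:
    """Golden-angle Cartesian randomized sampling mask.

    Frame 0 is fully sampled.  Each later frame accumulates randomly
    chosen points from successive golden-angle-rotated radial spokes
    (origin always included) until ceil(M/R) points are sampled.
    Reproducible for a fixed seed.
    """
    ky, kx = shape
    M = ky * kx
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > M:
        raise ValueError("R cannot exceed the number of k-space points")
    mask = np.zeros((n_frames, ky, kx), dtype=bool)
    mask[0] = True
    if R == 1:
        mask[:] = True
        return SamplingMask(mask=mask, R_nominal=float(R), seed=seed)
    rng = np.random.default_rng(seed)
    target = int(np.ceil(M / R))
    cy, cx = ky // 2, kx // 2
    rmax = np.hypot(max(cy, ky - cy), max(cx, kx - cx))
    radii = np.arange(-rmax, rmax + 0.25, 0.5)
    spoke_counter = 0
    for t in range(1, n_frames):
        frame = mask[t]
        frame[cy, cx] = True
        n_sampled = 1
        while n_sampled < target:
            theta = np.deg2rad(GOLDEN_ANGLE_DEG * spoke_counter)
            spoke_counter += 1
            iy = np.round(cy + radii * np.sin(theta)).astype(int)
            ix = np.round(cx + radii * np.cos(theta)).astype(int)
            ok = (iy >= 0) & (iy < ky) & (ix >= 0) & (ix < kx)
            pts = np.unique(iy[ok] * kx + ix[ok])
            rng.shuffle(pts)
            for p in pts:
                y, x = divmod(int(p), kx)
                if not frame[y, x]:
                    frame[y, x] = True
                    n_sampled += 1
                    if n_sampled >= target:
                        break
    return SamplingMask(mask=mask, R_nominal=float(R), seed=seed)


def synthetic_coil_maps(
    shape: tuple[int, int], n_coils: int = 8, coil_width: float = 0.9
) -> CoilMaps:
    """Smooth synthetic birdcage-like coil sensitivities.

    Gaussian magnitude profiles centered on a ring around the FOV with a
    smooth linear phase per coil; normalized to unit sum-of-squares at
    every pixel so the normalization invariant holds on any support.
    """
    ky, kx = shape
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, ky), np.linspace(-1, 1, kx), indexing="ij"
    )
    maps = np.empty((n_coils, ky, kx), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cy, cx = 1.2 * np.sin(ang), 1.2 * np.cos(ang)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * coil_width**2))
        phase = 0.5 * (np.cos(ang) * xx + np.sin(ang) * yy) + ang / 7.0
        maps[c] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return CoilMaps(maps=maps / sos)


def forward_linear(
    S: np.ndarray, coils: CoilMaps, mask: SamplingMask
) -> np.ndarray:
    """Linear part Fu Sm of the forward model.

    ``S`` is a (rows, cols, N) signal series (real or complex); returns
    masked k-space of shape (n_coils, N, rows, cols).
    """
    imgs = coils.maps[:, None, :, :] * np.moveaxis(S, -1, 0)[None]
    k = fft2c(imgs)
    return k * mask.mask[None]


def adjoint_linear(b: np.ndarray, coils: CoilMaps, mask: SamplingMask) -> np.ndarray:
    """Adjoint of :func:`forward_linear`; returns (rows, cols, N)."""
    imgs = ifft2c(b * mask.mask[None])
    combined = np.sum(np.conj(coils.maps)[:, None, :, :] * imgs, axis=0)
    return np.moveaxis(combined, 0, -1)


def apply_forward(
    C: np.ndarray,
    maps: TissueMaps,
    coils: CoilMaps,
    mask: SamplingMask,
    k: SPGRConstants,
) -> KTData:
    """Full forward model A C = Fu Sm T C."""
    C = np.asarray(C, dtype=float)
    if C.shape[:2] != coils.maps.shape[1:] or C.shape[-1] != mask.n_frames:
        raise ValueError("geometry of C, coil maps and mask must agree")
    S = conc_to_signal(C, maps, k)
    return KTData(b=forward_linear(S, coils, mask), mask=mask)


def estimate_coil_maps(kt: KTData, rel_threshold: float = 0.05) -> CoilMaps:
    """Sum-of-squares coil map estimation from time-collapsed k-t data.

    The k-t data are averaged over the frames at which each location is
    sampled, inverse-transformed per coil, and normalized by the
    sum-of-squares magnitude.  Pixels below ``rel_threshold`` of the
    peak combined magnitude are outside the support and set to zero.
    """
    counts = kt.mask.mask.sum(axis=0)
    ksum = kt.b.sum(axis=1)
    kavg = np.where(counts > 0, ksum / np.maximum(counts, 1), 0.0)
    imgs = ifft2c(kavg)
    sos = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    support = sos > rel_threshold * sos.max()
    maps = np.where(support, imgs / np.where(support, sos, 1.0), 0.0)
    return CoilMaps(maps=maps)


def add_noise(kt: KTData, snr: float | None, seed: int = 0) -> KTData:
    """Add i.i.d. complex Gaussian noise per channel at sampled points.

    sigma is defined as (peak coil-combined baseline magnitude) / snr,
    with the complex noise scaled so that E|n|^2 = sigma^2.  ``snr``
    of None or inf returns the data unchanged.
    """
    if snr is None or np.isinf(snr):
        return kt
    if snr <= 0:
        raise ValueError("snr must be positive")
    base = ifft2c(kt.b[:, 0])
    peak = float(np.sqrt(np.sum(np.abs(base) ** 2, axis=0)).max())
    sigma = peak / snr
    rng = np.random.default_rng(seed)
    shape = kt.b.shape
    noise = (sigma / np.sqrt(2.0)) * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )
    b = kt.b + noise * kt.mask.mask[None]
    return KTData(b=b, mask=kt.mask, noise_sigma=sigma)


class NoEnhancementError(ValueError):
    """The center-of-k-space series shows no contrast enhancement."""


def estimate_bolus_arrival(
    center_signal: np.ndarray,
    dt: float = 1.0,
    reference_frame: int = 2,
    n_baseline: int = 3,
) -> tuple[int, int]:
    """Bolus-arrival estimation from the k-space-center time series.

    The maximal-slope segment of the uptake is regressed linearly and
    intersected with the pre-contrast baseline level; the crossing time
    gives the arrival frame.  Returns ``(arrival_frame, shift)`` where
    ``shift = arrival_frame - reference_frame`` is the frame offset to
    correct with :func:`correct_delay`.
    """
    s = np.abs(np.asarray(center_signal, dtype=float))
    base = s[:n_baseline]
    b_mean = base.mean()
    b_std = base.std()
    if s.max() <= b_mean + 5 * max(b_std, 1e-12 * max(b_mean, 1.0)):
        raise NoEnhancementError("series shows no enhancement above baseline")
    d = np.diff(s)
    m = int(np.argmax(d))
    win = [m]
    for j in (m - 1, m + 1):
        if 0 <= j < len(d) and d[j] >= 0.5 * d[m]:
            win.append(j)
    idx = sorted(set(win))
    pts = sorted(set(i for j in idx for i in (j, j + 1)))
    tt = np.array(pts, dtype=float)
    ss = s[pts]
    slope, intercept = np.polyfit(tt, ss, 1)
    t_arrival = (b_mean - intercept) / slope
    arrival_frame = int(np.clip(round(t_arrival), 0, len(s) - 1))
    return arrival_frame, arrival_frame - reference_frame


def correct_delay(profiles: np.ndarray, shift: int) -> np.ndarray:
    """Align a (…, N) time series with the library time axis.

    ``shift`` is the measured arrival frame minus the library reference
    frame.  A late bolus (positive shift) is advanced by dropping the
    first frames and holding the final value; an early bolus (negative
    shift) is delayed by padding zeros at the start and omitting the
    last frames.
    """
    if shift == 0:
        return profiles
    out = np.zeros_like(profiles)
    if shift > 0:
        out[..., :-shift] = profiles[..., shift:]
        out[..., -shift:] = profiles[..., -1:]
    else:
        out[..., -shift:] = profiles[..., :shift]
    return out
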
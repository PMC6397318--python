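"""Stokes parameters and the degree of polarization uniformity (DOPU).

DOPU measures the local randomness of the backscattered polarization state
on the Poincaré sphere.  Melanin-rich tissue (RPE, choroidal stroma)
scrambles polarization, so DOPU drops well below 1 there, while
polarization-preserving tissue stays near 1.

The estimator kernel-averages the *unnormalized* Stokes elements and then
normalizes by the noise-bias-corrected mean intensity (Makita-style noise
immunity): additive circular detector noise inflates the mean intensity by
``2 * sigma2`` (two channels of variance ``sigma2``) but is zero-mean in Q,
U and V, so subtracting the bias from I alone removes the dominant
low-SNR bias of DOPU.  The classical normalize-then-average estimator is
available via ``average_normalized=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["StokesVolume", "DopuImage", "stokes_from_channels", "dopu"]


@dataclass
class StokesVolume:
    """Unnormalized Stokes elements per voxel, grid ``(nb, nz, nx)``."""

    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    V: np.ndarray
    repeat: int = 0

    @property
    def shape(self):
        return self.I.shape


@dataclass
class DopuImage:
    """DOPU per voxel in [0, 1] plus a validity mask.

    Voxels whose noise-corrected window intensity falls below ``eps`` are
    reported as 0 and flagged invalid rather than divided through.
    """

    values: np.ndarray
    valid: np.ndarray
    kernel: tuple[int, int]
    noise_variance: float
    meta: dict = field(default_factory=dict)


def stokes_from_channels(volume, repeat: int = 0) -> StokesVolume:
    """Stokes elements of one repeat of a two-channel complex volume.

    Sign convention: V = -2 Im(conj(h) v), so the circular state
    (h, v) = (1, i)/sqrt(2) maps to V = -1.  DOPU is invariant to this
    choice (it uses the magnitude only).
    """
    if not (0 <= repeat < volume.n_repeats):
        raise IndexError(f"repeat {repeat} out of range [0, {volume.n_repeats})")
    h = volume.h[repeat].astype(np.complex128)
    v = volume.v[repeat].astype(np.complex128)
    ah2 = np.abs(h) ** 2
    av2 = np.abs(v) ** 2
    hv = h * np.conj(v)
    return StokesVolume(
        I=ah2 + av2,
        Q=ah2 - av2,
        U=2.0 * hv.real,
        V=2.0 * hv.imag,
        repeat=repeat,
    )


def _window_mean(a: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Per-B-scan (depth × transverse) boxcar mean on a (nb, nz, nx) array."""
    transverse, depth = kernel
    return ndimage.uniform_filter(a, size=(1, depth, transverse), mode="nearest")


def dopu(
    stokes: StokesVolume,
    noise_variance: float,
    kernel: tuple[int, int] = (3, 3),
    *,
    corrected: bool = True,
    average_normalized: bool = False,
    eps: float | None = None,
) -> DopuImage:
    """Degree of polarization uniformity with noise-bias correction.

    Parameters
    ----------
    stokes
        Unnormalized Stokes volume of one repeat.
    noise_variance
        Additive complex noise variance ``sigma2`` per polarization channel.
    kernel
        ``(transverse, depth)`` window in pixels; both odd and >= 1. The
        window is applied within each B-scan.
    corrected
        Subtract the ``2 * sigma2`` noise bias from the window-mean
        intensity before normalizing. ``False`` gives the uncorrected
        estimator (for bias comparisons).
    average_normalized
        Classical variant: normalize per-voxel Stokes vectors first, then
        average, with no noise correction applied to the normalization.
    eps
        Invalid-window guard on the (corrected) mean intensity. Defaults to
        ``10 * machine epsilon * max window intensity``.
    """
    transverse, depth = kernel
    if transverse < 1 or depth < 1 or transverse % 2 == 0 or depth % 2 == 0:
        raise ValueError("kernel dims must be odd and >= 1")
    nb, nz, nx = stokes.shape
    if depth > nz or transverse > nx:
        raise ValueError(
            f"kernel {kernel} larger than B-scan grid (nz={nz}, nx={nx})"
        )
    if noise_variance < 0:
        raise ValueError("noise_variance must be >= 0")

    if average_normalized:
        denom = np.where(stokes.I > 0, stokes.I, np.inf)
        q = _window_mean(stokes.Q / denom, kernel)
        u = _window_mean(stokes.U / denom, kernel)
        v = _window_mean(stokes.V / denom, kernel)
        valid = _window_mean((stokes.I > 0).astype(float), kernel) > 0
        values = np.sqrt(q * q + u * u + v * v)
    else:
        i_bar = _window_mean(stokes.I, kernel)
        q_bar = _window_mean(stokes.Q, kernel)
        u_bar = _window_mean(stokes.U, kernel)
        v_bar = _window_mean(stokes.V, kernel)
        i_corr = i_bar - (2.0 * noise_variance if corrected else 0.0)
        if eps is None:
            eps = 10.0 * np.finfo(np.float64).eps * float(i_bar.max(initial=0.0))
        valid = i_corr > eps
        values = np.zeros_like(i_bar)
        np.divide(
            np.sqrt(q_bar**2 + u_bar**2 + v_bar**2),
            i_corr,
            out=values,
            where=valid,
        )
    values = np.clip(values, 0.0, 1.0)
    values[~valid] = 0.0
    return DopuImage(
        values=values,
        valid=valid,
        kernel=kernel,
        noise_variance=noise_variance,
        meta={"corrected": corrected, "average_normalized": average_normalized},
    )
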
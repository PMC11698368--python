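"""Fourier-domain low-pass downsampling of 3-D volumes.

A low-resolution counterpart of a volume is produced by taking the FFT of
the high-resolution grid, keeping only the central (low-frequency) block of
the zero-frequency-centered spectrum — an ideal low-pass filter — and
inverting the FFT on the reduced grid:

    y = F_lr^{-1} D F_hr x

The cropped spectrum is rescaled by the voxel-count ratio so that mean
intensity is preserved (a constant volume maps to the same constant). The
operator needs no training and sits outside any gradient path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = ["ScaleSpec", "lowpass_crop_spectrum", "downsample"]

DEFAULT_SCALES = (0.5, 0.25, 0.125)


@dataclass(frozen=True)
class ScaleSpec:
    """Per-axis downsampling factors s with target dims d_i = round(D_i * s_i)."""

    s: tuple[float, float, float]

    def __post_init__(self):
        if len(self.s) != 3 or any(not (0 < si <= 1) for si in self.s):
            raise ValueError(f"scale factors must lie in (0, 1], got {self.s}")

    @classmethod
    def isotropic(cls, s: float) -> "ScaleSpec":
        return cls((s, s, s))

    @classmethod
    def from_denominator(cls, denom: int) -> "ScaleSpec":
        return cls.isotropic(1.0 / denom)

    def target_shape(self, source_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        tgt = tuple(int(round(D * si)) for D, si in zip(source_shape, self.s))
        if any(t < 1 for t in tgt):
            raise ValueError(f"target shape {tgt} has an empty axis")
        return tgt


def lowpass_crop_spectrum(spectrum: np.ndarray, target_shape) -> np.ndarray:
    """Keep the central `target_shape` block of a zero-frequency-centered spectrum.

    For even target sizes the ambiguous highest-negative-frequency (Nyquist)
    plane has no conjugate partner on the reduced grid; it is zeroed rather
    than split, which keeps the cropped spectrum of a real signal Hermitian.
    Only signals with energy exactly at the cutoff are affected.
    """
    spectrum = np.asarray(spectrum)
    if any(t > s for t, s in zip(target_shape, spectrum.shape)):
        raise ValueError(
            f"target shape {tuple(target_shape)} exceeds spectrum shape {spectrum.shape}")
    slices = []
    for N, d in zip(spectrum.shape, target_shape):
        start = N // 2 - d // 2
        slices.append(slice(start, start + d))
    out = spectrum[tuple(slices)].copy()
    for ax, (N, d) in enumerate(zip(spectrum.shape, target_shape)):
        if d % 2 == 0 and d < N:
            idx = [slice(None)] * out.ndim
            idx[ax] = 0  # the -d/2 Nyquist plane of the reduced grid
            out[tuple(idx)] = 0
    return out


def downsample(vol: Volume, scale: ScaleSpec, noise=None) -> Volume:
    """Fourier low-pass downsample a volume to ``scale.target_shape``.

    `noise` is an optional callback ``f(shape) -> ndarray`` adding a spatial
    noise term to the low-resolution output (disabled by default).
    """
    data = np.asarray(vol.data, dtype=np.float64)
    tgt = scale.target_shape(data.shape)
    if any(t < 2 for t in tgt):
        raise ValueError(f"degenerate target shape {tgt}: every axis must be >= 2")
    spec = np.fft.fftshift(np.fft.fftn(data))
    cropped = lowpass_crop_spectrum(spec, tgt)
    ratio = np.prod(tgt) / np.prod(data.shape)
    small = np.fft.ifftn(np.fft.ifftshift(cropped * ratio))
    out = np.real(small)
    if noise is not None:
        out = out + noise(out.shape)
    return Volume(out, spacing=None if vol.spacing is None else tuple(
        sp / si for sp, si in zip(vol.spacing, scale.s)), value_range=vol.value_range)
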
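"""Rate and distortion metrics for neural volume compression.

Four measurements characterize one compressed configuration:

* **PSNR** (dB): ``10 * log10(MAX^2 / MSE)``; MAX defaults to 1 for
  volumes normalized to [0, 1].
* **SSIM**: luminance/contrast/structure similarity. The default *global*
  mode evaluates the formula once from whole-grid moments (population,
  1/N); a *windowed* mode averages it over sliding 3-D windows.
* **Bitrate** (bpp): stored bits per voxel — weight count x bits-per-weight
  / voxel count, since the network's weights are the compressed payload.
* **Compression rate** (%): ``(1 - n_params / n_voxels) * 100``; negative
  when the network outgrows the volume.

The two size metrics are linked by the exact identity
``bitrate = (1 - CR/100) * bit_depth``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["SSIMParams", "MetricRecord", "psnr", "ssim", "bitrate", "compression_rate"]


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizers and mode for SSIM. Defaults follow the common
    (0.01 L)^2 / (0.03 L)^2 convention with dynamic range L = 1."""

    C1: float = 1e-4
    C2: float = 9e-4
    mode: str = "global"
    window: int = 7

    def __post_init__(self):
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"unknown SSIM mode {self.mode!r}")
        if self.window % 2 != 1:
            raise ValueError("window must be odd")


@dataclass
class MetricRecord:
    """One configuration's (PSNR, SSIM, bitrate, CR, #params) bundle."""

    psnr_db: float
    ssim: float
    bitrate_bpp: float
    cr_percent: float
    n_params: int
    gpu_mem: float | None = None

    @property
    def cr_fraction(self) -> float:
        return self.cr_percent / 100.0

    @classmethod
    def from_counts(cls, psnr_db: float, ssim_val: float, n_params: int,
                    n_voxels: int, bit_depth: int = 32) -> "MetricRecord":
        return cls(psnr_db=psnr_db, ssim=ssim_val,
                   bitrate_bpp=bitrate(n_params, bit_depth, n_voxels),
                   cr_percent=compression_rate(n_params, n_voxels),
                   n_params=n_params)


def psnr(reference: np.ndarray, test: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the grids are identical."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_val ** 2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity; symmetric in its arguments, in [-1, 1]."""
    p = params or SSIMParams()
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if p.mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()        # population (1/N)
        cov = ((x - mx) * (y - my)).mean()
        return float(((2 * mx * my + p.C1) * (2 * cov + p.C2))
                     / ((mx ** 2 + my ** 2 + p.C1) * (vx + vy + p.C2)))
    w = p.window
    mx = uniform_filter(x, w)
    my = uniform_filter(y, w)
    vx = uniform_filter(x * x, w) - mx ** 2
    vy = uniform_filter(y * y, w) - my ** 2
    cov = uniform_filter(x * y, w) - mx * my
    smap = ((2 * mx * my + p.C1) * (2 * cov + p.C2)) / (
        (mx ** 2 + my ** 2 + p.C1) * (vx + vy + p.C2))
    return float(smap.mean())


def bitrate(n_params: int, bit_depth: int, n_voxels: int) -> float:
    """Bits per voxel of the stored network payload."""
    if n_params <= 0 or bit_depth <= 0 or n_voxels <= 0:
        raise ValueError("n_params, bit_depth and n_voxels must be positive")
    return n_params * bit_depth / n_voxels


def compression_rate(n_params: int, n_voxels: int) -> float:
    """Compression rate in percent; negative when the network is larger
    than the volume it encodes."""
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    return (1.0 - n_params / n_voxels) * 100.0
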
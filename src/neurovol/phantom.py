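"""Deterministic synthetic volumes for exercising the compression pipeline.

The phantoms emulate normalized MRI-like patches at desk scale: smooth
anatomy-like foreground structures on an exactly-zero background (so the
70 %-non-zero HR patch rule is exercised), optional band-limited texture,
and pure cosine modes for closed-form Fourier oracles. All generation is
seeded; no OS-entropy paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = ["PhantomSpec", "make_phantom", "make_sweep_fixture"]

KINDS = ("constant", "gaussian_blobs", "ellipsoid_shell", "bandlimited_noise", "cosine_mode")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    kind: str = "gaussian_blobs"
    n_structures: int = 3
    cutoff_fraction: float = 0.4       # of Nyquist, band-limited kinds
    spectral_slope: float = 2.0        # in-band PSD ~ 1/|k|^slope (MRI-like decay)
    mode: tuple[int, int, int] = (2, 1, 1)  # integer frequency, cosine_mode
    constant_value: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not (0 < self.cutoff_fraction <= 1):
            raise ValueError("cutoff_fraction must lie in (0, 1]")


def _index_grids(shape):
    return np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")


def _gaussian_blobs(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    ii, jj, kk = _index_grids(spec.shape)
    out = np.zeros(spec.shape)
    for _ in range(spec.n_structures):
        center = rng.uniform(0.25, 0.75, 3) * shape
        sigma = rng.uniform(0.05, 0.12) * shape.min()
        amp = rng.uniform(0.5, 1.0)
        r2 = ((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)
        out += amp * np.exp(-r2 / (2 * sigma ** 2))
    out = np.clip(out, 0.0, 1.0)
    out[out < 1e-3] = 0.0  # exact-zero background
    return out


def _ellipsoid_shell(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    ii, jj, kk = _index_grids(spec.shape)
    center = shape / 2.0
    semi = rng.uniform(0.25, 0.4, 3) * shape
    r = np.sqrt(((ii - center[0]) / semi[0]) ** 2 + ((jj - center[1]) / semi[1]) ** 2
                + ((kk - center[2]) / semi[2]) ** 2)
    thickness = 0.15
    out = np.exp(-((r - 1.0) / thickness) ** 2)
    out[out < 1e-3] = 0.0
    return np.clip(out, 0.0, 1.0)


def _bandlimited_noise(spec: PhantomSpec) -> np.ndarray:
    """Band-limited texture with an MRI-like decaying in-band spectrum.

    The spectrum is hard-zero above ``cutoff_fraction`` of Nyquist per axis
    (so ideal low-pass downsampling at a matching scale is lossless) and its
    in-band amplitude falls off as (1 + |k|^2)^(-slope/2), emulating the
    power-law spectra of anatomical images rather than white texture.
    """
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.shape)
    spectrum = np.fft.fftn(white)
    mask = np.ones(spec.shape, dtype=bool)
    k2 = np.zeros(spec.shape)
    for ax, d in enumerate(spec.shape):
        k = np.fft.fftfreq(d, d=1.0 / d)  # integer frequency indices
        kmax = max(int(spec.cutoff_fraction * (d // 2)) - 1, 1)
        sh = [1, 1, 1]
        sh[ax] = d
        mask &= (np.abs(k) <= kmax).reshape(sh)
        k2 = k2 + (k.reshape(sh)) ** 2
    weight = (1.0 + k2) ** (-spec.spectral_slope / 2.0)
    filtered = np.real(np.fft.ifftn(spectrum * mask * weight))
    lo, hi = filtered.min(), filtered.max()
    return (filtered - lo) / (hi - lo) if hi > lo else np.zeros(spec.shape)


def _cosine_mode(spec: PhantomSpec) -> np.ndarray:
    ii, jj, kk = _index_grids(spec.shape)
    k1, k2, k3 = spec.mode
    dx, dy, dz = spec.shape
    phase = 2 * np.pi * (k1 * ii / dx + k2 * jj / dy + k3 * kk / dz)
    return 0.5 + 0.4 * np.cos(phase)


def make_phantom(spec: PhantomSpec) -> Volume:
    """Generate a deterministic phantom volume with values in [0, 1]."""
    if spec.kind == "constant":
        data = np.full(spec.shape, spec.constant_value)
    elif spec.kind == "gaussian_blobs":
        data = _gaussian_blobs(spec)
    elif spec.kind == "ellipsoid_shell":
        data = _ellipsoid_shell(spec)
    elif spec.kind == "bandlimited_noise":
        data = _bandlimited_noise(spec)
    else:
        data = _cosine_mode(spec)
    return Volume(data, value_range=(float(data.min()), float(data.max())))


def make_sweep_fixture(shape=(16, 16, 16), axes=None, epochs: int = 50, seed: int = 0):
    """Run a miniature configuration sweep on a fixed-seed phantom.

    Returns a complete SweepGrid suitable for trade-off machinery tests.
    """
    from .spectral_downsample import DEFAULT_SCALES
    from .compressor import TrainConfig
    from .tradeoff import SweepAxes, run_sweep
    from .volume_io import Patch

    if axes is None:
        axes = SweepAxes(ds=list(DEFAULT_SCALES[:2]), nc=[4], sn=[20, 40])
    vol = make_phantom(PhantomSpec(shape=shape, kind="gaussian_blobs", seed=seed))
    patch = Patch(origin=(0, 0, 0), size=shape[0], data=vol.data)
    tc = TrainConfig(epochs=epochs, seed=seed)
    return run_sweep(patch, axes, tc)
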
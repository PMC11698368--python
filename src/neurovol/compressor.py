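"""End-to-end training of the INR + SR pipeline and artifact serialization.

The forward path per optimization step: the patch is spectrally
downsampled once (outside the gradient path); the SIREN is evaluated on
the low-resolution coordinate grid; the SR decoder maps that grid back to
the patch resolution; the loss is the mean absolute error against the
original patch (optionally plus an auxiliary low-resolution term). Both
networks are updated jointly with Adam. Training is fully deterministic
for a fixed seed.

The compressed artifact stores both weight sets as float32, which defines
the payload size entering the bitrate/CR accounting (32 bits per weight).
The reconstruction reported with the artifact is recomputed from those
float32 weights, so decompression reproduces it bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor
from .inr_siren import SirenConfig, SirenModel, build_siren, coordinate_grid
from .metrics import MetricRecord, psnr, ssim
from .neural_sr import SRConfig, SRModel, build_sr
from .spectral_downsample import ScaleSpec, downsample
from .volume_io import Patch, Volume

__all__ = ["TrainConfig", "CompressedArtifact", "TrainHistory", "ChecksumError",
           "train_end_to_end", "decompress", "artifact_metrics",
           "save_artifact", "load_artifact"]

MAGIC = b"NVZ1"


class ChecksumError(IOError):
    """The artifact payload does not match its recorded digest."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.0015
    epochs: int = 5000
    seed: int = 0
    aux_lr_loss_weight: float = 0.0
    log_every: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate must be > 0 and epochs >= 1")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    psnr_db: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)
    final_reconstruction: np.ndarray | None = None

    def to_csv(self, path):
        with open(path, "w") as f:
            f.write("epoch,loss,psnr_db,ssim\n")
            for i, (l, p, s) in enumerate(zip(self.loss, self.psnr_db, self.ssim)):
                f.write(f"{i},{l:.8g},{p:.6g},{s:.8g}\n")


@dataclass
class CompressedArtifact:
    siren_config: SirenConfig
    sr_config: SRConfig
    scale: ScaleSpec
    siren_weights: np.ndarray          # float32 flat vector
    sr_weights: np.ndarray             # float32 flat vector
    normalization: tuple[float, float]
    patch_shape: tuple[int, int, int]
    bit_depth: int = 32
    provenance: dict = field(default_factory=dict)

    @property
    def total_params(self) -> int:
        return int(self.siren_weights.size + self.sr_weights.size)

    @property
    def total_bits(self) -> int:
        return self.total_params * self.bit_depth

    def lr_shape(self) -> tuple[int, int, int]:
        return self.scale.target_shape(self.patch_shape)


def _rebuild(artifact: CompressedArtifact) -> tuple[SirenModel, SRModel]:
    siren = build_siren(artifact.siren_config, seed=0)
    siren.load_flat_weights(artifact.siren_weights.astype(np.float64))
    sr = build_sr(artifact.sr_config, seed=0)
    sr.load_flat_weights(artifact.sr_weights.astype(np.float64))
    return siren, sr


def _reconstruct(siren: SirenModel, sr: SRModel, lr_shape, target_shape) -> np.ndarray:
    coords = coordinate_grid(lr_shape)
    lr_grid = siren.forward(coords).reshape(lr_shape)
    return sr.forward(lr_grid, target_shape).data


def train_end_to_end(patch: Patch, scale: ScaleSpec, siren_cfg: SirenConfig,
                     sr_cfg: SRConfig, tc: TrainConfig
                     ) -> tuple[CompressedArtifact, TrainHistory]:
    """Jointly fit the SIREN and SR decoder to one normalized patch."""
    target = np.asarray(patch.data, dtype=np.float64)
    shape = target.shape
    lr_vol = downsample(Volume(target), scale)
    lr_target = lr_vol.data
    lr_shape = lr_target.shape
    coords = coordinate_grid(lr_shape)

    siren = build_siren(siren_cfg, seed=tc.seed)
    siren.trained_on = lr_shape
    sr = build_sr(sr_cfg, seed=tc.seed + 1)
    opt = Adam(siren.parameters() + sr.parameters(), lr=tc.learning_rate)

    target_t = Tensor(target)
    lr_target_t = Tensor(lr_target)
    history = TrainHistory()
    for epoch in range(tc.epochs):
        opt.zero_grad()
        lr_grid = siren.forward(coords).reshape(lr_shape)
        recon = sr.forward(lr_grid, shape)
        loss = (recon - target_t).abs().mean()
        if tc.aux_lr_loss_weight > 0:
            loss = loss + tc.aux_lr_loss_weight * (lr_grid - lr_target_t).abs().mean()
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite loss {loss_val} at epoch {epoch} (lr={tc.learning_rate})")
        loss.backward()
        opt.step()
        if epoch % tc.log_every == 0 or epoch == tc.epochs - 1:
            history.loss.append(loss_val)
            history.psnr_db.append(psnr(target, recon.data))
            history.ssim.append(ssim(target, recon.data))

    siren_w = siren.flat_weights().astype(np.float32)
    sr_w = sr.flat_weights().astype(np.float32)
    lo, hi = patch_value_range(patch)
    artifact = CompressedArtifact(
        siren_config=siren_cfg, sr_config=sr_cfg, scale=scale,
        siren_weights=siren_w, sr_weights=sr_w,
        normalization=(lo, hi), patch_shape=shape,
        provenance={
            "train_config": asdict(tc),
            "loss_digest": hashlib.sha256(
                np.asarray(history.loss).tobytes()).hexdigest()[:16],
        })
    # final reconstruction from the stored (float32) weights: this is what
    # decompression reproduces bit-for-bit
    s2, r2 = _rebuild(artifact)
    history.final_reconstruction = _reconstruct(s2, r2, lr_shape, shape)
    return artifact, history


def patch_value_range(patch: Patch) -> tuple[float, float]:
    vr = getattr(patch, "value_range", None)
    if vr is not None:
        return vr
    return 0.0, 1.0


def decompress(artifact: CompressedArtifact, target_shape=None) -> Volume:
    """Reconstruct the volume from an artifact at the requested resolution.

    The SIREN is evaluated on the low-resolution grid implied by the
    stored scale, the SR decoder maps it to ``target_shape`` (default: the
    original patch shape), and intensities are mapped back to the raw
    value range recorded at compression time.
    """
    shape = tuple(target_shape) if target_shape is not None else artifact.patch_shape
    siren, sr = _rebuild(artifact)
    recon = _reconstruct(siren, sr, artifact.lr_shape(), shape)
    lo, hi = artifact.normalization
    return Volume(recon * (hi - lo) + lo, value_range=(lo, hi))


def artifact_metrics(artifact: CompressedArtifact, original: Patch) -> MetricRecord:
    """Bundle PSNR/SSIM/bitrate/CR/#params for an artifact vs its source.

    Quality metrics are computed in the normalized [0, 1] domain (MAX = 1).
    """
    target = np.asarray(original.data, dtype=np.float64)
    siren, sr = _rebuild(artifact)
    recon = _reconstruct(siren, sr, artifact.lr_shape(), target.shape)
    return MetricRecord.from_counts(
        psnr_db=psnr(target, recon), ssim_val=ssim(target, recon),
        n_params=artifact.total_params, n_voxels=int(np.prod(target.shape)),
        bit_depth=artifact.bit_depth)


# -- serialization -----------------------------------------------------------
#
# Container layout: MAGIC | u32 header length | JSON header | float32 payload
# (SIREN weights then SR weights, little endian) | 32-byte SHA-256 over
# everything before it.

def save_artifact(path, artifact: CompressedArtifact):
    header = {
        "version": 1,
        "siren_config": asdict(artifact.siren_config),
        "sr_config": asdict(artifact.sr_config),
        "scale": list(artifact.scale.s),
        "normalization": list(artifact.normalization),
        "patch_shape": list(artifact.patch_shape),
        "bit_depth": artifact.bit_depth,
        "n_siren": int(artifact.siren_weights.size),
        "n_sr": int(artifact.sr_weights.size),
        "provenance": artifact.provenance,
    }
    hbytes = json.dumps(header, sort_keys=True).encode()
    payload = (artifact.siren_weights.astype("<f4").tobytes()
               + artifact.sr_weights.astype("<f4").tobytes())
    body = MAGIC + struct.pack("<I", len(hbytes)) + hbytes + payload
    with open(path, "wb") as f:
        f.write(body + hashlib.sha256(body).digest())


def load_artifact(path) -> CompressedArtifact:
    blob = Path(path).read_bytes()
    if len(blob) < 40 or blob[:4] != MAGIC:
        raise IOError(f"{path}: not a neurovol artifact")
    body, digest = blob[:-32], blob[-32:]
    if hashlib.sha256(body).digest() != digest:
        raise ChecksumError(f"{path}: payload checksum mismatch")
    hlen = struct.unpack("<I", body[4:8])[0]
    header = json.loads(body[8:8 + hlen].decode())
    payload = body[8 + hlen:]
    n_siren, n_sr = header["n_siren"], header["n_sr"]
    weights = np.frombuffer(payload, dtype="<f4", count=n_siren + n_sr)
    sc = header["sr_config"]
    sc["upscale"] = tuple(sc["upscale"])
    return CompressedArtifact(
        siren_config=SirenConfig(**header["siren_config"]),
        sr_config=SRConfig(**sc),
        scale=ScaleSpec(tuple(header["scale"])),
        siren_weights=weights[:n_siren].copy(),
        sr_weights=weights[n_siren:].copy(),
        normalization=tuple(header["normalization"]),
        patch_shape=tuple(header["patch_shape"]),
        bit_depth=header["bit_depth"],
        provenance=header["provenance"])
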
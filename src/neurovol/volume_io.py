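"""Reading, writing, normalizing and patching 3-D volumes.

A :class:`Volume` is a rank-3 intensity grid plus spacing and value-range
metadata. Volumes come from NIfTI (via nibabel), NRRD (raw-encoding subset,
parsed here), or headerless raw grids with a JSON side-car descriptor.
Patching follows the preprocessing used for MRI compression experiments:
axis-aligned non-overlapping 64-cube tiles, with tiles containing at least
70 % non-zero voxels classified as high-resolution (HR) patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import nibabel as nib

__all__ = [
    "Volume", "Patch", "NoHRPatchError",
    "read_volume", "write_volume", "normalize", "denormalize",
    "extract_patches", "select_hr_patch", "save_patches_hdf5", "load_patches_hdf5",
]

DEFAULT_PATCH_SIZE = 64
DEFAULT_HR_THRESHOLD = 0.7


class NoHRPatchError(ValueError):
    """No patch reaches the high-resolution non-zero-fraction threshold."""


@dataclass
class Volume:
    """A rank-3 intensity grid with acquisition metadata.

    ``value_range`` records the raw intensity extremes before min-max
    normalization so that decompressed outputs can be mapped back.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] | None = None
    value_range: tuple[float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume payload must be rank-3, got rank {self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Patch:
    """A cubic tile of a parent volume (0-based corner index, half-open)."""

    origin: tuple[int, int, int]
    size: int
    data: np.ndarray
    nonzero_fraction: float = field(init=False)
    is_hr: bool = field(init=False, default=False)
    hr_threshold: float = DEFAULT_HR_THRESHOLD

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.nonzero_fraction = float(np.count_nonzero(self.data) / self.size ** 3)
        self.is_hr = self.nonzero_fraction >= self.hr_threshold


def _read_nrrd(path: Path) -> tuple[np.ndarray, dict]:
    """Minimal NRRD reader: raw encoding, single text header block."""
    with open(path, "rb") as f:
        blob = f.read()
    head, _, payload = blob.partition(b"\n\n")
    lines = head.decode("ascii").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise IOError(f"{path}: not an NRRD file")
    fields = {}
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        k, _, v = line.partition(":")
        fields[k.strip()] = v.strip()
    if fields.get("encoding", "raw") != "raw":
        raise IOError(f"{path}: only raw NRRD encoding is supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    # NRRD type names: "float" is 32-bit, "double" 64-bit
    type_map = {"float": "float32", "double": "float64"}
    tname = fields.get("type", "float")
    dtype = np.dtype(type_map.get(tname, tname))
    if fields.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    data = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    return data.reshape(sizes, order="F"), fields


def _write_nrrd(path: Path, vol: Volume):
    data = np.asarray(vol.data, dtype=np.float32)
    header = [
        "NRRD0004",
        f"type: float",
        f"dimension: {data.ndim}",
        f"sizes: {' '.join(str(s) for s in data.shape)}",
        "encoding: raw",
        "endian: little",
    ]
    if vol.spacing is not None:
        header.append(f"spacings: {' '.join(str(s) for s in vol.spacing)}")
    with open(path, "wb") as f:
        f.write(("\n".join(header) + "\n\n").encode("ascii"))
        f.write(data.tobytes(order="F"))


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith(".raw"):
        return "raw"
    raise IOError(f"cannot infer volume format from {path.name}")


def read_volume(path, format: str | None = None) -> Volume:
    """Read a 3-D volume from NIfTI, NRRD or raw+descriptor storage.

    Raw grids expect a side-car ``<stem>.json`` with keys ``shape``,
    ``dtype`` and optional ``order`` (default Fortran, matching scanners).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error text varies
            raise IOError(f"unreadable NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return Volume(np.asarray(data), spacing=spacing)
    if fmt == "nrrd":
        data, fields = _read_nrrd(path)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
        spacing = None
        if "spacings" in fields:
            spacing = tuple(float(s) for s in fields["spacings"].split())
        return Volume(data, spacing=spacing)
    if fmt == "raw":
        desc_path = path.with_suffix(".json")
        if not desc_path.exists():
            raise IOError(f"raw volume {path} is missing its descriptor {desc_path.name}")
        desc = json.loads(desc_path.read_text())
        shape = tuple(desc["shape"])
        if len(shape) != 3:
            raise ValueError(f"{path}: descriptor shape {shape} is not 3-D")
        data = np.fromfile(path, dtype=np.dtype(desc["dtype"]))
        data = data.reshape(shape, order=desc.get("order", "F"))
        spacing = tuple(desc["spacing"]) if "spacing" in desc else None
        return Volume(data, spacing=spacing)
    raise IOError(f"unknown volume format: {fmt}")


def write_volume(path, vol: Volume, format: str | None = None):
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        affine = np.diag(list(vol.spacing) + [1.0]) if vol.spacing else np.eye(4)
        nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))
    elif fmt == "nrrd":
        _write_nrrd(path, vol)
    elif fmt == "raw":
        data = np.asarray(vol.data, dtype=np.float32)
        data.tofile(path)  # C order, matching the descriptor below
        desc = {"shape": list(data.shape), "dtype": "float32", "order": "C"}
        if vol.spacing is not None:
            desc["spacing"] = list(vol.spacing)
        path.with_suffix(".json").write_text(json.dumps(desc))
    else:
        raise IOError(f"unknown volume format: {fmt}")


def normalize(vol: Volume) -> Volume:
    """Min-max scale intensities to [0, 1], recording the raw value range.

    A constant volume maps to all-zeros (the degenerate max == min case).
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains NaN or Inf voxels")
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        out = (data - lo) / (hi - lo)
    else:
        out = np.zeros_like(data)
    return Volume(out, spacing=vol.spacing, value_range=(lo, hi))


def denormalize(vol: Volume) -> Volume:
    """Invert :func:`normalize` using the recorded value range."""
    if vol.value_range is None:
        raise ValueError("volume has no recorded value_range")
    lo, hi = vol.value_range
    return Volume(vol.data * (hi - lo) + lo, spacing=vol.spacing)


def extract_patches(vol: Volume, size: int = DEFAULT_PATCH_SIZE,
                    policy: str = "tile_drop_partial",
                    hr_threshold: float = DEFAULT_HR_THRESHOLD) -> list[Patch]:
    """Tile a volume into non-overlapping cubes starting at index (0,0,0).

    ``tile_drop_partial`` discards incomplete edge tiles; ``tile_pad``
    zero-pads them to full size (padding counts as zero voxels in the
    non-zero fraction).
    """
    if policy not in ("tile_drop_partial", "tile_pad"):
        raise ValueError(f"unknown tiling policy {policy!r}")
    shape = vol.shape
    if any(size > s for s in shape):
        raise ValueError(f"patch size {size} exceeds volume shape {shape}")
    patches = []
    import math
    counts = [s // size if policy == "tile_drop_partial" else math.ceil(s / size)
              for s in shape]
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                o = (ix * size, iy * size, iz * size)
                block = vol.data[o[0]:o[0] + size, o[1]:o[1] + size, o[2]:o[2] + size]
                if block.shape != (size, size, size):
                    pad = [(0, size - s) for s in block.shape]
                    block = np.pad(block, pad)
                patches.append(Patch(origin=o, size=size, data=block,
                                     hr_threshold=hr_threshold))
    return patches


def select_hr_patch(patches: list[Patch], hr_threshold: float = DEFAULT_HR_THRESHOLD,
                    rule: str = "max_nonzero") -> Patch:
    """Pick one high-resolution patch (non-zero fraction >= threshold).

    ``max_nonzero`` takes the qualifying patch with the largest fraction
    (first in list order on ties); ``first`` takes the first qualifier.
    """
    if not patches:
        raise ValueError("empty patch list")
    if rule not in ("first", "max_nonzero"):
        raise ValueError(f"unknown HR selection rule {rule!r}")
    qualifiers = [p for p in patches if p.nonzero_fraction >= hr_threshold]
    if not qualifiers:
        raise NoHRPatchError(
            f"no HR patch: best non-zero fraction "
            f"{max(p.nonzero_fraction for p in patches):.3f} < {hr_threshold}")
    if rule == "first":
        return qualifiers[0]
    return max(qualifiers, key=lambda p: p.nonzero_fraction)


def save_patches_hdf5(path, patches: list[Patch]):
    """Store a patch list as an HDF5 container with per-patch origin attrs."""
    with h5py.File(path, "w") as f:
        for i, p in enumerate(patches):
            ds = f.create_dataset(f"patch_{i:04d}", data=p.data)
            ds.attrs["origin"] = p.origin
            ds.attrs["size"] = p.size
            ds.attrs["hr_threshold"] = p.hr_threshold


def load_patches_hdf5(path) -> list[Patch]:
    patches = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            ds = f[name]
            patches.append(Patch(origin=tuple(int(o) for o in ds.attrs["origin"]),
                                 size=int(ds.attrs["size"]), data=ds[()],
                                 hr_threshold=float(ds.attrs["hr_threshold"])))
    return patches
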
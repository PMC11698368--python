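"""Rate-distortion trade-off selection over the configuration sweep.

Every combination of downsampling scale (DS), SR feature channels (NC)
and SIREN neurons per layer (SN) yields one metric bundle; the complete
3-axis grid is the sweep. The selected configuration minimizes

    1/PSNR + (1 - |SSIM|) + (1 - CR)          (CR as a fraction)

subject to corner constraints c1: x = DS_max, c2: y = NC_min,
c3: z = SN_min, solved with an Augmented Lagrangian:

    argmin  obj - sum_i alpha_i c_i + (beta/2) sum_i c_i^2

Axis values are min-max normalized to [0, 1] before the residuals c_i are
formed, so the penalty is commensurate with the objective. The multipliers
are updated at the incumbent argmin (alpha_i <- alpha_i - beta c_i) for a
fixed number of rounds; selection over the finite grid is exhaustive each
round, with a lexicographic (ds, nc, sn) index tie-break.

Marginal curves reduce a transformed metric (1/PSNR, 1-|SSIM|, 1-CR) over
the two complementary axes; the default reduction is the mean. Note one
quirk of the published summary table this fixture reproduces: its first
two column headers are swapped relative to the marginal semantics (the
mean over the DS = 1/2 slice appears under the NC = 4 header and vice
versa); the implementation defines marginals by the computation.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from .metrics import MetricRecord
from .volume_io import Patch

__all__ = ["SweepAxes", "SweepGrid", "TradeoffSpec", "TradeoffPoint", "MarginalCurve",
           "objective", "tradeoff_point", "marginal", "run_sweep", "load_table_fixture"]

METRIC_TRANSFORMS = ("inv_psnr", "one_minus_ssim", "one_minus_cr")
AXES = ("DS", "NC", "SN")


@dataclass(frozen=True)
class SweepAxes:
    ds: list[float]
    nc: list[int]
    sn: list[int]

    def __post_init__(self):
        for name, ax in (("ds", self.ds), ("nc", self.nc), ("sn", self.sn)):
            if not ax:
                raise ValueError(f"axis {name} is empty")
            if sorted(ax) != list(ax) or len(set(ax)) != len(ax):
                raise ValueError(f"axis {name} must be strictly sorted: {ax}")


@dataclass
class SweepGrid:
    axes: SweepAxes
    cells: dict[tuple[float, int, int], MetricRecord] = field(default_factory=dict)
    failures: list[tuple[tuple, str]] = field(default_factory=list)

    def validate_complete(self):
        missing = [key for key in self.keys() if key not in self.cells]
        if missing:
            raise ValueError(f"incomplete sweep grid; missing cells: {missing}")

    def keys(self):
        for d in self.axes.ds:
            for n in self.axes.nc:
                for s in self.axes.sn:
                    yield (d, n, s)

    def to_json(self, path):
        payload = {
            "axes": {"ds": self.axes.ds, "nc": self.axes.nc, "sn": self.axes.sn},
            "cells": [
                {"ds": k[0], "nc": k[1], "sn": k[2], **asdict(v)}
                for k, v in self.cells.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        grid = cls(axes=SweepAxes(**payload["axes"]))
        for c in payload["cells"]:
            key = (c.pop("ds"), c.pop("nc"), c.pop("sn"))
            grid.cells[key] = MetricRecord(**c)
        return grid


@dataclass(frozen=True)
class TradeoffSpec:
    ds_max: float | None = None    # least aggressive retained scale (largest s)
    nc_min: int | None = None
    sn_min: int | None = None
    alpha: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beta: float = 1.0
    iterations: int = 10

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class TradeoffPoint:
    ds: float
    nc: int
    sn: int
    objective_value: float
    marginal_bounds: dict[str, dict[str, float]]
    alpha_final: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class MarginalCurve:
    axis: str
    metric: str
    ticks: list
    values: list[float]
    reduction: str = "mean"


def _transform(cell: MetricRecord, metric: str) -> float:
    if metric == "inv_psnr":
        if not cell.psnr_db > 0:
            raise ValueError(f"PSNR must be positive, got {cell.psnr_db}")
        return 0.0 if np.isinf(cell.psnr_db) else 1.0 / cell.psnr_db
    if metric == "one_minus_ssim":
        return 1.0 - abs(cell.ssim)
    if metric == "one_minus_cr":
        return 1.0 - cell.cr_fraction
    raise ValueError(f"unknown metric transform {metric!r}")


def objective(cell: MetricRecord) -> float:
    """Composite rate-distortion objective; lower is better."""
    return sum(_transform(cell, m) for m in METRIC_TRANSFORMS)


def _norm_axis(values: list) -> dict:
    vals = [float(v) for v in values]
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return {v: 0.0 for v in values}
    return {v: (float(v) - lo) / (hi - lo) for v in values}


def tradeoff_point(grid: SweepGrid, spec: TradeoffSpec | None = None) -> TradeoffPoint:
    """Select the trade-off configuration by Augmented-Lagrangian scan.

    Each round exhaustively evaluates the augmented objective at every
    grid cell (ties broken lexicographically on axis indices), then
    updates the multipliers at the incumbent. The result of the final
    round is returned.
    """
    grid.validate_complete()
    spec = spec or TradeoffSpec()
    ax = grid.axes
    ds_max = spec.ds_max if spec.ds_max is not None else max(ax.ds)
    nc_min = spec.nc_min if spec.nc_min is not None else min(ax.nc)
    sn_min = spec.sn_min if spec.sn_min is not None else min(ax.sn)
    for val, axis, name in ((ds_max, ax.ds, "ds_max"), (nc_min, ax.nc, "nc_min"),
                            (sn_min, ax.sn, "sn_min")):
        if val not in axis:
            raise ValueError(f"{name}={val} is not a tick of its axis {axis}")
    nds, nnc, nsn = _norm_axis(ax.ds), _norm_axis(ax.nc), _norm_axis(ax.sn)
    corner = (nds[ds_max], nnc[nc_min], nsn[sn_min])
    base = {key: objective(grid.cells[key]) for key in grid.keys()}
    residual = {key: (nds[key[0]] - corner[0], nnc[key[1]] - corner[1],
                      nsn[key[2]] - corner[2]) for key in base}

    alpha = np.asarray(spec.alpha, dtype=float)
    incumbent = None
    for _ in range(spec.iterations):
        best, best_val = None, np.inf
        for key in grid.keys():       # lexicographic order -> first-hit tie-break
            c = residual[key]
            val = (base[key] - float(alpha @ c)
                   + 0.5 * spec.beta * float(np.dot(c, c)))
            if val < best_val - 1e-15:
                best, best_val = key, val
        incumbent = best
        alpha = alpha - spec.beta * np.asarray(residual[incumbent])

    bounds = {}
    tick_of = {"DS": incumbent[0], "NC": incumbent[1], "SN": incumbent[2]}
    for axis in AXES:
        curves = {m: marginal(grid, m, axis) for m in METRIC_TRANSFORMS}
        bounds[axis] = {m: curves[m].values[curves[m].ticks.index(tick_of[axis])]
                        for m in METRIC_TRANSFORMS}
    return TradeoffPoint(ds=incumbent[0], nc=incumbent[1], sn=incumbent[2],
                         objective_value=base[incumbent], marginal_bounds=bounds,
                         alpha_final=tuple(alpha))


def marginal(grid: SweepGrid, metric: str, axis: str,
             reduction: str = "mean") -> MarginalCurve:
    """Reduce a transformed metric over the two complementary axes."""
    grid.validate_complete()
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    ticks = {"DS": grid.axes.ds, "NC": grid.axes.nc, "SN": grid.axes.sn}[axis]
    pos = AXES.index(axis)
    values = []
    for tick in ticks:
        vals = [_transform(cell, metric) for key, cell in grid.cells.items()
                if key[pos] == tick]
        values.append(float(np.mean(vals) if reduction == "mean" else np.sum(vals)))
    return MarginalCurve(axis=axis, metric=metric, ticks=list(ticks),
                         values=values, reduction=reduction)


def _cell_cache_key(patch_digest: str, key, siren_layers, tc) -> str:
    blob = json.dumps({"patch": patch_digest, "cell": list(key),
                       "layers": siren_layers, "tc": asdict(tc)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:24]


def run_sweep(patch: Patch, axes: SweepAxes, train_cfg,
              siren_layers: int = 3, cache_dir=None) -> SweepGrid:
    """Train one end-to-end model per (DS, NC, SN) combination.

    Completed cells are cached as JSON under ``cache_dir`` (keyed by patch
    digest + configuration) and skipped on rerun. A cell whose training
    aborts is recorded as a failure and the sweep continues.
    """
    from .compressor import artifact_metrics, train_end_to_end
    from .inr_siren import SirenConfig
    from .neural_sr import SRConfig
    from .spectral_downsample import ScaleSpec

    grid = SweepGrid(axes=axes)
    digest = hashlib.sha256(np.ascontiguousarray(patch.data).tobytes()).hexdigest()[:16]
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for key in grid.keys():
        ds, nc, sn = key
        cpath = cache / f"{_cell_cache_key(digest, key, siren_layers, train_cfg)}.json" \
            if cache else None
        if cpath is not None and cpath.exists():
            grid.cells[key] = MetricRecord(**json.loads(cpath.read_text()))
            continue
        try:
            scale = ScaleSpec.isotropic(ds)
            upscale = tuple(int(round(1 / ds)) for _ in range(3))
            artifact, _ = train_end_to_end(
                patch, scale, SirenConfig(layers=siren_layers, neurons=sn),
                SRConfig(channels=nc, upscale=upscale), train_cfg)
            rec = artifact_metrics(artifact, patch)
        except (FloatingPointError, ValueError) as exc:
            grid.failures.append((key, str(exc)))
            continue
        grid.cells[key] = rec
        if cpath is not None:
            cpath.write_text(json.dumps(asdict(rec)))
    return grid


_SCALE_STR = {"1/2": 0.5, "1/4": 0.25, "1/8": 0.125}


def load_table_fixture() -> SweepGrid:
    """The packaged 99-row published sweep (NC x DS x SN) as a SweepGrid."""
    with resources.files("neurovol.data").joinpath("sweep_table.csv").open() as f:
        rows = list(csv.DictReader(f))
    ds_axis = sorted({_SCALE_STR[r["scale"]] for r in rows})
    nc_axis = sorted({int(r["nc"]) for r in rows})
    sn_axis = sorted({int(r["neurons"]) for r in rows})
    grid = SweepGrid(axes=SweepAxes(ds=ds_axis, nc=nc_axis, sn=sn_axis))
    for r in rows:
        key = (_SCALE_STR[r["scale"]], int(r["nc"]), int(r["neurons"]))
        grid.cells[key] = MetricRecord(
            psnr_db=float(r["psnr_db"]), ssim=float(r["ssim"]),
            bitrate_bpp=float(r["bitrate_bpp"]), cr_percent=float(r["cr_percent"]),
            n_params=int(r["n_params"]), gpu_mem=float(r["gpu_mem_gb"]))
    grid.validate_complete()
    return grid


def load_siren_table() -> list[dict]:
    """The packaged 44-row published INR-only table (layers x neurons)."""
    with resources.files("neurovol.data").joinpath("siren_table.csv").open() as f:
        return [{k: (float(v) if "." in v or k in ("bitrate_bpp", "cr_percent",
                                                   "psnr_db", "ssim") else int(v))
                 for k, v in row.items()} for row in csv.DictReader(f)]
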
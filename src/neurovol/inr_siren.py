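"""Sinusoidal implicit neural representation (SIREN) of a 3-D volume.

The volume is encoded as the weights of a coordinate MLP mapping
(x, y, z) in [-1, 1]^3 to intensity. A configuration with L layers and n
neurons per hidden layer realizes L+1 affine maps — the input map 3 -> n,
L-1 hidden maps n -> n, and a linear output map n -> 1 — for a total of

    (L - 1) n^2 + (L + 4) n + 1

trainable weights (biases included). All layers but the last apply a sine
activation; the first layer is scaled by the frequency omega0 (default 30),
with the standard SIREN initialization (first layer uniform +-1/in_dim,
later layers uniform +-sqrt(6/fan_in)/omega0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor

__all__ = ["SirenConfig", "SirenModel", "count_params", "coordinate_grid",
           "build_siren", "evaluate"]


@dataclass(frozen=True)
class SirenConfig:
    layers: int = 3
    neurons: int = 30
    omega0: float = 30.0
    in_dim: int = 3
    out_dim: int = 1

    def __post_init__(self):
        if self.layers < 1 or self.neurons < 1:
            raise ValueError("layers and neurons must be >= 1")


def count_params(cfg: SirenConfig) -> int:
    """Closed-form trainable-weight count of the realized network.

    input map: in_dim*n + n; (L-1) hidden maps: n^2 + n each;
    output map: n*out_dim + out_dim. For in_dim=3, out_dim=1 this is
    (L-1) n^2 + (L+4) n + 1.
    """
    n, L = cfg.neurons, cfg.layers
    return (cfg.in_dim * n + n) + (L - 1) * (n * n + n) + (n * cfg.out_dim + cfg.out_dim)


def coordinate_grid(shape) -> np.ndarray:
    """Raster-ordered coordinate triples spanning [-1, 1] inclusive per axis.

    An axis of extent 1 is sampled at its midpoint 0. Returns (prod(shape), 3).
    """
    axes = [np.linspace(-1.0, 1.0, d) if d > 1 else np.zeros(1) for d in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


@dataclass
class SirenModel:
    config: SirenConfig
    weights: list[tuple[Tensor, Tensor]]   # (W, b) per affine map, W is (fan_in, fan_out)
    trained_on: tuple[int, int, int] | None = None

    @property
    def n_params(self) -> int:
        return sum(W.data.size + b.data.size for W, b in self.weights)

    def parameters(self) -> list[Tensor]:
        return [t for pair in self.weights for t in pair]

    def forward(self, coords: np.ndarray) -> Tensor:
        """Differentiable forward pass; coords is (N, 3)."""
        h = Tensor(np.asarray(coords, dtype=np.float64))
        W, b = self.weights[0]
        h = ((h @ W + b) * self.config.omega0).sin()
        for W, b in self.weights[1:-1]:
            h = (h @ W + b).sin()
        W, b = self.weights[-1]
        return h @ W + b

    def flat_weights(self) -> np.ndarray:
        return np.concatenate([t.data.ravel() for pair in self.weights for t in pair])

    def load_flat_weights(self, flat: np.ndarray):
        pos = 0
        for pair in self.weights:
            for t in pair:
                n = t.data.size
                t.data = np.asarray(flat[pos:pos + n], dtype=np.float64).reshape(t.data.shape)
                pos += n
        if pos != flat.size:
            raise ValueError("weight vector length does not match the architecture")


def build_siren(cfg: SirenConfig, seed: int = 0) -> SirenModel:
    """Construct a SIREN with the standard sine-aware initialization."""
    rng = np.random.default_rng(seed)
    dims = [cfg.in_dim] + [cfg.neurons] * cfg.layers + [cfg.out_dim]
    weights = []
    for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
        if i == 0:
            bound = 1.0 / fan_in
        else:
            bound = np.sqrt(6.0 / fan_in) / cfg.omega0
        W = Tensor(rng.uniform(-bound, bound, (fan_in, fan_out)), requires_grad=True)
        # biases keep the framework-default range: phase diversity across
        # neurons matters for sine networks far more than small magnitudes
        b_bound = 1.0 / np.sqrt(fan_in)
        b = Tensor(rng.uniform(-b_bound, b_bound, fan_out), requires_grad=True)
        weights.append((W, b))
    model = SirenModel(config=cfg, weights=weights)
    assert model.n_params == count_params(cfg)
    return model


def evaluate(model: SirenModel, coords: np.ndarray, shape=None) -> np.ndarray:
    """Evaluate the representation at arbitrary coordinates (no gradients).

    Coordinates outside [-1, 1]^3 trigger an extrapolation warning but are
    evaluated anyway — the representation is a globally defined function.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if np.any(np.abs(coords) > 1.0 + 1e-12):
        import warnings
        warnings.warn("coordinates outside [-1, 1]^3: extrapolating", stacklevel=2)
    out = model.forward(coords).data[:, 0]
    return out.reshape(shape) if shape is not None else out
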
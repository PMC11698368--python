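"""Attention-based continuous 3-D super-resolution decoder.

In the neural-operator view of super-resolution, a discretized volume is a
sample of an underlying function; the decoder learns a mapping between
function spaces and can therefore be queried at any target resolution.
The pipeline is:

1. **Shallow features** — one same-size 3-D convolution lifts the
   low-resolution grid to NC channels.
2. **Galerkin attention** — a softmax-free linear attention block: keys
   and values are normalized per channel across tokens, aggregated as
   (K^T V)/N (a channels x channels matrix), applied to the queries and
   projected back with a residual connection. Cost is linear in voxel
   count, yet equals the explicit N x N attention product by associativity.
3. **Continuous decode** — for every target-grid coordinate, trilinearly
   sample the feature grid, concatenate the sub-voxel offset and a
   per-axis scale token, and decode through a small MLP to one intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, conv3d, trilinear_sample

__all__ = ["SRConfig", "SRModel", "build_sr", "shallow_features",
           "galerkin_attention", "continuous_decode", "count_sr_params"]

_EPS = 1e-5


@dataclass(frozen=True)
class SRConfig:
    channels: int = 4                 # NC, feature-extractor width
    upscale: tuple[int, int, int] = (2, 2, 2)
    attention_width: int | None = None  # default 4 * NC
    attention_blocks: int = 1
    decoder_hidden: int = 64
    kernel: int = 3
    padding: str = "zeros"

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")

    @property
    def aw(self) -> int:
        return self.attention_width if self.attention_width is not None else 4 * self.channels


@dataclass
class SRModel:
    config: SRConfig
    conv_w: Tensor
    conv_b: Tensor
    attn: list[dict]        # per block: Wq, Wk, Wv, Wo, bo
    dec_w1: Tensor
    dec_b1: Tensor
    dec_w2: Tensor
    dec_b2: Tensor

    def parameters(self) -> list[Tensor]:
        ps = [self.conv_w, self.conv_b]
        for blk in self.attn:
            ps += [blk["Wq"], blk["Wk"], blk["Wv"], blk["Wo"], blk["bo"]]
        ps += [self.dec_w1, self.dec_b1, self.dec_w2, self.dec_b2]
        return ps

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def flat_weights(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.parameters()])

    def load_flat_weights(self, flat: np.ndarray):
        pos = 0
        for p in self.parameters():
            n = p.data.size
            p.data = np.asarray(flat[pos:pos + n], dtype=np.float64).reshape(p.data.shape)
            pos += n
        if pos != flat.size:
            raise ValueError("weight vector length does not match the architecture")

    def forward(self, lr: Tensor | np.ndarray, target_shape) -> Tensor:
        feats = shallow_features(lr, self)
        for blk in self.attn:
            feats = galerkin_attention(feats, self, blk)
        return continuous_decode(feats, target_shape, model=self)


def _uniform(rng, fan_in, shape):
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)


def build_sr(cfg: SRConfig, seed: int = 0) -> SRModel:
    rng = np.random.default_rng(seed)
    nc, aw, k = cfg.channels, cfg.aw, cfg.kernel
    conv_w = _uniform(rng, k ** 3, (nc, 1, k, k, k))
    conv_b = Tensor(np.zeros(nc), requires_grad=True)
    attn = []
    for _ in range(cfg.attention_blocks):
        attn.append({
            "Wq": _uniform(rng, nc, (nc, aw)),
            "Wk": _uniform(rng, nc, (nc, aw)),
            "Wv": _uniform(rng, nc, (nc, aw)),
            "Wo": _uniform(rng, aw, (aw, nc)),
            "bo": Tensor(np.zeros(nc), requires_grad=True),
        })
    din = nc + 6  # features + relative offset (3) + scale token (3)
    dec_w1 = _uniform(rng, din, (din, cfg.decoder_hidden))
    dec_b1 = Tensor(np.zeros(cfg.decoder_hidden), requires_grad=True)
    dec_w2 = _uniform(rng, cfg.decoder_hidden, (cfg.decoder_hidden, 1))
    dec_b2 = Tensor(np.zeros(1), requires_grad=True)
    return SRModel(config=cfg, conv_w=conv_w, conv_b=conv_b, attn=attn,
                   dec_w1=dec_w1, dec_b1=dec_b1, dec_w2=dec_w2, dec_b2=dec_b2)


def shallow_features(lr: Tensor | np.ndarray, model: SRModel) -> Tensor:
    """Lift a rank-3 low-resolution grid to an NC-channel feature grid."""
    x = lr if isinstance(lr, Tensor) else Tensor(np.asarray(lr, dtype=np.float64))
    if x.ndim != 3:
        raise ValueError(f"expected a rank-3 grid, got rank {x.ndim}")
    x4 = x.reshape((1,) + x.shape)
    return conv3d(x4, model.conv_w, model.conv_b, padding=model.config.padding)


def _channel_norm(t: Tensor) -> Tensor:
    """Normalize each channel to zero mean / unit variance across tokens."""
    mu = t.mean(axis=0, keepdims=True)
    centered = t - mu
    var = (centered * centered).mean(axis=0, keepdims=True)
    return centered * (var + _EPS) ** -0.5


def galerkin_attention(features: Tensor, model: SRModel, block: dict | None = None) -> Tensor:
    """Softmax-free linear attention over the voxel tokens of a feature grid.

    features: (NC, dx, dy, dz). Keys and values are channel-normalized, the
    attention matrix (K^T V)/N is formed in channel space, applied to the
    queries, projected, and added back residually. Output shape equals the
    input shape.
    """
    blk = block if block is not None else model.attn[0]
    nc = features.shape[0]
    spatial = features.shape[1:]
    N = int(np.prod(spatial))
    tokens = features.reshape((nc, N)).T                 # (N, NC)
    Q = tokens @ blk["Wq"]
    K = _channel_norm(tokens @ blk["Wk"])
    V = _channel_norm(tokens @ blk["Wv"])
    A = (K.T @ V) * (1.0 / N)                            # (aw, aw)
    out = (Q @ A) @ blk["Wo"] + blk["bo"]                # (N, NC)
    return (tokens + out).T.reshape((nc,) + spatial)


def continuous_decode(features: Tensor | np.ndarray, target_shape,
                      scale=None, model: SRModel | None = None) -> Tensor:
    """Decode a feature grid to an arbitrary target resolution.

    For each target voxel center (endpoint-inclusive [-1, 1] grid) the
    feature grid is sampled trilinearly in its own index space; the decoder
    MLP sees the sampled features, the fractional offset to the nearest
    source voxel, and the per-axis scale ratio as a scale token.
    """
    f = features if isinstance(features, Tensor) else Tensor(np.asarray(features))
    src_shape = f.shape[1:]
    ratio = tuple(t / s for t, s in zip(target_shape, src_shape))
    if scale is not None:
        given = tuple(float(s) for s in (scale if np.iterable(scale) else (scale,) * 3))
        if any(abs(g - r) > 1e-9 for g, r in zip(given, ratio)):
            raise ValueError(f"upscale {given} inconsistent with "
                             f"{src_shape} -> {tuple(target_shape)} (ratio {ratio})")
    if model is None:
        raise ValueError("continuous_decode requires an SRModel for its decoder")
    # target coordinates in the source grid's index space
    idx_axes = []
    for t, s in zip(target_shape, src_shape):
        c = np.linspace(-1.0, 1.0, t) if t > 1 else np.zeros(1)
        idx_axes.append((c + 1.0) / 2.0 * (s - 1))
    gi, gj, gk = np.meshgrid(*idx_axes, indexing="ij")
    idx = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1)     # (N, 3)
    feat_cl = f.reshape((f.shape[0], -1)).T.reshape(tuple(src_shape) + (f.shape[0],))
    sampled = trilinear_sample(feat_cl, idx)                          # (N, NC)
    rel = idx - np.round(idx)                                         # in [-0.5, 0.5]
    scale_tok = np.broadcast_to(np.asarray(ratio), (idx.shape[0], 3))
    dec_in = concat([sampled, Tensor(rel), Tensor(scale_tok)], axis=1)
    h = (dec_in @ model.dec_w1 + model.dec_b1).relu()
    out = h @ model.dec_w2 + model.dec_b2
    return out.reshape(tuple(target_shape))


def count_sr_params(cfg: SRConfig) -> int:
    """Exact realized trainable-weight count for a configuration."""
    return build_sr(cfg, seed=0).n_params
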
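"""Multiview spatial-temporal graph convolutional network for CPR quality
assessment.

One five-block STGCN encoder per camera view turns a normalised pose stream
(T x N x 4: coordinates plus detection confidence) into a pooled feature
vector; the per-view vectors are fused by a softmax over learnable scalar
logits, and a two-layer fully connected head regresses the six checklist
item scores (hand, arm, shoulder, depth, rate, release), each on the 0-4
scale.

Each block applies a per-frame graph convolution ``A_hat X_t W`` over the
skeleton, a kernel-9 temporal convolution per joint, batch normalisation and
a ReLU, with a residual connection whenever input and output shapes agree.
The network is pure NumPy; backpropagation is hand-written in
:mod:`cpraqa.nn` and validated against finite differences.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (Adam, BatchNorm, Dense, GlobalAvgPool, InputNorm, Param,
                 ReLU, SpatialGraphConv, TemporalConv)
from .skeleton import SkeletonGraph, normalized_adjacency

__all__ = [
    "ITEM_NAMES", "ModelConfig", "MultiviewSTGCN", "spatial_graph_conv",
    "fuse_views", "mae_loss", "small_model_config",
]

ITEM_NAMES = ("hand", "arm", "shoulder", "depth", "rate", "release")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``channels`` gives the channel plan through the five blocks (first entry
    is the input width, normally 4); ``strides`` the temporal stride of each
    block.  ``views`` are the camera ids the model consumes — cameras 1, 4
    and 5 by default, the frontal/side subset raters predominantly used.
    """

    views: tuple[str, ...] = ("1", "4", "5")
    channels: tuple[int, ...] = (4, 64, 64, 128, 128, 256)
    strides: tuple[int, ...] = (1, 1, 2, 1, 2)
    temporal_kernel: int = 9
    head_hidden: int = 128
    n_items: int = 6
    clamp: tuple[float, float] = (0.0, 4.0)
    input_norm: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if len(self.strides) != len(self.channels) - 1:
            raise ValueError("need one stride per block")


def small_model_config(**overrides) -> ModelConfig:
    """Reduced-width configuration for CPU-scale experiments and tests."""
    kw = dict(channels=(4, 8, 8, 16, 16, 32), head_hidden=64)
    kw.update(overrides)
    return ModelConfig(**kw)


def spatial_graph_conv(x: np.ndarray, a_hat: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-frame graph convolution ``out_t = A_hat @ X_t @ W``.

    ``x`` is (T, N, C_in) or batched (B, T, N, C_in); ``a_hat`` the
    normalised adjacency; ``w`` the channel-mixing weights (C_in, C_out).
    """
    x = np.asarray(x)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(f"channel mismatch: {x.shape[-1]} vs {w.shape[0]}")
    if x.shape[-2] != a_hat.shape[0]:
        raise ValueError("joint count does not match adjacency")
    return np.matmul(a_hat, x @ w)


def mae_loss(pred: np.ndarray, y: np.ndarray) -> float:
    """Sum over items of |pred - y|; for a batch, the mean over samples."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {y.shape}")
    per_sample = np.abs(pred - y).sum(axis=-1)
    return float(np.mean(per_sample))


def fuse_views(features: dict[str, np.ndarray], alpha: dict[str, float]) -> np.ndarray:
    """Softmax(alpha)-weighted sum of per-view pooled feature vectors.

    Only views present in ``features`` enter the softmax, so a single view
    passes through unchanged.
    """
    if not features:
        raise ValueError("no views to fuse")
    keys = sorted(features)
    a = np.array([alpha[k] for k in keys], dtype=float)
    a = a - a.max()
    w = np.exp(a)
    w /= w.sum()
    return sum(w[i] * np.asarray(features[k]) for i, k in enumerate(keys))


class _Block:
    """spatial conv -> temporal conv -> batchnorm -> ReLU, plus residual
    when shapes permit."""

    def __init__(self, a_hat, c_in, c_out, kernel, stride, rng, dtype):
        self.sgc = SpatialGraphConv(a_hat, c_in, c_out, rng, dtype)
        self.tconv = TemporalConv(c_out, c_out, kernel, stride, rng, dtype)
        self.bn = BatchNorm(c_out, dtype)
        self.relu = ReLU()
        self.residual = (c_in == c_out and stride == 1)
        self.layers = [self.sgc, self.tconv, self.bn, self.relu]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def set_mode(self, train):
        for l in self.layers:
            l.set_mode(train)

    def forward(self, x):
        h = x
        for l in self.layers:
            h = l.forward(h)
        return h + x if self.residual else h

    def backward(self, g):
        gh = g
        for l in reversed(self.layers):
            gh = l.backward(gh)
        return gh + g if self.residual else gh


class _ViewEncoder:
    def __init__(self, a_hat, cfg: ModelConfig, rng, dtype):
        ch = cfg.channels
        self.inorm = InputNorm(a_hat.shape[0], ch[0], dtype) if cfg.input_norm else None
        self.blocks = [
            _Block(a_hat, ch[i], ch[i + 1], cfg.temporal_kernel, cfg.strides[i],
                   rng, dtype)
            for i in range(len(ch) - 1)
        ]
        self.pool = GlobalAvgPool()

    def params(self):
        ps = list(self.inorm.params()) if self.inorm else []
        return ps + [p for b in self.blocks for p in b.params()]

    def set_mode(self, train):
        if self.inorm:
            self.inorm.set_mode(train)
        for b in self.blocks:
            b.set_mode(train)

    def forward(self, x):
        h = self.inorm.forward(x) if self.inorm else x
        for b in self.blocks:
            h = b.forward(h)
        return self.pool.forward(h)

    def backward(self, g):
        gh = self.pool.backward(g)
        for b in reversed(self.blocks):
            gh = b.backward(gh)
        if self.inorm:
            gh = self.inorm.backward(gh)
        return gh


class MultiviewSTGCN:
    """The full assessment network: per-view STGCN encoders, learnable
    softmax fusion, two-layer regression head."""

    def __init__(self, config: ModelConfig, graph: SkeletonGraph, seed: int = 0):
        self.config = config
        self.graph = graph
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        a_hat = normalized_adjacency(graph).astype(self.dtype)
        self.encoders = {v: _ViewEncoder(a_hat, config, rng, self.dtype)
                         for v in config.views}
        # zero logits: uniform view weighting at initialisation
        self.alpha = Param(np.zeros(len(config.views), dtype=self.dtype), "fusion.alpha")
        f = config.channels[-1]
        self.head1 = Dense(f, config.head_hidden, rng, self.dtype)
        self.head_relu = ReLU()
        self.head2 = Dense(config.head_hidden, config.n_items, rng, self.dtype)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        ps = []
        for v in self.config.views:
            ps.extend(self.encoders[v].params())
        ps.append(self.alpha)
        ps.extend(self.head1.params())
        ps.extend(self.head2.params())
        return ps

    def set_mode(self, train: bool):
        for e in self.encoders.values():
            e.set_mode(train)
        for l in (self.head1, self.head_relu, self.head2):
            l.set_mode(train)

    # -- forward / backward -------------------------------------------------
    def encode_view(self, view: str, x: np.ndarray) -> np.ndarray:
        """Pooled feature vector for one view; x is (B, T, N, C)."""
        return self.encoders[view].forward(np.asarray(x, dtype=self.dtype))

    def _fusion_weights(self, present: list[str]) -> np.ndarray:
        idx = [self.config.views.index(v) for v in present]
        a = self.alpha.value[idx].astype(float)
        a = a - a.max()
        w = np.exp(a)
        return (w / w.sum()).astype(self.dtype)

    def forward(self, xs: dict[str, np.ndarray], clamp: bool = False) -> np.ndarray:
        present = sorted(set(xs) & set(self.config.views))
        if not present:
            raise ValueError("no configured views present in input")
        feats = {v: self.encode_view(v, xs[v]) for v in present}
        w = self._fusion_weights(present)
        fused = sum(w[i] * feats[v] for i, v in enumerate(present))
        h = self.head1.forward(fused)
        hr = self.head_relu.forward(h)
        pred = self.head2.forward(hr)
        self._cache = (present, feats, w, fused)
        if clamp:
            lo, hi = self.config.clamp
            pred = np.clip(pred, lo, hi)
        return pred

    def predict(self, xs: dict[str, np.ndarray]) -> np.ndarray:
        """Inference-mode prediction, clamped to the score range."""
        self.set_mode(False)
        try:
            return self.forward(xs, clamp=True)
        finally:
            self.set_mode(True)

    def loss_and_grad(self, xs: dict[str, np.ndarray], y: np.ndarray) -> float:
        """Batch MAE loss; accumulates parameter gradients."""
        pred = self.forward(xs, clamp=False)
        y = np.asarray(y, dtype=pred.dtype)
        loss = mae_loss(pred, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        B = pred.shape[0]
        g = (np.sign(pred - y) / B).astype(pred.dtype)
        gh = self.head2.backward(g)
        gh = self.head_relu.backward(gh)
        gfused = self.head1.backward(gh)
        present, feats, w, _ = self._cache
        # softmax fusion backward
        s = np.array([float((gfused * feats[v]).sum()) for v in present])
        sbar = float((w * s).sum())
        for i, v in enumerate(present):
            gi = self.config.views.index(v)
            self.alpha.grad[gi] += w[i] * (s[i] - sbar)
            self.encoders[v].backward(w[i] * gfused)
        return loss

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.params()):
            out[f"param_{i:04d}"] = p.value
        j = 0
        for v in self.config.views:
            enc = self.encoders[v]
            norms = ([enc.inorm] if enc.inorm else []) + [b.bn for b in enc.blocks]
            for nl in norms:
                out[f"bn_{j:04d}_mean"] = nl.run_mean
                out[f"bn_{j:04d}_var"] = nl.run_var
                j += 1
        return out

    def save(self, path):
        """Single-file checkpoint: config JSON + parameter arrays."""
        buf = io.BytesIO()
        np.savez(buf, **self.state_arrays())
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("config.json", json.dumps(asdict(self.config)))
            z.writestr("graph.json", json.dumps({
                "joint_names": list(self.graph.joint_names),
                "edges": sorted(map(list, self.graph.edges)),
            }))
            z.writestr("state.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "MultiviewSTGCN":
        with zipfile.ZipFile(path) as z:
            cfg = json.loads(z.read("config.json"))
            gj = json.loads(z.read("graph.json"))
            state = np.load(io.BytesIO(z.read("state.npz")))
            for k in ("views", "channels", "strides", "clamp"):
                cfg[k] = tuple(cfg[k])
            graph = SkeletonGraph(tuple(gj["joint_names"]),
                                  frozenset(map(tuple, gj["edges"])))
            m = cls(ModelConfig(**cfg), graph)
            for i, p in enumerate(m.params()):
                p.value[...] = state[f"param_{i:04d}"]
            j = 0
            for v in m.config.views:
                enc = m.encoders[v]
                norms = ([enc.inorm] if enc.inorm else []) + [b.bn for b in enc.blocks]
                for nl in norms:
                    nl.run_mean[...] = state[f"bn_{j:04d}_mean"]
                    nl.run_var[...] = state[f"bn_{j:04d}_var"]
                    j += 1
            return m

    def make_optimizer(self, lr: float = 0.01, weight_decay: float = 0.1,
                       **kw) -> Adam:
        return Adam(self.params(), lr=lr, weight_decay=weight_decay, **kw)
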
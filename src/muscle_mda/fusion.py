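"""Multi-scale attentional feature fusion (MS-AFF) across view channels.

The V per-view embedding stacks are fused through a channel-attention gate
built from two contexts:

* local — a point-wise-convolution bottleneck (V -> r -> V channels, 1x1
  kernels, batch-normalized with a ReLU between the stages) that mixes the
  V channel values independently at every (node, feature) position;
* global — global average pooling of each channel to a single scalar.

The sigmoid of their broadcast sum gates each channel, and the gated
channels are reduced (summed by default) to one N x d matrix.  Alternative
fusion strategies used by the ablation experiments — channel mean (ave),
elementwise product (dot), concatenation (cat), local-only gating (lf) and
a one-layer symmetric-normalized graph convolution followed by mean fusion
(gcn, an approximation) — are selectable through the same interface.

Channel normalization uses the statistics of the full stack at every
forward pass; because the stack covers the entire transductive node set,
training and inference see identical statistics and no running averages are
needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor, glorot
from .gat import ViewEmbeddingStack

logger = logging.getLogger(__name__)

STRATEGIES = ("msaff", "ave", "dot", "cat", "lf", "gcn")

_BN_EPS = 1e-5


class FusionParams:
    """Trainable parameters of the point-wise bottleneck.

    ``normalize=False`` bypasses both normalization stages, which makes the
    bottleneck act independently at every (node, feature) position — the
    closed-form configuration used by the unit fixtures.
    """

    def __init__(self, n_views: int, r: int = 1, normalize: bool = True,
                 rng: Optional[np.random.Generator] = None):
        if r < 1:
            raise ValueError(f"bottleneck width must be >= 1, got {r}")
        if r > n_views:
            warnings.warn(f"bottleneck width r={r} exceeds channel count V={n_views}: "
                          "no channel reduction", stacklevel=2)
        rng = rng or np.random.default_rng(0)
        self.n_views = n_views
        self.r = r
        self.normalize = normalize
        self.w1 = glorot(rng, n_views, r, r, n_views)   # channel reduction
        self.b1 = Tensor(np.zeros((r, 1)), requires_grad=True)
        self.w2 = glorot(rng, r, n_views, n_views, r)   # channel increase
        self.b2 = Tensor(np.zeros((n_views, 1)), requires_grad=True)
        self.gamma1 = Tensor(np.ones((r, 1)), requires_grad=True)
        self.beta1 = Tensor(np.zeros((r, 1)), requires_grad=True)
        self.gamma2 = Tensor(np.ones((n_views, 1)), requires_grad=True)
        self.beta2 = Tensor(np.zeros((n_views, 1)), requires_grad=True)

    def tensors(self) -> List[Tensor]:
        out = [self.w1, self.b1, self.w2, self.b2]
        if self.normalize:
            out += [self.gamma1, self.beta1, self.gamma2, self.beta2]
        return out


@dataclass(frozen=True)
class FusedFeatures:
    """Fused N x d features and the per-(view, position) sigmoid gates."""

    X_prime: np.ndarray
    gates: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.X_prime).all():
            raise ValueError("fused features contain non-finite values")
        if not ((self.gates > 0) & (self.gates < 1)).all():
            raise ValueError("gates must lie strictly inside (0, 1)")


def _channel_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Normalize each channel (row) over all positions, then affine."""
    mu = x.mean(axis=1, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=1, keepdims=True)
    return gamma * ((x - mu) / (var + _BN_EPS).sqrt()) + beta


def _as_array(X: ViewEmbeddingStack | np.ndarray) -> np.ndarray:
    return X.X if isinstance(X, ViewEmbeddingStack) else np.asarray(X, dtype=float)


def local_context_t(X: Tensor, params: FusionParams) -> Tensor:
    v, n, d = X.shape
    flat = X.reshape(v, n * d)
    h = params.w1 @ flat + params.b1
    if params.normalize:
        h = _channel_norm(h, params.gamma1, params.beta1)
    h = h.relu()
    h = params.w2 @ h + params.b2
    if params.normalize:
        h = _channel_norm(h, params.gamma2, params.beta2)
    return h.reshape(v, n, d)


def local_context(X: ViewEmbeddingStack | np.ndarray, params: FusionParams) -> np.ndarray:
    """Bottleneck local channel context L(X), same (V, N, d) shape as X."""
    return local_context_t(Tensor(_as_array(X)), params).data


def global_context_t(X: Tensor) -> Tensor:
    v = X.shape[0]
    return X.mean(axis=(1, 2)).reshape(v, 1, 1)


def global_context(X: ViewEmbeddingStack | np.ndarray) -> np.ndarray:
    """Global average pool of each channel: a length-V vector."""
    arr = _as_array(X)
    if arr.size == 0:
        raise ValueError("cannot pool an empty embedding stack")
    return global_context_t(Tensor(arr)).data.reshape(-1)


def fuse_t(X: Tensor, params: FusionParams, reduce: str = "sum") -> tuple[Tensor, Tensor]:
    """Differentiable MS-AFF fusion; returns (X', gates)."""
    gates = (local_context_t(X, params) + global_context_t(X)).sigmoid()
    gated = X * gates
    if reduce == "sum":
        fused = gated.sum(axis=0)
    elif reduce == "mean":
        fused = gated.mean(axis=0)
    else:
        raise ValueError(f"unknown reduction {reduce!r}")
    return fused, gates


def fuse(X: ViewEmbeddingStack | np.ndarray, params: FusionParams,
         reduce: str = "sum") -> FusedFeatures:
    """Gate each channel by sigmoid(local + global context) and reduce.

    The printed channel-attention product keeps V channels; reducing over
    the view axis (sum by default, mean optionally) yields the N x d fused
    matrix the classifier consumes.
    """
    arr = _as_array(X)
    fused, gates = fuse_t(Tensor(arr), params, reduce=reduce)
    return FusedFeatures(fused.data, gates.data)


class FusionModule:
    """Strategy-dispatching fusion layer over a (V, N, d) stack.

    ``propagators`` supplies, for the gcn strategy only, one symmetric-
    normalized N x N propagation matrix per view (the view adjacency plus
    self-loops, restricted to the kept miRNA+disease rows).
    """

    def __init__(self, n_views: int, strategy: str = "msaff", r: int = 1,
                 reduce: str = "sum", normalize: bool = True,
                 seed: int = 0,
                 propagators: Optional[Sequence[np.ndarray]] = None,
                 d: Optional[int] = None):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown fusion strategy {strategy!r}")
        self.strategy = strategy
        self.reduce = reduce
        self.n_views = n_views
        rng = np.random.default_rng(seed)
        self.params = (FusionParams(n_views, r=r, normalize=normalize, rng=rng)
                       if strategy in ("msaff", "lf") else None)
        self.propagators = ([np.asarray(p, dtype=float) for p in propagators]
                            if propagators is not None else None)
        self.gcn_weight: Optional[Tensor] = None
        if strategy == "gcn":
            if self.propagators is None or len(self.propagators) != n_views:
                raise ValueError("gcn strategy needs one propagator per view")
            if d is not None:
                self.gcn_weight = glorot(rng, d, d)

    def output_width(self, d: int) -> int:
        return d * self.n_views if self.strategy == "cat" else d

    def forward(self, X: Tensor) -> Tensor:
        v, n, d = X.shape
        if self.strategy == "msaff":
            fused, _ = fuse_t(X, self.params, reduce=self.reduce)
            return fused
        if self.strategy == "lf":
            gates = local_context_t(X, self.params).sigmoid()
            gated = X * gates
            return gated.sum(axis=0) if self.reduce == "sum" else gated.mean(axis=0)
        if self.strategy == "ave":
            return X.mean(axis=0)
        if self.strategy == "dot":
            out = X.gather_rows([0]).reshape(n, d)
            for k in range(1, v):
                out = out * X.gather_rows([k]).reshape(n, d)
            return out
        if self.strategy == "cat":
            return X.transpose(1, 0, 2).reshape(n, v * d)
        # gcn: one symmetric-normalized propagation per view, shared linear
        # map, then mean fusion (documented approximation)
        if self.gcn_weight is None:
            self.gcn_weight = glorot(np.random.default_rng(1), d, d)
        outs = []
        for k in range(v):
            xk = X.gather_rows([k]).reshape(n, d)
            outs.append(Tensor(self.propagators[k]) @ (xk @ self.gcn_weight))
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        return (acc * (1.0 / v)).elu()

    def parameters(self) -> List[Tensor]:
        if self.params is not None:
            return self.params.tensors()
        if self.strategy == "gcn":
            # ensure the weight exists before the optimizer snapshots params
            if self.gcn_weight is None:
                raise RuntimeError("call forward once (or set d) before parameters()")
            return [self.gcn_weight]
        return []


def normalized_propagator(A: np.ndarray, keep_rows: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} restricted to ``keep_rows`` (gcn strategy)."""
    Ah = np.asarray(A, dtype=float) + np.eye(A.shape[0])
    deg = Ah.sum(axis=1)
    inv = 1.0 / np.sqrt(deg)
    S = Ah * inv[:, None] * inv[None, :]
    return S[np.ix_(keep_rows, keep_rows)]
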
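"""Per-view graph attention encoders.

Every heterogeneous view gets its own multi-head graph attention network
(separate parameters per view).  Node features start from a seeded standard
normal and are themselves trainable; L attention layers aggregate
neighborhood messages with softmax attention coefficients

    alpha_ij = softmax_{j in N_i} LeakyReLU(a^T [W x_i || W x_j]),

heads are concatenated and passed through an ELU, and a final linear
projection sizes the embedding to the configured dimension d.  The miRNA
and disease rows are then extracted from each view and stacked into the
(V, n_m + n_d, d) tensor consumed by the fusion module.

Self-loops are added to every adjacency before attention so isolated nodes
keep their own (transformed) features instead of hitting an empty softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, concat, glorot, stack
from .graphs import ViewAdjacency


@dataclass
class GatConfig:
    """Architecture hyperparameters for one view's encoder.

    ``embed_dim`` is the per-node output dimension d after the final
    projection; ``None`` means half the number of stacked miRNA+disease
    rows, mirroring the 1778 -> 889 relation between the stacked node count
    and the fusion input feature dimension.
    """

    feature_dim: int = 128          # F: trainable input feature width
    hidden: int = 64                # F': per-head output width
    heads: int = 4                  # Phi
    layers: int = 2                 # L
    leaky_slope: float = 0.2
    dropout: float = 0.0  # on layer inputs and attention coefficients
    embed_dim: Optional[int] = None  # d (None -> (n_m + n_d) // 2)
    early_stop_tol: Optional[float] = None  # optional embedding-drift stop
    trainable_features: bool = True  # learn x0 jointly (False: fixed random)


@dataclass
class GatParams:
    """One attention layer: per-head weight matrices and attention vectors."""

    W: List[Tensor]          # each F_in x F'
    a: List[Tensor]          # each 2F'
    leaky_slope: float = 0.2

    @property
    def heads(self) -> int:
        return len(self.W)

    @classmethod
    def init(cls, rng: np.random.Generator, f_in: int, f_out: int, heads: int,
             leaky_slope: float = 0.2) -> "GatParams":
        return cls(
            W=[glorot(rng, f_in, f_out) for _ in range(heads)],
            a=[glorot(rng, 2 * f_out, 1, 2 * f_out) for _ in range(heads)],
            leaky_slope=leaky_slope,
        )

    def tensors(self) -> List[Tensor]:
        return [*self.W, *self.a]


def _masked_softmax(e_src: Tensor, e_dst: Tensor, mask: np.ndarray,
                    slope: float) -> Tensor:
    """Fused row-softmax of LeakyReLU(e_src_i + e_dst_j) over the mask.

    A single graph node with a custom backward: only the coefficient matrix
    and the pre-activation sign pattern are retained, so an epoch's graph
    stays small even with dense (n, n) attention.
    """
    raw = e_src.data + e_dst.data.T             # (n, n)
    pos = raw > 0
    logits = np.where(pos, raw, slope * raw)
    masked = np.where(mask > 0, logits, -np.inf)
    rowmax = masked.max(axis=1, keepdims=True)
    rowmax = np.where(np.isfinite(rowmax), rowmax, 0.0)
    exps = np.exp(logits - rowmax) * mask
    denom = exps.sum(axis=1, keepdims=True)
    alpha_val = exps / (denom + (denom == 0.0))  # isolated rows stay all-zero
    out = Tensor(alpha_val, parents=(e_src, e_dst))

    def bwd(g: np.ndarray) -> None:
        g_logits = alpha_val * (g - (g * alpha_val).sum(axis=1, keepdims=True))
        g_raw = np.where(pos, g_logits, slope * g_logits)
        if e_src.requires_grad:
            e_src._accumulate(g_raw.sum(axis=1, keepdims=True))
        if e_dst.requires_grad:
            e_dst._accumulate(g_raw.sum(axis=0)[:, None])

    out._backward = bwd
    return out


def _attention_t(x: Tensor, W: Tensor, a: Tensor, mask: np.ndarray,
                 slope: float) -> Tuple[Tensor, Tensor]:
    """Differentiable (alpha, Wx) for one head on a dense neighbor mask."""
    h = x @ W                                   # (n, F')
    f_out = W.shape[1]
    a_src = a.gather_rows(range(f_out)).reshape(f_out, 1)
    a_dst = a.gather_rows(range(f_out, 2 * f_out)).reshape(f_out, 1)
    e_src = h @ a_src                           # (n, 1)
    e_dst = h @ a_dst                           # (n, 1)
    return _masked_softmax(e_src, e_dst, mask, slope), h


def attention_coefficients(
    x: np.ndarray,
    params: GatParams,
    A: ViewAdjacency | np.ndarray,
    head: int = 0,
) -> np.ndarray:
    """Dense attention coefficient matrix for one head.

    Rows of non-isolated nodes sum to 1 over their neighborhood; isolated
    nodes (no neighbors in ``A``) get an all-zero row rather than an
    undefined softmax.
    """
    mask = (A.A if isinstance(A, ViewAdjacency) else np.asarray(A)).astype(float)
    alpha, _ = _attention_t(Tensor(x), params.W[head], params.a[head], mask,
                            params.leaky_slope)
    return alpha.data


def _dropout(t: Tensor, p: float, rng: Optional[np.random.Generator]) -> Tensor:
    if rng is None or p <= 0:
        return t
    keep = (rng.random(t.shape) >= p) / (1 - p)
    return t * keep


def _gat_layer_t(x: Tensor, params: GatParams, mask: np.ndarray,
                 activation: str = "elu", dropout: float = 0.0,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
    x = _dropout(x, dropout, rng)
    heads_out = []
    for W, a in zip(params.W, params.a):
        alpha, h = _attention_t(x, W, a, mask, params.leaky_slope)
        heads_out.append(_dropout(alpha, dropout, rng) @ h)
    out = concat(heads_out, axis=1)
    if activation == "elu":
        return out.elu()
    if activation == "identity":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def gat_layer(
    x: np.ndarray,
    params: GatParams,
    A: ViewAdjacency | np.ndarray,
    activation: str = "elu",
) -> np.ndarray:
    """One multi-head attention layer: concat over heads of the aggregated
    messages, then the activation.  Output width is heads * F'."""
    mask = (A.A if isinstance(A, ViewAdjacency) else np.asarray(A)).astype(float)
    return _gat_layer_t(Tensor(x), params, mask, activation).data


@dataclass(frozen=True)
class ViewEmbeddingStack:
    """(V, N, d) stack of per-view embeddings for the N = n_m + n_d nodes.

    miRNA rows come first, disease rows second, in the same shared order in
    every channel; mediator rows have already been discarded.
    """

    X: np.ndarray
    views: Tuple[str, ...]
    mirna_ids: Tuple[str, ...]
    disease_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        v, n, _ = self.X.shape
        if v != len(self.views):
            raise ValueError("channel count does not match view list")
        if n != len(self.mirna_ids) + len(self.disease_ids):
            raise ValueError("row count does not match miRNA + disease ids")


class ViewEncoder:
    """Trainable GAT encoder for a single view adjacency."""

    def __init__(self, view: ViewAdjacency, config: GatConfig, embed_dim: int,
                 rng: np.random.Generator):
        n = view.n_nodes
        self.view_tag = view.view
        self.dropout = config.dropout
        self.mask = view.A.astype(float) + np.eye(n)  # self-loops
        self.x0 = Tensor(rng.standard_normal((n, config.feature_dim)),
                         requires_grad=config.trainable_features)
        self.layers: List[GatParams] = []
        f_in = config.feature_dim
        for _ in range(config.layers):
            self.layers.append(
                GatParams.init(rng, f_in, config.hidden, config.heads,
                               config.leaky_slope)
            )
            f_in = config.hidden * config.heads
        self.proj = glorot(rng, f_in, embed_dim)
        # miRNA rows are the leading block, disease rows the trailing block
        idx = view.index
        off = idx.offsets()
        self.keep_rows = np.concatenate([
            np.arange(off["miRNA"], off["miRNA"] + idx.n_mirna),
            np.arange(off["disease"], off["disease"] + idx.n_disease),
        ])

    def forward(self, rng: Optional[np.random.Generator] = None) -> Tensor:
        x = self.x0
        for params in self.layers:
            x = _gat_layer_t(x, params, self.mask, dropout=self.dropout, rng=rng)
        x = x @ self.proj
        return x.gather_rows(self.keep_rows)

    def parameters(self) -> List[Tensor]:
        out = [self.x0]
        for layer in self.layers:
            out.extend(layer.tensors())
        out.append(self.proj)
        return out


class MultiViewGatEncoder:
    """Separate GAT encoders for every active view, stacked into one tensor."""

    def __init__(self, views: Sequence[ViewAdjacency], config: GatConfig,
                 seed: int = 123):
        if not views:
            raise ValueError("at least one view is required")
        first = views[0].index
        for v in views[1:]:
            if (v.index.mirnas, v.index.diseases) != (first.mirnas, first.diseases):
                raise ValueError("views disagree on the miRNA/disease index")
        self.mirna_ids = first.mirnas
        self.disease_ids = first.diseases
        n_stacked = len(self.mirna_ids) + len(self.disease_ids)
        self.embed_dim = config.embed_dim or max(1, n_stacked // 2)
        rng = np.random.default_rng(seed)
        self.encoders = [ViewEncoder(v, config, self.embed_dim, rng) for v in views]
        self.view_tags = tuple(v.view for v in views)

    def forward(self, rng: Optional[np.random.Generator] = None) -> Tensor:
        return stack([enc.forward(rng) for enc in self.encoders], axis=0)

    def parameters(self) -> List[Tensor]:
        return [p for enc in self.encoders for p in enc.parameters()]

    def stack(self) -> ViewEmbeddingStack:
        return ViewEmbeddingStack(
            self.forward().data, self.view_tags, self.mirna_ids, self.disease_ids
        )


def encode_views(
    views: Sequence[ViewAdjacency],
    config: Optional[GatConfig] = None,
    seed: int = 123,
) -> ViewEmbeddingStack:
    """Encode every view with freshly initialized GATs (no training).

    Deterministic under ``seed``: identical seeds give bit-identical stacks.
    """
    enc = MultiViewGatEncoder(views, config or GatConfig(), seed=seed)
    return enc.stack()
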
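"""End-to-end association model, cross-validation harness and metrics.

The public surface follows the statsmodels convention: :class:`MuscleModel`
is built from the raw inputs (sequences, ontology, per-view edge lists, a
labelled pair dataset and a :class:`TrainConfig`); ``fit()`` trains the GAT
encoders, the fusion gate and the MLP head jointly by Adam on binary
cross-entropy and returns a :class:`MuscleResults` carrying the fitted
scores, the loss trace and a ``summary()``.  :func:`run_cv` repeats the fit
over stratified folds and aggregates a :class:`CVResults` table.

Leakage control: the view graphs never contain a miRNA-disease edge, and
the GIP kernels (the only feature derived from the labels) are recomputed
inside every fold from the training positives alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, Tensor, concat, glorot
from .features import (
    AttributeMatrix,
    SimilarityMatrix,
    gip_kernel,
    integrate_disease,
    integrate_mirna,
    kmer_matrix,
    semantic_similarity_matrices,
)
from .fusion import FusionModule, normalized_propagator
from .gat import GatConfig, MultiViewGatEncoder
from .graphs import EntityIndex, ViewAdjacency, build_single_hetero_graph, build_view
from .io_formats import DagEdges, EdgeList, SequenceRecord

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]

#: mediator role -> view tag
ROLE_VIEW = {"drug": "MDD", "mRNA": "MMD", "lncRNA": "MLD"}

ALL_FEATURES = frozenset({"attr", "drug", "mRNA", "lncRNA"})


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainConfig:
    """Hyperparameters of one training/evaluation experiment."""

    k: int = 3
    delta: float = 0.5
    gamma_prime: float = 1.0
    clip_dss: bool = True
    epochs: int = 200
    lr: float = 1e-3
    lr_decay: str = "none"  # "none" | "cosine" (decay to 10% of lr)
    ema_decay: Optional[float] = None  # Polyak-average weights for prediction
    weight_decay: float = 0.0
    seed: int = 123
    folds: int = 5
    mlp_layers: int = 4
    mlp_widths: Optional[Tuple[int, ...]] = None  # None -> halve from input
    dropout: float = 0.3
    embed_dropout: float = 0.0  # dropout on the fused topology blocks
    feature_set: frozenset = ALL_FEATURES
    fusion_strategy: str = "msaff"
    fusion_reduce: str = "sum"
    fusion_r: int = 1
    single_graph: bool = False
    negative_mode: str = "once"  # or "per-fold"
    gat: GatConfig = field(default_factory=GatConfig)

    def __post_init__(self) -> None:
        if self.folds not in (5, 10):
            raise ValueError(f"folds must be 5 or 10, got {self.folds}")
        self.feature_set = frozenset(self.feature_set)
        if not self.feature_set:
            raise ValueError("feature_set must be non-empty")
        unknown = self.feature_set - ALL_FEATURES
        if unknown:
            raise ValueError(f"unknown feature_set entries {sorted(unknown)}")

    @property
    def active_mediators(self) -> List[str]:
        return [r for r in ("drug", "mRNA", "lncRNA") if r in self.feature_set]


# ---------------------------------------------------------------------------
# dataset


@dataclass(frozen=True)
class AssociationDataset:
    """Balanced labelled miRNA-disease pairs with fold assignments."""

    pairs: Tuple[Pair, ...]
    labels: np.ndarray
    fold_assignments: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.pairs)


def sample_negatives(
    positives: Set[Pair],
    mirnas: Sequence[str],
    diseases: Sequence[str],
    n: int,
    seed: int | np.random.Generator = 0,
) -> List[Pair]:
    """Uniform sample of n non-associated pairs, disjoint from the positives.

    Sampling is without replacement over the full miRNA x disease grid and
    reproducible under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_m, n_d = len(mirnas), len(diseases)
    pos_flat = np.array(
        sorted(mirnas.index(m) * n_d + diseases.index(d) for m, d in positives
               if m in mirnas and d in diseases),
        dtype=np.int64,
    ) if positives else np.empty(0, dtype=np.int64)
    candidates = np.setdiff1d(np.arange(n_m * n_d, dtype=np.int64), pos_flat)
    if len(candidates) < n:
        raise ValueError(
            f"cannot sample {n} negatives from {len(candidates)} non-associated pairs"
        )
    chosen = rng.choice(candidates, size=n, replace=False)
    return [(mirnas[int(c) // n_d], diseases[int(c) % n_d]) for c in np.sort(chosen)]


def kfold_split(labels: np.ndarray, folds: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (one test-fold index per pair)."""
    labels = np.asarray(labels)
    if folds > len(labels):
        raise ValueError("more folds than samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assign = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assign[test_idx] = f
    return assign


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics at 0.5 plus ranking metrics for one evaluation."""

    auc: float
    aupr: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    f1: float

    FIELDS = ("auc", "aupr", "accuracy", "sensitivity", "specificity",
              "precision", "mcc", "f1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])


def _auc_midrank(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank-sum (Mann-Whitney) identity, midranks for ties."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _aupr_step(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-integrated area under the precision-recall curve."""
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # evaluate at the last index of every tied-score group
    last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    precision = tps[last] / (tps[last] + fps[last])
    recall = tps[last] / tps[-1]
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Full metric suite from labels and predicted scores.

    AUC uses midrank tie handling (Mann-Whitney identity); AUPR uses
    step integration over the precision-recall curve; the remaining metrics
    come from the confusion matrix at the threshold.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("metrics need at least one positive and one negative")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / mcc_den) if mcc_den else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return MetricsReport(
        auc=_auc_midrank(y, s),
        aupr=_aupr_step(y, s),
        accuracy=acc, sensitivity=sens, specificity=spec,
        precision=prec, mcc=float(mcc), f1=f1,
    )


def build_pair_features(
    fused,
    dm: AttributeMatrix,
    dd: SimilarityMatrix,
    pair: Pair,
    feature_set: frozenset = ALL_FEATURES,
) -> np.ndarray:
    """Classifier input vector for one miRNA-disease pair.

    Concatenation order: fused miRNA row, DM row, fused disease row, DD row.
    ``fused`` is the N x d fused topology matrix (miRNA rows first) or a
    :class:`~muscle_mda.fusion.FusedFeatures`; ``None`` (or an attr-only
    feature set) drops the topology blocks, mirroring the ablation modes.
    """
    m, d = pair
    if m not in dm.ids:
        raise KeyError(f"miRNA id {m!r} unknown")
    if d not in dd.ids:
        raise KeyError(f"disease id {d!r} unknown")
    mi = dm.ids.index(m)
    di = dd.ids.index(d)
    use_topo = fused is not None and (feature_set & {"drug", "mRNA", "lncRNA"})
    use_attr = "attr" in feature_set
    X = getattr(fused, "X_prime", fused)
    blocks: List[np.ndarray] = []
    if use_topo:
        blocks.append(X[mi])
    if use_attr:
        blocks.append(dm.values[mi])
    if use_topo:
        blocks.append(X[len(dm.ids) + di])
    if use_attr:
        blocks.append(dd.values[di])
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# MLP head


class Mlp:
    """Fully connected classifier head with halving hidden widths."""

    def __init__(self, in_dim: int, n_layers: int, dropout: float,
                 rng: np.random.Generator,
                 widths: Optional[Tuple[int, ...]] = None):
        self.dropout = dropout
        if widths is not None:
            if len(widths) != n_layers:
                raise ValueError(f"{len(widths)} widths for {n_layers} hidden layers")
            widths = list(widths)
        else:
            widths = []
            w = in_dim
            for _ in range(n_layers):
                w = max(w // 2, 4)
                widths.append(w)
        self.weights: List[Tensor] = []
        self.biases: List[Tensor] = []
        prev = in_dim
        for w in widths + [1]:
            self.weights.append(glorot(rng, prev, w))
            self.biases.append(Tensor(np.zeros(w), requires_grad=True))
            prev = w

    def forward(self, x: Tensor, rng: Optional[np.random.Generator] = None) -> Tensor:
        """Logits; pass an rng to enable (inverted) dropout during training."""
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            x = (x @ self.weights[i] + self.biases[i]).relu()
            if rng is not None and self.dropout > 0:
                keep = (rng.random(x.shape) >= self.dropout) / (1 - self.dropout)
                x = x * keep
        z = x @ self.weights[-1] + self.biases[-1]
        return z.reshape(z.shape[0])

    def parameters(self) -> List[Tensor]:
        return [*self.weights, *self.biases]


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    zabs = z.relu() + (-z).relu()
    return (z.relu() - z * y + ((-zabs).exp() + 1.0).log()).mean()


# ---------------------------------------------------------------------------
# the model


@dataclass(frozen=True)
class ModelInputs:
    """Raw inputs the model is built from (real files or a synthetic world)."""

    sequences: Tuple[SequenceRecord, ...]
    dag: DagEdges
    view_edges: Dict[str, Tuple[EdgeList, EdgeList]]  # role -> (m-x, x-d)
    mirnas: Tuple[str, ...]
    diseases: Tuple[str, ...]


class MuscleModel:
    """Multi-view attentional association model over one labelled dataset.

    Parameters
    ----------
    inputs : ModelInputs
        Sequences, ontology and the per-view edge lists.
    dataset : AssociationDataset
        Balanced positive/negative miRNA-disease pairs.
    config : TrainConfig
        All training and architecture hyperparameters.
    """

    def __init__(self, inputs: ModelInputs, dataset: AssociationDataset,
                 config: Optional[TrainConfig] = None):
        self.inputs = inputs
        self.dataset = dataset
        self.config = config or TrainConfig()
        self.mirnas = tuple(sorted(inputs.mirnas))
        self.diseases = tuple(sorted(inputs.diseases))
        self._m_pos = {m: i for i, m in enumerate(self.mirnas)}
        self._d_pos = {d: i for i, d in enumerate(self.diseases)}
        for m, d in dataset.pairs:
            if m not in self._m_pos:
                raise KeyError(f"miRNA id {m!r} not covered by the model inputs")
            if d not in self._d_pos:
                raise KeyError(f"disease id {d!r} not covered by the model inputs")
        cfg = self.config
        # label-independent features, computed once
        self._sm = kmer_matrix(
            [s for s in inputs.sequences if s.id in self._m_pos], k=cfg.k
        )
        if self._sm.ids != self.mirnas:
            order = {i: n for n, i in enumerate(self._sm.ids)}
            rows = np.array([order[m] for m in self.mirnas])
            self._sm = AttributeMatrix("SM", self.mirnas, self._sm.values[rows])
        self._dss1, self._dss2, self._sem_mask = semantic_similarity_matrices(
            inputs.dag, list(self.diseases), delta=cfg.delta, clip=cfg.clip_dss
        )
        self._views = self._build_views()

    # -- graph assembly ----------------------------------------------------

    def _build_views(self) -> List[ViewAdjacency]:
        cfg = self.config
        roles = [r for r in cfg.active_mediators if r in self.inputs.view_edges]
        if not roles:
            return []
        if cfg.single_graph:
            mediators = {
                r: self._mediator_ids(*self.inputs.view_edges[r]) for r in roles
            }
            index = EntityIndex.build(self.mirnas, self.diseases, mediators)
            edge_lists = [e for r in roles for e in self.inputs.view_edges[r]]
            return [build_single_hetero_graph(edge_lists, index)]
        views = []
        for role in roles:
            e_mx, e_xd = self.inputs.view_edges[role]
            index = EntityIndex.build(
                self.mirnas, self.diseases, {role: self._mediator_ids(e_mx, e_xd)}
            )
            views.append(build_view(e_mx, e_xd, ROLE_VIEW[role], index))
        return views

    @staticmethod
    def _mediator_ids(e_mx: EdgeList, e_xd: EdgeList) -> List[str]:
        role = e_xd.source_type
        ids = {t if e_mx.target_type == role else s for s, t in e_mx.pairs}
        ids |= {s for s, _ in e_xd.pairs}
        return sorted(ids)

    # -- per-fit feature assembly ------------------------------------------

    def _fold_attributes(
        self, train_pairs: Sequence[Pair], train_labels: np.ndarray
    ) -> Tuple[AttributeMatrix, SimilarityMatrix]:
        """DM and DD with GIP kernels from the training positives only."""
        G = np.zeros((len(self.mirnas), len(self.diseases)))
        for (m, d), y in zip(train_pairs, train_labels):
            if y == 1:
                G[self._m_pos[m], self._d_pos[d]] = 1.0
        km = gip_kernel(G, self.mirnas, "KM", self.config.gamma_prime)
        kd = gip_kernel(G.T, self.diseases, "KD", self.config.gamma_prime)
        dm = integrate_mirna(self._sm, km)
        dd = integrate_disease(self._dss1, self._dss2, kd, self._sem_mask)
        return dm, dd

    def _pair_rows(self, pairs: Sequence[Pair]) -> Tuple[np.ndarray, np.ndarray]:
        mi = np.array([self._m_pos[m] for m, _ in pairs])
        di = np.array([self._d_pos[d] for _, d in pairs])
        return mi, di

    # -- fitting -----------------------------------------------------------

    def fit(self, train_idx: Optional[np.ndarray] = None) -> "MuscleResults":
        """Jointly train encoders, fusion and MLP on the (sub)dataset.

        ``train_idx`` selects the training pairs (default: all).  Returns a
        results object able to score arbitrary pairs.
        """
        cfg = self.config
        if train_idx is None:
            train_idx = np.arange(len(self.dataset))
        pairs = [self.dataset.pairs[i] for i in train_idx]
        y = self.dataset.labels[train_idx].astype(float)
        dm, dd = self._fold_attributes(pairs, y)
        use_attr = "attr" in cfg.feature_set
        use_views = bool(self._views)
        rng = np.random.default_rng(cfg.seed)

        encoder = fusion = None
        d_embed = 0
        if use_views:
            encoder = MultiViewGatEncoder(self._views, cfg.gat, seed=cfg.seed)
            d_embed = encoder.embed_dim
            propagators = None
            if cfg.fusion_strategy == "gcn":
                propagators = [
                    normalized_propagator(v.A, enc.keep_rows)
                    for v, enc in zip(self._views, encoder.encoders)
                ]
            if len(self._views) == 1:
                fusion = None  # single view/SHG: use the channel directly
            else:
                fusion = FusionModule(
                    len(self._views), strategy=cfg.fusion_strategy,
                    r=cfg.fusion_r, reduce=cfg.fusion_reduce,
                    seed=cfg.seed, propagators=propagators, d=d_embed,
                )
        topo_width = 0
        if use_views:
            topo_width = d_embed * (len(self._views)
                                    if cfg.fusion_strategy == "cat" and fusion else 1)
        width = 2 * topo_width + (dm.width + dd.values.shape[1] if use_attr else 0)
        mlp = Mlp(width, cfg.mlp_layers, cfg.dropout, rng, widths=cfg.mlp_widths)

        params = list(mlp.parameters())
        if encoder is not None:
            params += encoder.parameters()
        if fusion is not None:
            params += fusion.parameters()
        opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

        mi, di = self._pair_rows(pairs)
        n_m = len(self.mirnas)
        attr_block = (
            Tensor(np.hstack([dm.values[mi], dd.values[di]])) if use_attr else None
        )
        loss_trace: List[float] = []
        prev_fused: Optional[np.ndarray] = None
        ema: Optional[List[np.ndarray]] = None
        t0 = time.time()
        for epoch in range(cfg.epochs):
            if cfg.lr_decay == "cosine":
                frac = 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.epochs - 1, 1)))
                opt.lr = cfg.lr * (0.1 + 0.9 * frac)
            opt.zero_grad()
            blocks: List[Tensor] = []
            fused_t = None
            if use_views:
                X = encoder.forward(rng if cfg.gat.dropout > 0 else None)
                fused_t = fusion.forward(X) if fusion is not None else (
                    X.gather_rows([0]).reshape(X.shape[1], X.shape[2])
                )
                if cfg.embed_dropout > 0:
                    keep = (rng.random(fused_t.shape) >= cfg.embed_dropout)
                    fused_t = fused_t * (keep / (1 - cfg.embed_dropout))
                blocks.append(fused_t.gather_rows(mi))
            if use_attr:
                if use_views:
                    blocks = [blocks[0], Tensor(dm.values[mi]),
                              fused_t.gather_rows(n_m + di), Tensor(dd.values[di])]
                else:
                    blocks = [attr_block]
            else:
                blocks.append(fused_t.gather_rows(n_m + di))
            feats = blocks[0] if len(blocks) == 1 else concat(blocks, axis=1)
            z = mlp.forward(feats, rng=rng)
            loss = bce_with_logits(z, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}"
                )
            loss.backward()
            opt.step()
            loss_trace.append(float(loss.data))
            if cfg.ema_decay is not None:
                if ema is None:
                    ema = [p.data.copy() for p in opt.params]
                else:
                    for e, p in zip(ema, opt.params):
                        e += (1 - cfg.ema_decay) * (p.data - e)
            if cfg.gat.early_stop_tol is not None and fused_t is not None:
                cur = fused_t.data
                if prev_fused is not None and np.abs(cur - prev_fused).max() < cfg.gat.early_stop_tol:
                    logger.info("early stop at epoch %d (embedding drift below tol)", epoch)
                    break
                prev_fused = cur.copy()
        if ema is not None:
            for e, p in zip(ema, opt.params):
                p.data[...] = e  # predict with the Polyak-averaged weights
        logger.info("fit: %d epochs in %.1fs, final loss %.4f",
                    len(loss_trace), time.time() - t0, loss_trace[-1])
        return MuscleResults(self, encoder, fusion, mlp, dm, dd,
                             np.asarray(train_idx), loss_trace)


class MuscleResults:
    """Fitted model state: scores, loss trace, metrics and summary."""

    def __init__(self, model: MuscleModel, encoder, fusion, mlp: Mlp,
                 dm: AttributeMatrix, dd: SimilarityMatrix,
                 train_idx: np.ndarray, loss_trace: List[float]):
        self.model = model
        self.encoder = encoder
        self.fusion = fusion
        self.mlp = mlp
        self.dm = dm
        self.dd = dd
        self.train_idx = train_idx
        self.loss_trace = loss_trace
        self._fused_cache: Optional[np.ndarray] = None

    def _fused(self) -> Optional[np.ndarray]:
        if self.encoder is None:
            return None
        if self._fused_cache is None:
            X = self.encoder.forward()
            if self.fusion is not None:
                self._fused_cache = self.fusion.forward(X).data
            else:
                self._fused_cache = X.data[0]
        return self._fused_cache

    def predict(self, pairs: Sequence[Pair]) -> np.ndarray:
        """Association scores (sigmoid probabilities) for arbitrary pairs."""
        cfg = self.model.config
        mi, di = self.model._pair_rows(pairs)
        n_m = len(self.model.mirnas)
        blocks: List[np.ndarray] = []
        fused = self._fused()
        use_attr = "attr" in cfg.feature_set
        if fused is not None:
            if use_attr:
                blocks = [fused[mi], self.dm.values[mi],
                          fused[n_m + di], self.dd.values[di]]
            else:
                blocks = [fused[mi], fused[n_m + di]]
        else:
            blocks = [self.dm.values[mi], self.dd.values[di]]
        z = self.mlp.forward(Tensor(np.hstack(blocks)), rng=None)
        return 1.0 / (1.0 + np.exp(-z.data))

    def metrics(self, idx: Optional[np.ndarray] = None,
                threshold: float = 0.5) -> MetricsReport:
        """Metric suite on a subset of the dataset (default: training pairs)."""
        if idx is None:
            idx = self.train_idx
        pairs = [self.model.dataset.pairs[i] for i in idx]
        labels = self.model.dataset.labels[idx]
        return compute_metrics(labels, self.predict(pairs), threshold)

    def rank_candidates(self, disease: str,
                        exclude: Optional[Set[Pair]] = None) -> List[Tuple[str, float]]:
        """All miRNAs scored against one disease, best first."""
        exclude = exclude or set()
        pairs = [(m, disease) for m in self.model.mirnas if (m, disease) not in exclude]
        scores = self.predict(pairs)
        order = np.argsort(-scores)
        return [(pairs[i][0], float(scores[i])) for i in order]

    def summary(self) -> str:
        cfg = self.model.config
        rep = self.metrics()
        lines = [
            "MuscleResults",
            "=" * 60,
            f"training pairs:      {len(self.train_idx)}",
            f"epochs run:          {len(self.loss_trace)}",
            f"final training loss: {self.loss_trace[-1]:.4f}",
            f"feature set:         {'+'.join(sorted(cfg.feature_set))}",
            f"fusion strategy:     {cfg.fusion_strategy}",
            "-" * 60,
            "training-set metrics:",
        ]
        for name in MetricsReport.FIELDS:
            lines.append(f"  {name:<12} {getattr(rep, name):.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation


class CVResults:
    """Per-fold metric reports plus their mean and standard deviation."""

    def __init__(self, reports: List[MetricsReport], config: TrainConfig):
        self.reports = reports
        self.config = config

    @property
    def mean(self) -> MetricsReport:
        arr = np.mean([r.as_array() for r in self.reports], axis=0)
        return MetricsReport(*arr)

    @property
    def sd(self) -> MetricsReport:
        arr = np.std([r.as_array() for r in self.reports], axis=0)
        return MetricsReport(*arr)

    def summary(self) -> str:
        header = ["Fold"] + [f.capitalize() for f in MetricsReport.FIELDS]
        rows = [header]
        for i, rep in enumerate(self.reports, start=1):
            rows.append([str(i)] + [f"{v:.4f}" for v in rep.as_array()])
        rows.append(
            ["Average"]
            + [f"{m:.4f}+/-{s:.4f}" for m, s in zip(self.mean.as_array(), self.sd.as_array())]
        )
        widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fold\t" + "\t".join(MetricsReport.FIELDS) + "\n")
            for i, rep in enumerate(self.reports, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in rep.as_array()) + "\n")
            fh.write("mean\t" + "\t".join(f"{v:.6f}" for v in self.mean.as_array()) + "\n")
            fh.write("sd\t" + "\t".join(f"{v:.6f}" for v in self.sd.as_array()) + "\n")


def make_dataset(
    positives: Sequence[Pair],
    mirnas: Sequence[str],
    diseases: Sequence[str],
    seed: int,
    folds: Optional[int] = None,
) -> AssociationDataset:
    """Balanced dataset: the positives plus an equal number of sampled
    non-associations, optionally with stratified fold assignments."""
    positives = list(dict.fromkeys(positives))
    negatives = sample_negatives(set(positives), list(mirnas), list(diseases),
                                 len(positives), seed)
    pairs = tuple(positives) + tuple(negatives)
    labels = np.r_[np.ones(len(positives), dtype=int),
                   np.zeros(len(negatives), dtype=int)]
    assign = kfold_split(labels, folds, seed) if folds else None
    return AssociationDataset(pairs, labels, assign)


def run_cv(
    inputs: ModelInputs,
    dataset: AssociationDataset,
    config: Optional[TrainConfig] = None,
) -> CVResults:
    """Stratified k-fold cross-validation of the full pipeline.

    Each fold trains a fresh model on the training pairs (GIP kernels and
    all network parameters re-derived from that fold alone) and evaluates on
    the held-out pairs.
    """
    config = config or TrainConfig()
    assign = dataset.fold_assignments
    if assign is None:
        assign = kfold_split(dataset.labels, config.folds, config.seed)
        dataset = AssociationDataset(dataset.pairs, dataset.labels, assign)
    reports: List[MetricsReport] = []
    for fold in range(int(assign.max()) + 1):
        test_idx = np.nonzero(assign == fold)[0]
        train_idx = np.nonzero(assign != fold)[0]
        if config.negative_mode == "per-fold":
            pos = [dataset.pairs[i] for i in train_idx if dataset.labels[i] == 1]
            sub = make_dataset(pos, inputs.mirnas, inputs.diseases,
                               seed=config.seed + fold)
            model = MuscleModel(inputs, sub, config)
            res = model.fit()
            test_pairs = [dataset.pairs[i] for i in test_idx]
            scores = res.predict(test_pairs)
        else:
            model = MuscleModel(inputs, dataset, config)
            res = model.fit(train_idx)
            scores = res.predict([dataset.pairs[i] for i in test_idx])
        reports.append(compute_metrics(dataset.labels[test_idx], scores))
        logger.info("fold %d: AUC %.4f AUPR %.4f", fold + 1,
                    reports[-1].auc, reports[-1].aupr)
    return CVResults(reports, config)
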
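"""Run configuration: YAML loading, validation and defaults.

A single flat-sectioned YAML file configures every stage.  Unknown keys are
rejected, all problems are reported at once, and the fully resolved
configuration is echoed to the log so any run can be reproduced from its
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .gat import GatConfig
from .model import ALL_FEATURES, TrainConfig
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)

#: path keys for the real-data inputs (all two-column TSV except the FASTA)
PATH_KEYS = (
    "sequences", "dag", "terms", "labels",
    "mirna_drug", "drug_disease",
    "mirna_mrna", "mrna_disease",
    "mirna_lncrna", "lncrna_disease",
)


class _DupWarnLoader(yaml.SafeLoader):
    """SafeLoader that warns on duplicate mapping keys (last wins)."""


def _construct_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            warnings.warn(f"duplicate config key {key!r}: last value wins",
                          stacklevel=2)
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_DupWarnLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


@dataclass
class RunConfig:
    """Validated union of all module configurations plus io paths."""

    k: int = 3
    delta: float = 0.5
    gamma_prime: float = 1.0
    clip: bool = True
    folds: int = 5
    epochs: int = 200
    lr: float = 1e-3
    seed: int = 123
    mlp_layers: int = 4
    dropout: float = 0.3
    feature_set: List[str] = field(default_factory=lambda: sorted(ALL_FEATURES))
    single_graph: bool = False
    negative_mode: str = "once"
    fusion: Dict[str, Any] = field(default_factory=dict)
    gat: Dict[str, Any] = field(default_factory=dict)
    synthetic: Dict[str, Any] = field(default_factory=dict)
    paths: Dict[str, str] = field(default_factory=dict)
    out_dir: str = "results"
    allow_any_folds: bool = False

    _FUSION_KEYS = {"strategy", "reduce", "bottleneck_r"}
    _GAT_KEYS = {"feature_dim", "hidden", "heads", "layers", "leaky_slope",
                 "embed_dim", "early_stop_tol"}

    def validate(self, require_paths: bool = False) -> None:
        problems: List[str] = []
        if self.folds not in (5, 10) and not self.allow_any_folds:
            problems.append(
                f"folds must be 5 or 10 (got {self.folds}); "
                "set allow_any_folds to override"
            )
        bad = set(self.feature_set) - ALL_FEATURES
        if bad:
            problems.append(f"unknown feature_set entries {sorted(bad)}")
        if not self.feature_set:
            problems.append("feature_set must be non-empty")
        for key in self.fusion:
            if key not in self._FUSION_KEYS:
                problems.append(f"unknown fusion key {key!r}")
        for key in self.gat:
            if key not in self._GAT_KEYS:
                problems.append(f"unknown gat key {key!r}")
        syn_keys = {f.name for f in fields(SyntheticConfig)}
        for key in self.synthetic:
            if key not in syn_keys:
                problems.append(f"unknown synthetic key {key!r}")
        for key, value in self.paths.items():
            if key not in PATH_KEYS:
                problems.append(f"unknown path key {key!r}")
            elif require_paths and not Path(value).exists():
                problems.append(f"path {key!r} does not exist: {value}")
        if self.negative_mode not in ("once", "per-fold"):
            problems.append(f"negative_mode must be 'once' or 'per-fold', got {self.negative_mode!r}")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    # -- conversions -------------------------------------------------------

    def train_config(self) -> TrainConfig:
        gat = GatConfig(**self.gat)
        return TrainConfig(
            k=self.k, delta=self.delta, gamma_prime=self.gamma_prime,
            clip_dss=self.clip, epochs=self.epochs, lr=self.lr,
            seed=self.seed, folds=self.folds if self.folds in (5, 10) else 5,
            mlp_layers=self.mlp_layers, dropout=self.dropout,
            feature_set=frozenset(self.feature_set),
            fusion_strategy=self.fusion.get("strategy", "msaff"),
            fusion_reduce=self.fusion.get("reduce", "sum"),
            fusion_r=self.fusion.get("bottleneck_r", 1),
            single_graph=self.single_graph,
            negative_mode=self.negative_mode,
            gat=gat,
        )

    def synthetic_config(self) -> SyntheticConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        if "seq_len_range" in kwargs:
            kwargs["seq_len_range"] = tuple(kwargs["seq_len_range"])
        return SyntheticConfig(**kwargs)

    def resolved(self) -> Dict[str, Any]:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Dict[str, Any]] = None,
                require_paths: bool = False) -> RunConfig:
    """Load and validate a YAML run configuration.

    An absent or empty file yields pure defaults.  ``overrides`` (e.g. from
    CLI flags) are applied on top.  All validation problems are raised
    together; the resolved configuration is echoed to the log.
    """
    raw: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.load(fh, Loader=_DupWarnLoader)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
            raw = loaded
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            "invalid configuration:\n  "
            + "\n  ".join(f"unknown key {k!r}" for k in sorted(unknown))
        )
    cfg = RunConfig(**raw)
    cfg.validate(require_paths=require_paths)
    logger.info("resolved config: %s", json.dumps(cfg.resolved(), sort_keys=True))
    return cfg
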
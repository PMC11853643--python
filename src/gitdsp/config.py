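"""Run configuration: published defaults, a scaled profile, and YAML I/O."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All hyperparameters of an end-to-end run (published defaults).

    The full-scale defaults mirror the model's published configuration:
    embedding width 2048, 16 attention heads, one encoder layer, propagation
    widths 512-256-128-64, 100 representation epochs at lr 1e-4, 32 predictor
    epochs at lr 5e-4 with weight decay 1e-7, a 1:10 positive-to-negative
    ratio and a top-7 similar-circRNA exclusion during negative sampling.
    """

    embedding_dim: int = 2048
    n_heads: int = 16
    encoder_layers: int = 1
    ffn_hidden: int = 256
    krl_dropout: float = 0.2
    layer_widths: tuple[int, ...] = (512, 256, 128, 64)
    prop_dropout: float = 0.1
    aggregator: str = "GIN"
    reduction: str = "sum"
    krl_epochs: int = 100
    krl_lr: float = 1e-4
    krl_batch_size: int = 1024
    pred_epochs: int = 32
    pred_lr: float = 5e-4
    pred_batch_size: int = 512
    weight_decay: float = 1e-7
    neg_ratio: int = 10
    neg_mode: str = "mixed"
    similar_exclusion_k: int = 7
    lambda_reg: float = 1e-5
    stream1_widths: tuple[int, ...] | None = None
    stream2_widths: tuple[int, ...] | None = None
    k_folds: int = 5
    topk_values: tuple[int, ...] = (10, 20, 30, 40)
    seed: int = 0

    def __post_init__(self):
        self.layer_widths = tuple(int(w) for w in self.layer_widths)
        self.topk_values = tuple(int(k) for k in self.topk_values)
        pair_width = 2 * (self.embedding_dim + sum(self.layer_widths))
        if self.embedding_dim % self.n_heads != 0:
            raise ValueError("head count must divide the embedding dimension")
        if pair_width <= 0:
            raise ValueError("invalid width configuration")
        for name in ("stream1_widths", "stream2_widths"):
            widths = getattr(self, name)
            if widths is not None:
                widths = tuple(int(w) for w in widths)
                setattr(self, name, widths)
                if widths[0] != pair_width:
                    raise ValueError(
                        f"{name} input {widths[0]} != pair width {pair_width}")

    def pair_width(self) -> int:
        return 2 * (self.embedding_dim + sum(self.layer_widths))

    def estimator_kwargs(self) -> dict:
        skip = {"k_folds", "topk_values", "seed"}
        out = {f.name: getattr(self, f.name) for f in fields(self)
               if f.name not in skip}
        out["random_state"] = self.seed
        return out

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["layer_widths"] = list(self.layer_widths)
        data["topk_values"] = list(self.topk_values)
        for name in ("stream1_widths", "stream2_widths"):
            if data[name] is not None:
                data[name] = list(data[name])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def scaled_config(seed: int = 0, **overrides) -> RunConfig:
    """Reduced profile for CPU-scale experiments and tests.

    Keeps every formula and the head-divisibility constraint while shrinking
    widths: d = 64, 4 heads, propagation widths 32-16-8-8, 30 representation
    epochs + 16 predictor epochs.  Learning rates are raised (1e-2 / 5e-3)
    and the predictor batch shrunk to 128: at these widths and epoch counts
    the full-scale rates leave the training loss essentially undescended.
    """
    base = dict(embedding_dim=64, n_heads=4, ffn_hidden=64,
                layer_widths=(32, 16, 8, 8), krl_epochs=30, krl_lr=1e-2,
                krl_batch_size=1024, pred_epochs=16, pred_lr=5e-3,
                pred_batch_size=128, seed=seed)
    base.update(overrides)
    return RunConfig(**base)
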
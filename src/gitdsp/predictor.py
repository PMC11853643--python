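"""Dual-Stream Neural Predictor (DSP) for circRNA-disease pair scoring.

Each entity's per-layer embeddings are concatenated,
``e = e^(0) ‖ … ‖ e^(L)``, and a circRNA-disease pair is represented by
``e_c ‖ e_d``.  Two parallel MLP streams read the pair vector — Stream 1 a
progressively narrowing network (default widths 6016-3008-1504-752) and
Stream 2 a shallower, wider one (6016-6016-3008).  Their outputs are
concatenated and a single affine fusion head plus sigmoid produces the
affinity score ŷ in (0, 1).  Training uses the BPR loss
``L2 = -Σ ln σ(ŷ_pos − ŷ_neg)``; the total objective adds an L2 penalty,
``L = L1 + L2 + λ‖α‖²``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .propagation import LEAKY_SLOPE

#: full-scale stream architectures (input widths match pair width 2 * 3008)
DEFAULT_STREAM1 = [6016, 3008, 1504, 752]
DEFAULT_STREAM2 = [6016, 6016, 3008]


def concat_embeddings(stages: list[Tensor] | list[np.ndarray],
                      entity: int | np.ndarray) -> np.ndarray:
    """Stage-ordered concatenation e^(0) ‖ … ‖ e^(L) for one or many entities."""
    if len(stages) == 0:
        raise ValueError("no embedding stages supplied")
    arrays = [s.data if isinstance(s, Tensor) else np.asarray(s)
              for s in stages]
    return np.concatenate([a[entity] for a in arrays], axis=-1)


def concat_stages(stages: list[Tensor]) -> Tensor:
    """Differentiable concatenation of all stages for every entity."""
    return ad.concat(stages, axis=-1)


@dataclass
class DSPParams:
    stream1: list[tuple[Tensor, Tensor]]   # (W, b) per layer
    stream2: list[tuple[Tensor, Tensor]]
    head_w: Tensor
    head_b: Tensor
    dropout: float = 0.1

    @property
    def pair_width(self) -> int:
        return self.stream1[0][0].shape[0]

    def parameters(self) -> list[Tensor]:
        out = []
        for w, b in self.stream1 + self.stream2:
            out.extend([w, b])
        out.extend([self.head_w, self.head_b])
        return out


def init_dsp(stream1_widths: list[int], stream2_widths: list[int],
             pair_width: int, rng: np.random.Generator,
             dropout: float = 0.1) -> DSPParams:
    """Build stream parameters; refuses widths inconsistent with the pair width."""
    for name, widths in (("stream 1", stream1_widths), ("stream 2", stream2_widths)):
        if widths[0] != pair_width:
            raise ValueError(
                f"{name} input width {widths[0]} != pair width {pair_width}")
    def affine_chain(widths):
        return [(ad.xavier_uniform((a, b), rng),
                 Tensor(np.zeros(b), requires_grad=True))
                for a, b in zip(widths[:-1], widths[1:])]
    s1 = affine_chain(stream1_widths)
    s2 = affine_chain(stream2_widths)
    fused = stream1_widths[-1] + stream2_widths[-1]
    return DSPParams(stream1=s1, stream2=s2,
                     head_w=ad.xavier_uniform((fused, 1), rng),
                     head_b=Tensor(np.zeros(1), requires_grad=True),
                     dropout=dropout)


def _run_stream(x: Tensor, layers: list[tuple[Tensor, Tensor]], dropout: float,
                rng: np.random.Generator, training: bool) -> Tensor:
    for w, b in layers:
        x = (x @ w + b).leaky_relu(LEAKY_SLOPE)
        x = ad.dropout(x, dropout, rng, training)
    return x


def dsp_forward(pair: Tensor, params: DSPParams,
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
    """Score (batched) pair vectors; returns ŷ in (0, 1) of shape (B,)."""
    if pair.ndim == 1:
        pair = pair.reshape(1, -1)
    if pair.shape[-1] != params.pair_width:
        raise ValueError(f"pair width {pair.shape[-1]} != expected "
                         f"{params.pair_width}")
    drop = rng if rng is not None else np.random.default_rng(0)
    out1 = _run_stream(pair, params.stream1, params.dropout, drop, training)
    out2 = _run_stream(pair, params.stream2, params.dropout, drop, training)
    delta = ad.concat([out1, out2], axis=-1)
    logits = (delta @ params.head_w + params.head_b).reshape(-1)
    return logits.sigmoid()


def bpr_pred_loss(pos: Tensor, neg: Tensor) -> Tensor:
    """``L2 = -Σ ln σ(ŷ_pos − ŷ_neg)`` over matched positive/negative scores."""
    if pos.data.size == 0:
        raise ValueError("empty score lists")
    if pos.data.shape != neg.data.shape:
        raise ValueError("positive and negative lists must be matched")
    return (-(pos - neg)).softplus().sum()


def total_loss(l1: Tensor | float, l2: Tensor | float, params: list[Tensor],
               lam: float) -> Tensor:
    """``L = L1 + L2 + λ‖α‖²`` over all trainable parameters α."""
    if lam < 0:
        raise ValueError("regularization weight must be non-negative")
    l1 = l1 if isinstance(l1, Tensor) else Tensor(l1)
    l2 = l2 if isinstance(l2, Tensor) else Tensor(l2)
    reg = Tensor(0.0)
    for p in params:
        reg = reg + (p ** 2.0).sum()
    return l1 + l2 + lam * reg
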
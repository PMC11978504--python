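"""Message-passing layers: encoder (node+edge update), decoder (node-only),
and the per-residue context-atom layer.

All three share the message pattern: concatenate the central node state with
the neighbor state and the edge feature, push through a three-layer GELU MLP,
sum messages scaled by 1/s, and apply a residual + LayerNorm, followed by a
position-wise feed-forward block. Masked neighbors contribute exactly zero to
the message sums; masked nodes are zeroed after each update.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .layers import Dropout, LayerNorm, Linear, Module, PositionWiseFeedForward


class EncLayer(Module):
    """Node and edge update over the sparse protein graph."""

    def __init__(self, num_hidden: int, rng: np.random.Generator,
                 dropout: float = 0.1, scale: float = 30.0,
                 ffn_width: int | None = None):
        super().__init__()
        h = num_hidden
        ffn = ffn_width or 4 * h
        self.scale = scale
        self.W1 = Linear(3 * h, h, rng)
        self.W2 = Linear(h, h, rng)
        self.W3 = Linear(h, h, rng)
        self.norm1 = LayerNorm(h)
        self.dense = PositionWiseFeedForward(h, ffn, rng)
        self.norm2 = LayerNorm(h)
        self.W11 = Linear(3 * h, h, rng)
        self.W12 = Linear(h, h, rng)
        self.W13 = Linear(h, h, rng)
        self.norm3 = LayerNorm(h)
        self.dropout1 = Dropout(dropout, rng)
        self.dropout2 = Dropout(dropout, rng)
        self.dropout3 = Dropout(dropout, rng)

    def __call__(self, v, e, e_idx: np.ndarray, mask: np.ndarray | None = None):
        L, K = e_idx.shape
        mask = np.ones(L) if mask is None else np.asarray(mask, dtype=np.float64)
        mask_j = mask[e_idx][..., None]          # neighbor validity [L,K,1]

        v_i = T.expand_axis(v, 1, K)
        v_j = T.gather_rows(v, e_idx)
        q = T.concatenate([v_i, v_j, e], axis=-1)
        q = self.W3(T.gelu(self.W2(T.gelu(self.W1(q)))))
        dh = T.tsum(q * mask_j, axis=1) * (1.0 / self.scale)
        v = self.norm1(v + self.dropout1(dh))
        v = self.norm2(v + self.dropout2(self.dense(v)))
        v = v * mask[:, None]

        v_i = T.expand_axis(v, 1, K)
        v_j = T.gather_rows(v, e_idx)
        q = T.concatenate([v_i, v_j, e], axis=-1)
        q = self.W13(T.gelu(self.W12(T.gelu(self.W11(q)))))
        e = self.norm3(e + self.dropout3(q))
        return v, e


class DecLayer(Module):
    """Node-only update; edges arrive pre-gathered with width ``num_in``."""

    def __init__(self, num_hidden: int, num_in: int, rng: np.random.Generator,
                 dropout: float = 0.1, scale: float = 30.0,
                 ffn_width: int | None = None):
        super().__init__()
        h = num_hidden
        ffn = ffn_width or 4 * h
        self.scale = scale
        self.W1 = Linear(h + num_in, h, rng)
        self.W2 = Linear(h, h, rng)
        self.W3 = Linear(h, h, rng)
        self.norm1 = LayerNorm(h)
        self.dense = PositionWiseFeedForward(h, ffn, rng)
        self.norm2 = LayerNorm(h)
        self.dropout1 = Dropout(dropout, rng)
        self.dropout2 = Dropout(dropout, rng)

    def __call__(self, v, e, mask_v: np.ndarray | None = None,
                 mask_attend: np.ndarray | None = None):
        n_nb = e.shape[-2]
        v_i = T.expand_axis(v, -2, n_nb)
        q = T.concatenate([v_i, e], axis=-1)
        q = self.W3(T.gelu(self.W2(T.gelu(self.W1(q)))))
        if mask_attend is not None:
            q = q * np.asarray(mask_attend, dtype=np.float64)[..., None]
        dh = T.tsum(q, axis=-2) * (1.0 / self.scale)
        v = self.norm1(v + self.dropout1(dh))
        v = self.norm2(v + self.dropout2(self.dense(v)))
        if mask_v is not None:
            v = v * np.asarray(mask_v, dtype=np.float64)[..., None]
        return v


class DecLayerJ(DecLayer):
    """Context-atom layer: fully connected message passing among each
    residue's M context atoms (same update pattern, shapes [L,M,...])."""
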
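"""The full networks: learned featurization projections, the three-block
encoder, the autoregressive sequence decoder, and the torsion-mixture head.

Two variants exist: ``"full"`` (protein + context-atom branches) and
``"protein_only"`` (the ablation without any context featurization or
protein-context message passing). At the default configuration the two count
2,618,693 and 1,660,485 trainable scalars respectively.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ..featurization import (FeatureConfig, ResidueContext, build_protein_graph,
                             context_feature_blocks)
from ..structures_io import ProteinStructure
from . import tensor as T
from .blocks import DecLayer, DecLayerJ, EncLayer
from .layers import Embedding, Dropout, LayerNorm, Linear, Module
from .tensor import Tensor

POS_EMBED_DIM = 16


@dataclass
class ModelConfig:
    m: int = 128
    num_enc_layers: int = 3
    num_ctx_layers: int = 2
    num_dec_layers: int = 3
    dropout_p: float = 0.1
    msg_scale: float = 30.0
    ffn_width: int | None = None  # defaults to 4*m
    alphabet_size: int = 21

    def __post_init__(self):
        if min(self.m, self.num_enc_layers, self.num_ctx_layers,
               self.num_dec_layers, self.alphabet_size) < 1:
            raise ValueError("all sizes must be positive")
        if self.msg_scale <= 0:
            raise ValueError("msg_scale must be > 0")

    @property
    def ffn(self) -> int:
        return self.ffn_width or 4 * self.m


@dataclass(eq=False)
class EncodedState:
    """Encoder output: node states, edge states, neighbor list, residue mask."""

    h_V: Tensor
    e: Tensor
    e_idx: np.ndarray
    mask: np.ndarray


def _empty_context(L: int, config: FeatureConfig) -> ResidueContext:
    return ResidueContext(np.zeros((L, config.M, 3)), np.zeros((L, config.M)),
                          np.zeros((L, config.M), dtype=np.int64))


class FeatureEmbedder(Module):
    """Learned projections of the numeric feature blocks."""

    def __init__(self, mc: ModelConfig, fc: FeatureConfig,
                 variant: str, rng: np.random.Generator):
        super().__init__()
        m = mc.m
        self.pos_linear = Linear(fc.pos_onehot_width, POS_EMBED_DIM, rng)
        self.edge_embedding = Linear(fc.edge_in_width, m, rng, bias=False)
        self.norm_edges = LayerNorm(m)
        if variant == "full":
            from ..featurization import ELEMENT_FEATURE_WIDTH
            self.type_linear = Linear(ELEMENT_FEATURE_WIDTH, fc.element_embed_dim, rng)
            self.node_project_down = Linear(fc.context_node_in_width, m, rng)
            self.norm_nodes = LayerNorm(m)
            self.y_nodes = Linear(ELEMENT_FEATURE_WIDTH, m, rng, bias=False)
            self.norm_y_nodes = LayerNorm(m)
            self.y_edges = Linear(fc.r, m, rng, bias=False)
            self.norm_y_edges = LayerNorm(m)

    def protein_edges(self, graph: dict) -> Tensor:
        pos = self.pos_linear(Tensor(graph["pos_onehot"]))
        edge_in = T.concatenate([pos, Tensor(graph["rbf"])], axis=-1)
        return self.norm_edges(self.edge_embedding(edge_in))

    def context_nodes(self, blocks: dict) -> tuple[Tensor, Tensor, Tensor]:
        onehot = Tensor(blocks["element_onehot"])
        embedded = self.type_linear(onehot)
        ctx_in = T.concatenate([Tensor(blocks["rbf_y"]), embedded,
                                Tensor(blocks["angles"])], axis=-1)
        v_ctx = self.norm_nodes(self.node_project_down(ctx_in))
        y_nodes = self.norm_y_nodes(self.y_nodes(onehot))
        y_edges = self.norm_y_edges(self.y_edges(Tensor(blocks["y_edges_rbf"])))
        return v_ctx, y_nodes, y_edges


class EncoderCore(Module):
    """Protein encoder plus (for the full variant) the context branch."""

    def __init__(self, mc: ModelConfig, fc: FeatureConfig, variant: str,
                 rng: np.random.Generator):
        super().__init__()
        if variant not in ("full", "protein_only"):
            raise ValueError(f"unknown variant: {variant}")
        self.variant = variant
        self.model_config = mc
        self.feature_config = fc
        m = mc.m
        self.features = FeatureEmbedder(mc, fc, variant, rng)
        self.W_e = Linear(m, m, rng)
        self.enc_layers = [EncLayer(m, rng, mc.dropout_p, mc.msg_scale, mc.ffn)
                           for _ in range(mc.num_enc_layers)]
        if variant == "full":
            self.W_v = Linear(m, m, rng)
            self.W_c = Linear(m, m, rng)
            self.W_nodes_y = Linear(m, m, rng)
            self.W_edges_y = Linear(m, m, rng)
            self.y_context_layers = [
                DecLayerJ(m, m, rng, mc.dropout_p, mc.msg_scale, mc.ffn)
                for _ in range(mc.num_ctx_layers)]
            self.context_layers = [
                DecLayer(m, 2 * m, rng, mc.dropout_p, mc.msg_scale, mc.ffn)
                for _ in range(mc.num_ctx_layers)]
            self.V_C = Linear(m, m, rng, bias=False)
            self.V_C_norm = LayerNorm(m)
            self.V_C_dropout = Dropout(mc.dropout_p, rng)

    def __call__(self, structure: ProteinStructure,
                 rc: ResidueContext | None = None) -> EncodedState:
        fc = self.feature_config
        L = len(structure)
        mask = structure.residue_mask.astype(np.float64)
        graph = build_protein_graph(structure, fc)
        e_idx = graph["e_idx"]
        e = self.W_e(self.features.protein_edges(graph))
        v = Tensor(np.zeros((L, self.model_config.m)))
        for layer in self.enc_layers:
            v, e = layer(v, e, e_idx, mask)
        if self.variant == "full":
            if rc is None:
                rc = _empty_context(L, fc)
            blocks = context_feature_blocks(structure, rc, fc)
            v_ctx, y_nodes, y_edges = self.features.context_nodes(blocks)
            v_y = self.W_v(v_ctx)
            v_c = self.W_c(v)
            y_nodes = self.W_nodes_y(y_nodes)
            y_edges = self.W_edges_y(y_edges)
            y_m = rc.Y_m
            y_m_edges = y_m[:, :, None] * y_m[:, None, :]
            for atom_layer, ctx_layer in zip(self.y_context_layers,
                                             self.context_layers):
                y_nodes = atom_layer(y_nodes, y_edges, mask_v=y_m,
                                     mask_attend=y_m_edges)
                y_nodes_c = T.concatenate([v_y, y_nodes], axis=-1)
                v_c = ctx_layer(v_c, y_nodes_c, mask_v=mask, mask_attend=y_m)
            v_c = self.V_C(v_c)
            v = v + self.V_C_norm(self.V_C_dropout(v_c))
            v = v * mask[:, None]
        return EncodedState(h_V=v, e=e, e_idx=e_idx, mask=mask)


def causal_attend_mask(decoding_order: np.ndarray, e_idx: np.ndarray) -> np.ndarray:
    """[L, K] binary mask: edge (i -> j) may carry j's token iff j is decoded
    before i under ``decoding_order``. Raises on non-permutations."""
    order = np.asarray(decoding_order, dtype=np.int64)
    L = e_idx.shape[0]
    if sorted(order.tolist()) != list(range(L)):
        raise ValueError("decoding_order must be a permutation of range(L)")
    position = np.empty(L, dtype=np.int64)
    position[order] = np.arange(L)
    attend = position[:, None] > position[None, :]
    return attend[np.arange(L)[:, None], e_idx].astype(np.float64)


class SequenceDesignModel(Module):
    """Context-conditioned autoregressive sequence design network."""

    def __init__(self, model_config: ModelConfig | None = None,
                 feature_config: FeatureConfig | None = None,
                 variant: str = "full", seed: int = 0):
        super().__init__()
        mc = model_config or ModelConfig()
        fc = feature_config or FeatureConfig(m=mc.m)
        rng = np.random.default_rng(seed)
        self.model_config = mc
        self.feature_config = fc
        self.variant = variant
        self.encoder = EncoderCore(mc, fc, variant, rng)
        m = mc.m
        self.W_s = Embedding(mc.alphabet_size, m, rng)
        self.dec_layers = [DecLayer(m, 3 * m, rng, mc.dropout_p, mc.msg_scale, mc.ffn)
                           for _ in range(mc.num_dec_layers)]
        self.W_out = Linear(m, mc.alphabet_size, rng)

    # -- forward passes ----------------------------------------------------
    def encode(self, structure: ProteinStructure,
               rc: ResidueContext | None = None) -> EncodedState:
        return self.encoder(structure, rc)

    def decode_logits(self, state: EncodedState, S: np.ndarray,
                      decoding_order: np.ndarray) -> tuple[Tensor, Tensor]:
        """Teacher-forced logits and log-probabilities under a decoding order.

        Position i attends the sequence tokens only of positions decoded
        before it; for later positions the edge falls back to encoder-only
        features (zeroed sequence slot).
        """
        e_idx = state.e_idx
        L, K = e_idx.shape
        attend = causal_attend_mask(decoding_order, e_idx)
        mask_i = state.mask[:, None]
        bw = (attend * mask_i)[..., None]
        fw = ((1.0 - attend) * mask_i)[..., None]

        h_S = self.W_s(np.asarray(S, dtype=np.int64))
        h_ES = T.concatenate([T.gather_rows(h_S, e_idx), state.e], axis=-1)
        h_V_enc_j = T.gather_rows(state.h_V, e_idx)
        zeros_seq = Tensor(np.zeros(h_V_enc_j.shape))
        h_EXV = T.concatenate([h_V_enc_j, zeros_seq, state.e], axis=-1)
        h_EXV_fw = h_EXV * fw

        h_V = state.h_V
        for layer in self.dec_layers:
            h_ESV = T.concatenate([T.gather_rows(h_V, e_idx), h_ES], axis=-1)
            h_ESV = h_ESV * bw + h_EXV_fw
            h_V = layer(h_V, h_ESV, mask_v=state.mask)
        logits = self.W_out(h_V)
        return logits, T.log_softmax(logits, axis=-1)

    def config_dict(self) -> dict:
        return {
            "model_config": asdict(self.model_config),
            "feature_config": asdict(self.feature_config),
            "variant": self.variant,
        }


class SidechainPackerModel(Module):
    """Torsion-mixture prediction head on two independent encoder stacks.

    The sequence is injected additively into the decoder node states; the
    decoder mixes encoder-A edges (future positions) with encoder-B edges
    (already decoded positions) under the causal mask, and a final linear map
    emits per-residue [4 chi x 3 components x (mean, raw concentration,
    mixing logit)].
    """

    CONCENTRATION_FLOOR = 0.1

    def __init__(self, model_config: ModelConfig | None = None,
                 feature_config: FeatureConfig | None = None,
                 variant: str = "full", seed: int = 0):
        super().__init__()
        mc = model_config or ModelConfig()
        fc = feature_config or FeatureConfig(m=mc.m)
        rng = np.random.default_rng(seed)
        self.model_config = mc
        self.feature_config = fc
        self.variant = variant
        m = mc.m
        self.encoder_a = EncoderCore(mc, fc, variant, rng)
        self.encoder_b = EncoderCore(mc, fc, variant, rng)
        self.W_s = Embedding(mc.alphabet_size, m, rng)
        self.dec_layers = [DecLayer(m, 2 * m, rng, mc.dropout_p, mc.msg_scale, mc.ffn)
                           for _ in range(mc.num_dec_layers)]
        self.W_torsion = Linear(m, 4 * 3 * 3, rng)

    def __call__(self, structure: ProteinStructure, S: np.ndarray,
                 rc: ResidueContext | None,
                 decoding_order: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (mean, concentration, mix_logits), each [L, 4, 3]."""
        state_a = self.encoder_a(structure, rc)
        state_b = self.encoder_b(structure, rc)
        e_idx = state_a.e_idx
        L, K = e_idx.shape
        attend = causal_attend_mask(decoding_order, e_idx)
        mask_i = state_a.mask[:, None]
        bw = (attend * mask_i)[..., None]
        fw = ((1.0 - attend) * mask_i)[..., None]

        h_EV_enc = T.concatenate([T.gather_rows(state_a.h_V, e_idx), state_a.e],
                                 axis=-1)
        h_EV_enc_fw = h_EV_enc * fw
        e_dec = state_b.e
        h_V = state_a.h_V + self.W_s(np.asarray(S, dtype=np.int64))
        for layer in self.dec_layers:
            h_EV = T.concatenate([T.gather_rows(h_V, e_idx), e_dec], axis=-1)
            h_ECV = h_EV * bw + h_EV_enc_fw
            h_V = layer(h_V, h_ECV, mask_v=state_a.mask)
        torsions = T.reshape(self.W_torsion(h_V), (L, 4, 3, 3))
        mean = T.wrap_angle(torsions[:, :, :, 0])
        concentration = T.softplus(torsions[:, :, :, 1]) + self.CONCENTRATION_FLOOR
        mix_logits = torsions[:, :, :, 2]
        return mean, concentration, mix_logits

    def config_dict(self) -> dict:
        return {
            "model_config": asdict(self.model_config),
            "feature_config": asdict(self.feature_config),
            "variant": self.variant,
        }


def count_parameters(model_config: ModelConfig | None = None,
                     feature_config: FeatureConfig | None = None,
                     variant: str = "full") -> int:
    """Exact count of trainable scalars of the sequence design network."""
    model = SequenceDesignModel(model_config, feature_config, variant=variant)
    return model.num_parameters()
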
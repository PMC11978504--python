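"""Network building blocks: printed-formula primitives, scalar oracles for
each message-passing layer type, masking, parameter counts, determinism."""

import math

import numpy as np
import pytest

from contextmpnn.featurization import FeatureConfig, select_context_atoms
from contextmpnn.fixtures import FixtureSpec, LigandSpec, make_backbone, make_context
from contextmpnn.nn import tensor as T
from contextmpnn.nn.blocks import DecLayer, DecLayerJ, EncLayer
from contextmpnn.nn.layers import (Adam, Dropout, LayerNorm, load_checkpoint,
                                   save_checkpoint)
from contextmpnn.nn.model import (ModelConfig, SequenceDesignModel,
                                  count_parameters)
from contextmpnn.nn.tensor import Tensor
from contextmpnn.structures_io import ContextAtoms


# ---------------------------------------------------------------------------
# scalar reference implementations (plain python floats)

def gelu_scalar(x):
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + math.tanh(c * (x + 0.044715 * x ** 3)))


def linear_scalar(x, W, b):
    out = []
    for row in range(W.shape[0]):
        acc = 0.0 if b is None else float(b[row])
        for col in range(W.shape[1]):
            acc += float(W[row, col]) * x[col]
        out.append(acc)
    return out


def layer_norm_scalar(x, gamma, beta, eps=1e-5):
    n = len(x)
    mu = sum(x) / n
    var = sum((xi - mu) ** 2 for xi in x) / n
    return [float(gamma[i]) * (x[i] - mu) / math.sqrt(var + eps) + float(beta[i])
            for i in range(n)]


def mlp3_scalar(q, layer, names=("W1", "W2", "W3")):
    w1, w2, w3 = (getattr(layer, n) for n in names)
    h = [gelu_scalar(v) for v in linear_scalar(q, w1.weight.data, w1.bias.data)]
    h = [gelu_scalar(v) for v in linear_scalar(h, w2.weight.data, w2.bias.data)]
    return linear_scalar(h, w3.weight.data, w3.bias.data)


def ffn_norm_scalar(v, layer):
    hidden = [gelu_scalar(x) for x in linear_scalar(
        v, layer.dense.w_in.weight.data, layer.dense.w_in.bias.data)]
    delta = linear_scalar(hidden, layer.dense.w_out.weight.data,
                          layer.dense.w_out.bias.data)
    return layer_norm_scalar([a + b for a, b in zip(v, delta)],
                             layer.norm2.gamma.data, layer.norm2.beta.data)


class TestPrimitives:
    def test_gelu_zero(self):
        assert float(T.gelu(Tensor(np.zeros(1))).data[0]) == 0.0

    def test_gelu_matches_scalar_formula(self, rng):
        x = rng.standard_normal(10)
        expected = [gelu_scalar(v) for v in x]
        np.testing.assert_allclose(T.gelu(Tensor(x)).data, expected, atol=1e-12)

    def test_layer_norm_constant_vector_gives_beta(self, rng):
        ln = LayerNorm(4)
        ln.beta.data = rng.standard_normal(4)
        out = ln(Tensor(np.full((3, 4), 2.5)))
        np.testing.assert_allclose(out.data, np.tile(ln.beta.data, (3, 1)),
                                   atol=1e-6)

    def test_dropout_eval_identity(self, rng):
        drop = Dropout(0.5, np.random.default_rng(0))
        drop.eval()
        x = rng.standard_normal((5, 5))
        np.testing.assert_array_equal(drop(Tensor(x)).data, x)

    def test_dropout_training_inverted_scaling(self):
        drop = Dropout(0.25, np.random.default_rng(0))
        drop.train()
        x = np.ones((200, 200))
        out = drop(Tensor(x)).data
        kept = out[out != 0]
        np.testing.assert_allclose(kept, 1.0 / 0.75)
        assert abs((out != 0).mean() - 0.75) < 0.02

    def test_ffn_shapes(self, rng):
        from contextmpnn.nn.layers import PositionWiseFeedForward
        ffn = PositionWiseFeedForward(8, 32, np.random.default_rng(0))
        out = ffn(Tensor(rng.standard_normal((3, 8))))
        assert out.shape == (3, 8)


class TestEncLayerOracle:
    @pytest.fixture()
    def layer(self):
        return EncLayer(2, np.random.default_rng(1), dropout=0.1, scale=30.0).eval()

    def test_two_residue_scalar_oracle(self, layer, rng):
        v = rng.standard_normal((2, 2))
        e = rng.standard_normal((2, 2, 2))
        e_idx = np.array([[0, 1], [1, 0]])
        v_out, e_out = layer(Tensor(v), Tensor(e), e_idx)

        expected_v = []
        for i in range(2):
            dh = [0.0, 0.0]
            for k in range(2):
                j = e_idx[i, k]
                q = list(v[i]) + list(v[j]) + list(e[i, k])
                msg = mlp3_scalar(q, layer)
                dh = [a + b / 30.0 for a, b in zip(dh, msg)]
            vi = layer_norm_scalar([v[i][d] + dh[d] for d in range(2)],
                                   layer.norm1.gamma.data, layer.norm1.beta.data)
            expected_v.append(ffn_norm_scalar(vi, layer))
        np.testing.assert_allclose(v_out.data, expected_v, atol=1e-6)

        expected_e = []
        for i in range(2):
            rows = []
            for k in range(2):
                j = e_idx[i, k]
                q = list(expected_v[i]) + list(expected_v[j]) + list(e[i, k])
                msg = mlp3_scalar(q, layer, names=("W11", "W12", "W13"))
                rows.append(layer_norm_scalar(
                    [e[i, k][d] + msg[d] for d in range(2)],
                    layer.norm3.gamma.data, layer.norm3.beta.data))
            expected_e.append(rows)
        np.testing.assert_allclose(e_out.data, expected_e, atol=1e-6)

    def test_zero_weights_reduce_to_normalized_residual(self, rng):
        layer = EncLayer(2, np.random.default_rng(0)).eval()
        for _, p in layer.named_parameters():
            if p.data.ndim >= 1 and not np.all(p.data == 1.0):
                p.data[:] = 0.0
        layer.norm1.gamma.data[:] = 1.0
        layer.norm2.gamma.data[:] = 1.0
        layer.norm3.gamma.data[:] = 1.0
        v = rng.standard_normal((2, 2))
        e = rng.standard_normal((2, 2, 2))
        v_out, e_out = layer(Tensor(v), Tensor(e), np.array([[0, 1], [1, 0]]))
        expected = [layer_norm_scalar(
            layer_norm_scalar(list(v[i]), [1, 1], [0, 0]), [1, 1], [0, 0])
            for i in range(2)]
        np.testing.assert_allclose(v_out.data, expected, atol=1e-9)
        for i in range(2):
            for k in range(2):
                np.testing.assert_allclose(
                    e_out.data[i, k],
                    layer_norm_scalar(list(e[i, k]), [1, 1], [0, 0]), atol=1e-9)

    def test_single_residue_self_edge(self, layer, rng):
        v = rng.standard_normal((1, 2))
        e = rng.standard_normal((1, 1, 2))
        v_out, _ = layer(Tensor(v), Tensor(e), np.array([[0]]))
        q = list(v[0]) * 2 + list(e[0, 0])
        dh = [m / 30.0 for m in mlp3_scalar(q, layer)]
        vi = layer_norm_scalar([v[0][d] + dh[d] for d in range(2)],
                               layer.norm1.gamma.data, layer.norm1.beta.data)
        np.testing.assert_allclose(v_out.data[0], ffn_norm_scalar(vi, layer),
                                   atol=1e-6)

    def test_masked_neighbor_messages_are_inert(self, layer, rng):
        v = rng.standard_normal((3, 2))
        e = rng.standard_normal((3, 2, 2))
        e_idx = np.array([[0, 2], [1, 2], [2, 0]])
        mask = np.array([1.0, 1.0, 0.0])
        v_out, _ = layer(Tensor(v), Tensor(e), e_idx, mask)
        v2 = v.copy()
        v2[2] = 100.0  # masked residue's state must not leak into messages
        v_out2, _ = layer(Tensor(v2), Tensor(e), e_idx, mask)
        np.testing.assert_allclose(v_out.data[:2], v_out2.data[:2], atol=1e-12)
        np.testing.assert_array_equal(v_out.data[2], 0.0)


class TestDecLayerOracle:
    @pytest.fixture()
    def layer(self):
        return DecLayer(2, 4, np.random.default_rng(2)).eval()

    def test_two_residue_scalar_oracle(self, layer, rng):
        v = rng.standard_normal((2, 2))
        e = rng.standard_normal((2, 2, 4))
        v_out = layer(Tensor(v), Tensor(e))
        for i in range(2):
            dh = [0.0, 0.0]
            for k in range(2):
                q = list(v[i]) + list(e[i, k])
                msg = mlp3_scalar(q, layer)
                dh = [a + b / 30.0 for a, b in zip(dh, msg)]
            vi = layer_norm_scalar([v[i][d] + dh[d] for d in range(2)],
                                   layer.norm1.gamma.data, layer.norm1.beta.data)
            np.testing.assert_allclose(v_out.data[i], ffn_norm_scalar(vi, layer),
                                       atol=1e-6)

    def test_single_neighbor_message(self, layer, rng):
        v = rng.standard_normal((1, 2))
        e = rng.standard_normal((1, 1, 4))
        v_out = layer(Tensor(v), Tensor(e))
        assert v_out.shape == (1, 2)

    def test_mask_attend_zeroes_messages(self, layer, rng):
        v = rng.standard_normal((2, 2))
        e = rng.standard_normal((2, 2, 4))
        out_masked = layer(Tensor(v), Tensor(e),
                           mask_attend=np.zeros((2, 2)))
        e2 = rng.standard_normal((2, 2, 4))
        out_masked2 = layer(Tensor(v), Tensor(e2),
                            mask_attend=np.zeros((2, 2)))
        np.testing.assert_allclose(out_masked.data, out_masked2.data, atol=1e-12)


class TestContextDecLayer:
    @pytest.fixture()
    def layer(self):
        return DecLayerJ(2, 2, np.random.default_rng(3)).eval()

    def test_permuting_atoms_permutes_outputs(self, layer, rng):
        v = rng.standard_normal((1, 4, 2))
        e = rng.standard_normal((1, 4, 4, 2))
        out = layer(Tensor(v), Tensor(e)).data
        perm = np.array([2, 0, 3, 1])
        out_perm = layer(Tensor(v[:, perm]),
                         Tensor(e[:, perm][:, :, perm])).data
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-10)

    def test_all_masked_context_zeroed(self, layer, rng):
        v = rng.standard_normal((2, 3, 2))
        e = rng.standard_normal((2, 3, 3, 2))
        y_m = np.zeros((2, 3))
        out = layer(Tensor(v), Tensor(e), mask_v=y_m,
                    mask_attend=np.zeros((2, 3, 3)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_m_equals_one_self_message(self, layer, rng):
        v = rng.standard_normal((1, 1, 2))
        e = rng.standard_normal((1, 1, 1, 2))
        out = layer(Tensor(v), Tensor(e))
        q = list(v[0, 0]) + list(v[0, 0]) + list(e[0, 0, 0])
        dh = [m / 30.0 for m in mlp3_scalar(q, layer)]
        vi = layer_norm_scalar([v[0, 0][d] + dh[d] for d in range(2)],
                               layer.norm1.gamma.data, layer.norm1.beta.data)
        np.testing.assert_allclose(out.data[0, 0], ffn_norm_scalar(vi, layer),
                                   atol=1e-6)


class TestParameterCounts:
    def test_full_default(self):
        assert count_parameters() == 2618693
        assert round(count_parameters() / 1e6, 2) == 2.62

    def test_protein_only_default(self):
        assert count_parameters(variant="protein_only") == 1660485
        assert round(count_parameters(variant="protein_only") / 1e6, 2) == 1.66

    def test_width_scaling_quadratic(self):
        base = count_parameters(ModelConfig(m=64), FeatureConfig(m=64))
        double = count_parameters(ModelConfig(m=128), FeatureConfig(m=128))
        assert double > base
        assert 2.5 < double / base < 4.5

    def test_deterministic_given_config(self):
        assert count_parameters() == count_parameters()


class TestEncode:
    def _structure(self, L, seed=0):
        spec = FixtureSpec(chain_length=L, rng_seed=seed,
                           ligands=(LigandSpec(anchor_residue=min(3, L - 1)),))
        s = make_backbone(spec)
        return s, make_context(spec, s)

    def test_empty_context_matches_masked_context(self, small_model):
        s, _ = self._structure(8)
        fc = small_model.feature_config
        rc_none = None
        rc_masked = select_context_atoms(s, ContextAtoms.empty(), fc)
        with T.no_grad():
            a = small_model.encode(s, rc_none)
            b = small_model.encode(s, rc_masked)
        np.testing.assert_allclose(a.h_V.data, b.h_V.data, atol=1e-12)

    def test_eval_mode_deterministic(self, small_model):
        s, ctx = self._structure(6)
        rc = select_context_atoms(s, ctx, small_model.feature_config)
        with T.no_grad():
            a = small_model.encode(s, rc)
            b = small_model.encode(s, rc)
        np.testing.assert_array_equal(a.h_V.data, b.h_V.data)

    @pytest.mark.parametrize("L", [1, 5, 200])
    def test_finite_on_fuzzed_sizes(self, small_model, L):
        s, ctx = self._structure(L, seed=L)
        rc = select_context_atoms(s, ctx, small_model.feature_config)
        with T.no_grad():
            state = small_model.encode(s, rc)
        assert np.isfinite(state.h_V.data).all()
        assert np.isfinite(state.e.data).all()

    def test_gradients_flow_to_every_parameter(self):
        mc = ModelConfig(m=8)
        fc = FeatureConfig(K=4, M=3, m=8, r=4)
        model = SequenceDesignModel(mc, fc, variant="full", seed=0).train()
        s, ctx = self._structure(6)
        rc = select_context_atoms(s, ctx, fc)
        state = model.encode(s, rc)
        _, log_probs = model.decode_logits(state, s.sequence,
                                           np.random.default_rng(0).permutation(6))
        loss = -T.tmean(log_probs)
        model.zero_grad()
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []


class TestCheckpoint:
    def test_round_trip_with_optimizer(self, tmp_path, small_model_config):
        fc = FeatureConfig(K=4, M=3, m=16)
        model = SequenceDesignModel(small_model_config, fc, seed=1)
        opt = Adam(model.parameters())
        opt.step_count = 7
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, model.config_dict(), opt,
                        extra={"epoch": 3})
        model2 = SequenceDesignModel(small_model_config, fc, seed=2)
        opt2 = Adam(model2.parameters())
        manifest = load_checkpoint(path, model2, opt2)
        for (n1, p1), (n2, p2) in zip(model.named_parameters(),
                                      model2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)
        assert opt2.step_count == 7
        assert manifest["extra"]["epoch"] == 3

    def test_shape_mismatch_rejected(self, tmp_path, small_model_config):
        fc = FeatureConfig(K=4, M=3, m=16)
        model = SequenceDesignModel(small_model_config, fc, seed=1)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, {})
        other = SequenceDesignModel(ModelConfig(m=32), FeatureConfig(K=4, M=3, m=32),
                                    seed=0)
        with pytest.raises(ValueError):
            load_checkpoint(path, other)


class TestModelConfigValidation:
    def test_bad_scale(self):
        with pytest.raises(ValueError):
            ModelConfig(msg_scale=0.0)

    def test_bad_sizes(self):
        with pytest.raises(ValueError):
            ModelConfig(m=0)
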
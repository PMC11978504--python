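"""Losses, augmentation, training loop behavior, and evaluation metrics."""

import numpy as np
import pytest

from contextmpnn.alphabet import encode_sequence
from contextmpnn.featurization import FeatureConfig, select_context_atoms
from contextmpnn.fixtures import (FixtureSpec, LigandSpec, make_backbone,
                                  make_context)
from contextmpnn.geometry import place_sidechain
from contextmpnn.metrics import (chi_recovery, confidence_calibration,
                                 context_shell_residues, median_recovery,
                                 metrics_frame, sequence_recovery)
from contextmpnn.nn import tensor as T
from contextmpnn.nn.model import ModelConfig, SequenceDesignModel
from contextmpnn.nn.tensor import Tensor
from contextmpnn.structures_io import Category, ContextAtoms
from contextmpnn.training import (TrainConfig, TrainExample,
                                  augment_sidechain_context, filter_dataset,
                                  load_cluster_table, pack_structures,
                                  sequence_loss, split_by_cluster, train)

SMALL_FC = FeatureConfig(K=4, M=3, m=16)
SMALL_MC = ModelConfig(m=16)


def _tiny_dataset(n=2, L=10, seed=0):
    out = []
    for i in range(n):
        spec = FixtureSpec(chain_length=L, rng_seed=seed + i,
                           ligands=(LigandSpec(anchor_residue=L // 2),))
        s = make_backbone(spec)
        s.sequence = np.random.default_rng(seed + i).integers(0, 20, L)
        out.append(TrainExample(s, make_context(spec, s)))
    return out


class TestSequenceLoss:
    def test_perfect_prediction_zero(self):
        S = np.array([0, 3, 7])
        lp = np.full((3, 21), -50.0)
        lp[np.arange(3), S] = 0.0
        loss = sequence_loss(Tensor(lp), S, np.ones(3))
        assert float(loss.data) == 0.0

    def test_uniform_prediction_ln21(self):
        lp = np.full((4, 21), np.log(1 / 21))
        loss = sequence_loss(Tensor(lp), np.zeros(4, dtype=int), np.ones(4))
        np.testing.assert_allclose(float(loss.data), np.log(21), atol=1e-12)

    def test_hand_computed_three_residue_case(self):
        probs = np.full((3, 21), 1e-9)
        probs[0, 2], probs[1, 5], probs[2, 5] = 0.5, 0.25, 0.9
        lp = np.log(probs)
        S = np.array([2, 5, 5])
        mask = np.array([1.0, 1.0, 0.0])
        expected = -(np.log(0.5) + np.log(0.25)) / 2
        loss = sequence_loss(Tensor(lp), S, mask)
        np.testing.assert_allclose(float(loss.data), expected, atol=1e-12)


class TestAugmentation:
    def _examples(self):
        return _tiny_dataset(n=3, L=20)

    def test_fraction_zero_no_donors(self):
        donors = augment_sidechain_context(self._examples(), (0.0, 0.0),
                                           np.random.default_rng(0))
        assert all(not d.any() for d in donors)

    def test_fraction_one_all_donate(self):
        donors = augment_sidechain_context(self._examples(), (1.0, 1.0),
                                           np.random.default_rng(0))
        assert all(d.all() for d in donors)

    def test_binomial_count_distribution(self):
        examples = self._examples()
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(1000):
            donors = augment_sidechain_context(examples, (0.1, 0.1), rng)
            counts.append(sum(d.sum() for d in donors))
        n_total = sum(len(ex.structure) for ex in examples)
        mean = np.mean(counts)
        expected = 0.1 * n_total
        std = np.sqrt(n_total * 0.1 * 0.9 / 1000)
        assert abs(mean - expected) < 5 * std

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(sidechain_context_fraction=(0.5, 0.2))

    def test_train_config_yaml_round_trip(self, tmp_path):
        config = TrainConfig(lr=5e-4, epochs=3,
                             sidechain_context_fraction=(0.01, 0.05))
        path = tmp_path / "train.yaml"
        config.to_yaml(path)
        assert TrainConfig.from_yaml(path) == config


class TestPacking:
    def test_packed_forward_equivalent_to_single(self):
        examples = _tiny_dataset(n=2, L=8)
        model = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=0).eval()
        rcs = [select_context_atoms(ex.structure, ex.context, SMALL_FC)
               for ex in examples]
        packed, rc = pack_structures(
            [(ex.structure, r) for ex, r in zip(examples, rcs)])
        with T.no_grad():
            state = model.encode(packed, rc)
            solo = model.encode(examples[0].structure, rcs[0])
        np.testing.assert_allclose(state.h_V.data[:8], solo.h_V.data,
                                   atol=1e-8)

    def test_packed_chain_labels_distinct(self):
        examples = _tiny_dataset(n=3, L=4)
        rcs = [select_context_atoms(ex.structure, ex.context, SMALL_FC)
               for ex in examples]
        packed, _ = pack_structures(
            [(ex.structure, r) for ex, r in zip(examples, rcs)])
        assert len(set(packed.chain_labels.tolist())) == 3


class TestTrainLoop:
    def test_overfit_single_structure_decreases_loss(self):
        examples = _tiny_dataset(n=1, L=12)
        model = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=0)
        cfg = TrainConfig(epochs=8, batch_tokens=50, rng_seed=0, lr=3e-3,
                          noise_level=0.02)
        result = train(model, examples, cfg)
        assert np.mean(result.loss_curve[-3:]) < result.loss_curve[0]

    def test_equal_seeds_equal_curves(self):
        examples = _tiny_dataset(n=2, L=8)
        curves = []
        for _ in range(2):
            model = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=1)
            cfg = TrainConfig(epochs=2, batch_tokens=30, rng_seed=5)
            curves.append(train(model, examples, cfg).loss_curve)
        np.testing.assert_array_equal(curves[0], curves[1])

    def test_empty_dataset_rejected(self):
        model = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())

    def test_loss_at_init_near_ln21(self):
        examples = _tiny_dataset(n=1, L=30)
        model = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=3).eval()
        ex = examples[0]
        rc = select_context_atoms(ex.structure, ex.context, SMALL_FC)
        with T.no_grad():
            state = model.encode(ex.structure, rc)
            _, lp = model.decode_logits(state, ex.structure.sequence,
                                        np.arange(30))
            loss = sequence_loss(lp, ex.structure.sequence,
                                 ex.structure.residue_mask)
        assert abs(float(loss.data) - np.log(21)) < 0.5

    def test_resume_from_checkpoint(self, tmp_path):
        examples = _tiny_dataset(n=1, L=8)
        path = tmp_path / "ckpt.npz"
        model = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=0)
        cfg = TrainConfig(epochs=2, batch_tokens=30, rng_seed=2)
        train(model, examples, cfg, checkpoint_path=path)
        model2 = SequenceDesignModel(SMALL_MC, SMALL_FC, seed=9)
        cfg4 = TrainConfig(epochs=4, batch_tokens=30, rng_seed=2)
        result = train(model2, examples, cfg4, checkpoint_path=path,
                       resume=True)
        # resumed run continues from epoch 2: only 2 more epochs of steps
        assert result.steps == 4


class TestContextShell:
    def _setup(self, distance):
        spec = FixtureSpec(chain_length=6, rng_seed=0)
        s = make_backbone(spec)
        s.sequence = encode_sequence("AAAAAA")
        coords = np.stack([place_sidechain("ALA", s.backbone_coords[i],
                                           np.zeros(4)) for i in range(6)])
        cb = coords[2, 4]
        direction = np.array([0.0, 0.0, 1.0])
        ctx = ContextAtoms(np.array([cb + distance * direction]),
                           np.array([30]), np.array([int(Category.METAL)]))
        return s, ctx, coords

    def test_inside_boundary_included(self):
        s, ctx, coords = self._setup(4.9)
        shell = context_shell_residues(s, ctx, 5.0, sidechain_coords=coords)
        assert 2 in shell

    def test_outside_boundary_excluded(self):
        s, ctx, coords = self._setup(5.1)
        shell = context_shell_residues(s, ctx, 5.0, sidechain_coords=coords)
        assert 2 not in shell

    def test_virtual_cb_fallback(self):
        s, ctx, _ = self._setup(4.0)
        shell = context_shell_residues(s, ctx, 5.0)
        assert 2 in shell

    def test_brute_force_oracle(self, rng):
        spec = FixtureSpec(chain_length=10, rng_seed=1)
        s = make_backbone(spec)
        s.sequence = encode_sequence("KLYWMENQRD")
        coords = np.stack([place_sidechain(
            ["LYS", "LEU", "TYR", "TRP", "MET", "GLU", "ASN", "GLN", "ARG",
             "ASP"][i], s.backbone_coords[i], rng.uniform(-np.pi, np.pi, 4))
            for i in range(10)])
        ctx = ContextAtoms(rng.standard_normal((5, 3)) * 8 + 5.0,
                           np.full(5, 6), np.zeros(5))
        shell = set(context_shell_residues(s, ctx, 5.0,
                                           sidechain_coords=coords).tolist())
        expected = set()
        for i in range(10):
            for slot in range(4, 14):
                if not np.isfinite(coords[i, slot]).all():
                    continue
                for atom in ctx.coords:
                    if np.linalg.norm(coords[i, slot] - atom) <= 5.0:
                        expected.add(i)
        assert shell == expected


class TestSequenceRecovery:
    def test_identical_design(self):
        native = np.array([1, 2, 3, 4])
        assert sequence_recovery([native.copy()], native, np.arange(4)) == 1.0

    def test_half_match(self):
        native = np.array([1, 2, 3, 4])
        design = np.array([1, 2, 0, 0])
        assert sequence_recovery([design], native, np.arange(4)) == 0.5

    def test_median(self):
        assert median_recovery([0.2, 0.6, 0.9]) == 0.6

    def test_empty_positions_nan(self):
        assert np.isnan(sequence_recovery([np.array([1])], np.array([1]),
                                          np.array([], dtype=int)))


class TestChiRecovery:
    def test_wraparound(self):
        pred = np.deg2rad(np.array([[359.0, 0, 0, 0]]))
        native = np.deg2rad(np.array([[1.0, 0, 0, 0]]))
        mask = np.array([[True, False, False, False]])
        out = chi_recovery(pred, native, mask, encode_sequence("S"))
        assert out[0] == 1.0

    def test_symmetric_phe_chi2(self):
        pred = np.deg2rad(np.array([[0.0, 95.0, 0, 0]]))
        native = np.deg2rad(np.array([[0.0, -85.0, 0, 0]]))
        mask = np.array([[True, True, False, False]])
        out = chi_recovery(pred, native, mask, encode_sequence("F"))
        assert out[1] == 1.0
        # an asymmetric residue with the same angles misses
        out_lys = chi_recovery(pred, native, mask, encode_sequence("K"))
        assert out_lys[1] == 0.0

    def test_hand_counted_table(self):
        pred = np.deg2rad(np.array([
            [10.0, 20.0, np.nan, np.nan],
            [-170.0, 95.0, np.nan, np.nan],
            [55.0, 182.0, np.nan, np.nan],
        ]))
        native = np.deg2rad(np.array([
            [15.0, 25.0, np.nan, np.nan],   # both within 10
            [175.0, -85.0, np.nan, np.nan],  # chi1 15 deg off (miss), chi2 sym hit
            [80.0, 170.0, np.nan, np.nan],   # chi1 miss, chi2 miss (LYS-like)
        ]))
        mask = np.ones((3, 4), dtype=bool)
        mask[:, 2:] = False
        seq = encode_sequence("LFK")
        out = chi_recovery(pred, native, mask, seq)
        np.testing.assert_allclose(out[:2], [1 / 3, 2 / 3])

    def test_position_restriction(self):
        pred = np.zeros((3, 4))
        native = np.zeros((3, 4))
        native[0, 0] = 3.0  # far off
        mask = np.zeros((3, 4), dtype=bool)
        mask[:, 0] = True
        out = chi_recovery(pred, native, mask, encode_sequence("SSS"),
                           positions=np.array([1, 2]))
        assert out[0] == 1.0


class TestConfidenceCalibration:
    def test_perfectly_informative(self):
        conf = np.array([10.0, 40.0, 90.0])
        rec = np.array([0.1, 0.4, 0.9])
        rho, defined = confidence_calibration(conf, rec)
        assert defined and rho == 1.0

    def test_constant_confidence_flagged(self):
        rho, defined = confidence_calibration(np.full(5, 3.0),
                                              np.linspace(0, 1, 5))
        assert not defined and np.isnan(rho)

    def test_matches_rank_correlation_oracle(self, rng):
        from scipy.stats import spearmanr
        conf = rng.random(20)
        rec = rng.random(20)
        rho, defined = confidence_calibration(conf, rec)
        assert defined
        np.testing.assert_allclose(rho, spearmanr(conf, rec).statistic)


class TestPureFunctions:
    def test_metrics_do_not_mutate_inputs(self, rng):
        native = rng.integers(0, 20, 10)
        design = rng.integers(0, 20, 10)
        native_copy, design_copy = native.copy(), design.copy()
        sequence_recovery([design], native, np.arange(10))
        np.testing.assert_array_equal(native, native_copy)
        np.testing.assert_array_equal(design, design_copy)

    def test_metrics_frame_columns(self):
        frame = metrics_frame([{"protein": "p1", "category": "metal",
                                "metric": "recovery", "value": 0.5}])
        assert list(frame.columns) == ["protein", "category", "metric", "value"]


class TestEvalReport:
    def test_medians_and_calibration(self):
        from contextmpnn.metrics import EvalReport
        report = EvalReport()
        report.add_protein("p1", "metal", 0.9, confidence=90.0,
                           chi_fractions=np.array([0.8, 0.6, np.nan, np.nan]))
        report.add_protein("p2", "metal", 0.5, confidence=50.0)
        report.add_protein("p3", "small_molecule", 0.7, confidence=70.0)
        medians = report.median_by_category()
        assert medians["metal"] == 0.7
        assert medians["small_molecule"] == 0.7
        rho, defined = report.calibration()
        assert defined and rho == 1.0
        frame = report.to_frame()
        assert set(frame["metric"]) == {"recovery", "confidence",
                                        "chi1_recovery", "chi2_recovery",
                                        "chi3_recovery", "chi4_recovery"}


class TestDatasetFilters:
    def test_resolution_and_length_filters(self):
        examples = _tiny_dataset(n=3, L=10)
        examples[0].resolution = 2.0
        examples[1].resolution = 4.0   # above the 3.5 A cutoff
        examples[2].resolution = None  # missing metadata: kept, warned
        warnings = []
        kept = filter_dataset(examples, TrainConfig(), warn=warnings.append)
        kept_ids = {id(ex) for ex in kept}
        assert id(examples[0]) in kept_ids and id(examples[2]) in kept_ids
        assert id(examples[1]) not in kept_ids
        assert len(warnings) == 1

    def test_length_filter(self):
        examples = _tiny_dataset(n=2, L=10)
        cfg = TrainConfig(max_length=10)
        assert filter_dataset(examples, cfg, warn=lambda *_: None) == []


class TestClusterTable:
    def test_load_and_split(self, tmp_path):
        path = tmp_path / "clusters.tsv"
        path.write_text("# id\tcluster\na\t0\nb\t0\nc\t1\nd\t2\n")
        table = load_cluster_table(path)
        assert table == {"a": 0, "b": 0, "c": 1, "d": 2}
        train_ids, heldout_ids = split_by_cluster(list("abcd"), table, 0.34, 0)
        # clusters stay together
        assert ("a" in train_ids) == ("b" in train_ids)
        assert set(train_ids) | set(heldout_ids) == set("abcd")
        assert not set(train_ids) & set(heldout_ids)
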
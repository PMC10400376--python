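"""Training harness: schedules, optimizer contracts, TTA, folds, ensembling."""

import numpy as np
import pytest

import legnet as lg
from conftest import micro_config


def _toy_records(n=200, seed=0, length=40):
    rng = np.random.default_rng(seed)
    seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, length)) for _ in range(n)]
    # simple learnable signal: expression tracks GC content
    exprs = [2.0 + 13.0 * (s.count("G") + s.count("C")) / length for s in seqs]
    return [lg.PromoterRecord(s, e) for s, e in zip(seqs, exprs)]


class TestOptimizerContract:
    def test_adamw_settings(self):
        model = lg.build_legnet(micro_config())
        opt = lg.make_optimizer(lg.TrainConfig(max_lr=0.005), model)
        assert opt.lr == pytest.approx(0.005)
        assert opt.weight_decay == pytest.approx(0.01)

    def test_lion_tenfold_rules(self):
        model = lg.build_legnet(micro_config())
        opt = lg.make_optimizer(lg.TrainConfig(max_lr=0.005, optimizer="lion"), model)
        assert opt.lr == pytest.approx(0.0005)
        assert opt.weight_decay == pytest.approx(0.1)

    def test_schedule_peak_equals_max_lr(self):
        cfg = lg.TrainConfig(max_lr=0.005)
        total = 500
        lrs = [lg.schedule_lr(s, total, cfg) for s in range(total)]
        assert max(lrs) == pytest.approx(0.005)
        assert lrs[0] == pytest.approx(0.005 / cfg.div_start)


class TestTrainPredictor:
    def test_loss_decreases_and_log_structure(self):
        records = _toy_records(1000)
        cfg = lg.TrainConfig(batch_size=64, epochs=2, seed=1, frame_length=40)
        model, log = lg.train_predictor(records, cfg, micro_config())
        assert len(log) == 2
        assert {"epoch", "mean_loss", "lr", "wall_time_s"} <= set(log[0])
        assert log[1]["mean_loss"] < log[0]["mean_loss"]

    def test_same_seed_identical_log(self):
        records = _toy_records(300)
        cfg = lg.TrainConfig(batch_size=64, epochs=1, seed=5, frame_length=40)
        _, log_a = lg.train_predictor(records, cfg, micro_config())
        _, log_b = lg.train_predictor(records, cfg, micro_config())
        assert log_a[0]["mean_loss"] == log_b[0]["mean_loss"]

    def test_mse_regression_toggle_runs(self):
        records = _toy_records(200)
        cfg = lg.TrainConfig(
            batch_size=64, epochs=1, seed=1, loss="mse_regression", frame_length=40
        )
        _, log = lg.train_predictor(records, cfg, micro_config())
        assert np.isfinite(log[0]["mean_loss"])

    def test_strict_doubling_augmentation_runs(self):
        records = _toy_records(128)
        cfg = lg.TrainConfig(
            batch_size=32, epochs=1, seed=1, augment="double", frame_length=40
        )
        _, log = lg.train_predictor(records, cfg, micro_config())
        assert np.isfinite(log[0]["mean_loss"])

    def test_reduce_on_plateau_needs_validation(self):
        records = _toy_records(64)
        cfg = lg.TrainConfig(scheduler="reduce_on_plateau", epochs=1, frame_length=40)
        with pytest.raises(ValueError):
            lg.train_predictor(records, cfg, micro_config())

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            lg.train_predictor([], lg.TrainConfig(), micro_config())


class TestPredictWithTTA:
    def test_outputs_in_range_and_ids(self, trained_micro_predictor):
        model, _, ds = trained_micro_predictor
        seqs = [r.insert for r in ds.test[:50]]
        ps = lg.predict_with_tta(model, seqs)
        assert len(ps.values) == 50
        assert np.all((ps.values >= 0) & (ps.values <= 17))
        assert ps.ids[0] == "seq0"

    def test_invalid_sequences_skipped_with_warning(self, trained_micro_predictor):
        model, _, _ = trained_micro_predictor
        with pytest.warns(UserWarning):
            ps = lg.predict_with_tta(
                model, [("ok", "ACGT" * 20), ("bad", "ACGU" * 20)]
            )
        assert ps.ids == ["ok"]
        assert ps.skipped[0][0] == "bad"

    def test_tta_invariant_to_reverse_complement_input(self, trained_micro_predictor):
        """Orientation symmetry of the averaged pair.

        TTA feeds {(s, is_reverse=0), (rc(s), is_reverse=1)}; for input rc(s)
        the same two nucleotide matrices appear with swapped orientation
        labels, so exact invariance holds for a model blind to the
        is_reverse channel. Verify by silencing that input channel.
        """
        import copy

        model, _, ds = trained_micro_predictor
        blind = copy.deepcopy(model)
        stem_conv = blind.stem.layers[0]
        stem_conv.weight.value[:, :, 5, :] = 0.0  # (g, og, cin, k): channel 5
        seqs = [r.insert for r in ds.test[:20]]
        rc = [lg.reverse_complement(s) for s in seqs]
        a = lg.predict_with_tta(blind, seqs).values
        b = lg.predict_with_tta(blind, rc).values
        np.testing.assert_allclose(a, b, atol=1e-4)


class TestEnsemble:
    def test_single_model_matches_tta(self, trained_micro_predictor):
        model, _, ds = trained_micro_predictor
        seqs = [r.insert for r in ds.test[:20]]
        np.testing.assert_allclose(
            lg.ensemble_predict([model], seqs).values,
            lg.predict_with_tta(model, seqs).values,
        )

    def test_duplicate_checkpoints_equal_single(self, trained_micro_predictor):
        model, _, ds = trained_micro_predictor
        seqs = [r.insert for r in ds.test[:20]]
        np.testing.assert_allclose(
            lg.ensemble_predict([model, model, model], seqs).values,
            lg.predict_with_tta(model, seqs).values,
            rtol=1e-6,
        )

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            lg.ensemble_predict([], ["ACGT"])


class TestKFold:
    def test_fold_sizes_and_coverage(self):
        records = _toy_records(100)
        train, val = lg.kfold_validation(records, k=10, fold_index=3, seed=0)
        assert len(val) == 10 and len(train) == 90
        together = sorted(r.insert for r in train + val)
        assert together == sorted(r.insert for r in records)
        assert not set(r.insert for r in train) & set(r.insert for r in val)

    def test_deterministic(self):
        records = _toy_records(50)
        a = lg.kfold_validation(records, 5, 0, seed=9)
        b = lg.kfold_validation(records, 5, 0, seed=9)
        assert a == b

    def test_validation_errors(self):
        records = _toy_records(5)
        with pytest.raises(ValueError):
            lg.kfold_validation(records, 10, 0)
        with pytest.raises(ValueError):
            lg.kfold_validation(records, 2, 2)
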
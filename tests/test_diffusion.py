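"""Cold-diffusion noising law, conditioned encoding and the generation loop."""

import numpy as np
import pytest
from scipy import stats

import legnet as lg
from legnet._rng import substream
from legnet.diffusion import (
    build_generator,
    expected_changed_fraction,
    generate_batch,
    mutate_codes,
    reconstruction_accuracy,
)
from conftest import micro_config


class TestMutate:
    def test_zero_is_identity(self):
        rng = substream(0, "t")
        assert lg.mutate("ACGTACGT", 0, rng) == "ACGTACGT"

    def test_single_event_hamming_one(self):
        rng = substream(1, "t")
        for _ in range(200):
            out = lg.mutate("ACGTACGTACGT", 1, rng)
            assert sum(a != b for a, b in zip(out, "ACGTACGTACGT")) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lg.mutate("ACGT", -1, substream(0, "t"))

    def test_changed_fraction_matches_closed_form(self):
        """Monte-Carlo fraction after k events vs the memoryless closed form."""
        rng = substream(2, "t")
        L, k, trials = 80, 300, 10_000
        codes = rng.integers(0, 4, size=(trials, L))
        mutated = mutate_codes(codes, np.full(trials, k), rng)
        frac = float((mutated != codes).mean())
        expected = expected_changed_fraction(L, k)
        assert expected == pytest.approx(0.745, abs=0.002)
        assert frac == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("L,k", [(30, 12), (80, 300)])
    def test_distributional_law_chi_square(self, L, k):
        """Exact per-position law: P(same) = 1/4 + (3/4)(1 - 4/(3L))^k.

        One focal position per independent trial, 4-category goodness of
        fit of the final base against the Markov-chain closed form.
        """
        rng = substream(3, f"law-{L}-{k}")
        trials = 10_000
        codes = np.zeros((trials, L), dtype=np.int64)  # start from all-A
        mutated = mutate_codes(codes, np.full(trials, k), rng)
        focal = mutated[:, L // 2]
        lam = 1.0 - 4.0 / (3.0 * L)
        p_same = 0.25 + 0.75 * lam**k
        p_other = (1.0 - p_same) / 3.0
        obs = np.bincount(focal, minlength=4)
        exp = np.array([p_same, p_other, p_other, p_other]) * trials
        chi = stats.chisquare(obs, exp)
        assert chi.pvalue > 1e-4


class TestGeneratorEncoding:
    def test_conditioning_channels(self):
        cfg = lg.DiffusionConfig()
        codes = np.zeros((2, 80), dtype=np.int64)
        x = lg.encode_generator_input(codes, 0, 8.5, cfg)
        assert x.shape == (2, 6, 80)
        assert np.all(x[:, 4] == 0.0)
        assert np.all(x[:, 5] == pytest.approx(0.5))
        x2 = lg.encode_generator_input(codes, cfg.max_mutations, 8.5, cfg)
        assert np.all(x2[:, 4] == 1.0)
        # two inputs differing only in expression differ in exactly one channel
        x3 = lg.encode_generator_input(codes, cfg.max_mutations, 17.0, cfg)
        diff = (x2 != x3).any(axis=2)
        assert diff.sum() == 2  # one channel per sequence

    def test_out_of_range_conditioning_rejected(self):
        cfg = lg.DiffusionConfig()
        codes = np.zeros((1, 80), dtype=np.int64)
        with pytest.raises(ValueError):
            lg.encode_generator_input(codes, cfg.max_mutations + 1, 5.0, cfg)
        with pytest.raises(ValueError):
            lg.encode_generator_input(codes, 0, 18.0, cfg)


class TestDiffusionConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            lg.DiffusionConfig(shift=200, iterations=100)
        with pytest.raises(ValueError):
            lg.DiffusionConfig(iterations=500, max_mutations=300)


class TestGeneratorTraining:
    def test_copy_task_learns_identity(self, sim_dataset_small):
        """n = 0 only: the denoiser must reproduce its input near-perfectly."""
        _, ds = sim_dataset_small
        records = ds.train[:1000]
        dcfg = lg.DiffusionConfig(seed=2)
        gcfg = lg.GeneratorTrainConfig(
            epochs=1, batch_size=64, batches_per_epoch=250, seed=2
        )
        gen, log = lg.train_generator(
            records, dcfg, gcfg, micro_config(), n_range=(0, 0)
        )
        assert log[-1]["val_accuracy"] >= 0.99

    def test_seeded_determinism(self, sim_dataset_small):
        _, ds = sim_dataset_small
        records = ds.train[:300]
        dcfg = lg.DiffusionConfig(seed=4)
        gcfg = lg.GeneratorTrainConfig(epochs=1, batch_size=32, batches_per_epoch=5, seed=4)
        _, log_a = lg.train_generator(records, dcfg, gcfg, micro_config(), n_range=(0, 10))
        _, log_b = lg.train_generator(records, dcfg, gcfg, micro_config(), n_range=(0, 10))
        assert log_a[0]["mean_loss"] == log_b[0]["mean_loss"]

    def test_harder_corruption_harder_to_denoise(self, trained_generator):
        gen, _, dcfg, ds = trained_generator
        sample = ds.train[:400]
        acc_easy = reconstruction_accuracy(gen, sample, dcfg, n_mutations=0, seed=1)
        acc_hard = reconstruction_accuracy(
            gen, sample, dcfg, n_mutations=dcfg.max_mutations, seed=1
        )
        assert acc_easy >= acc_hard


class TestGeneration:
    def test_output_alphabet_length_and_reproducibility(self, trained_generator):
        gen, _, dcfg, _ = trained_generator
        seqs_a = generate_batch(gen, [5.0, 10.0, 15.0], dcfg, seed=11)
        seqs_b = generate_batch(gen, [5.0, 10.0, 15.0], dcfg, seed=11)
        seqs_c = generate_batch(gen, [5.0, 10.0, 15.0], dcfg, seed=12)
        assert seqs_a == seqs_b
        assert seqs_a != seqs_c
        for s in seqs_a:
            assert len(s) == dcfg.insert_length
            assert set(s) <= set("ACGT")

    def test_degenerate_single_iteration(self, trained_generator):
        gen, _, _, _ = trained_generator
        cfg = lg.DiffusionConfig(iterations=1, shift=0, seed=0)
        out = lg.generate(gen, 9.0, cfg, seed=3)
        assert len(out) == cfg.insert_length

    def test_schedule_gap_equals_shift(self, trained_generator):
        """Declared count overstates the actual re-corruption by `shift`."""
        gen, _, _, _ = trained_generator
        cfg = lg.DiffusionConfig(iterations=50, shift=10, seed=0)
        _, schedule = generate_batch(gen, [8.0], cfg, seed=1, record_schedule=True)
        for step in schedule[:-1]:
            if step["reintroduced"] > 0:
                assert step["declared_next"] - step["reintroduced"] == cfg.shift

    def test_corruption_stop_rule_stops_earlier(self, trained_generator):
        gen, _, _, _ = trained_generator
        base = dict(iterations=50, shift=10, seed=0)
        _, s_declared = generate_batch(
            gen, [8.0], lg.DiffusionConfig(**base), seed=1, record_schedule=True
        )
        _, s_corruption = generate_batch(
            gen,
            [8.0],
            lg.DiffusionConfig(**base, stop_rule="corruption"),
            seed=1,
            record_schedule=True,
        )
        assert len(s_corruption) < len(s_declared)


class TestScoreDesigns:
    def test_perfect_predictions(self, trained_micro_predictor, rng):
        model, _, ds = trained_micro_predictor
        seqs = [r.insert for r in ds.test[:10]]
        preds = lg.predict_with_tta(model, seqs).values
        out = lg.score_designs(model, seqs, preds)
        assert out["pearson"] == pytest.approx(1.0, abs=1e-9)
        assert np.all((out["predicted"] >= 0) & (out["predicted"] <= 17))

    def test_constant_targets_reported_missing(self, trained_micro_predictor):
        model, _, ds = trained_micro_predictor
        seqs = [r.insert for r in ds.test[:5]]
        out = lg.score_designs(model, seqs, [8.0] * 5)
        assert np.isnan(out["pearson"])
        assert "reason" in out
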
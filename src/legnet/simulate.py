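"""Synthetic sorting-bin reporter assay: oracle, measurement model, datasets.

A desk-scale stand-in for the real yeast experiment in which millions of
random 80-bp inserts drive a fluorescent reporter and cells are sorted into
18 expression bins. The simulator has two layers:

* a deterministic *oracle* mapping a sequence to its true expression: a
  planted grammar of position-weight-matrix motifs, each contributing its
  best sliding-window log-odds score times a signed effect weight, passed
  through an affine map clamped to [0, 17];
* a stochastic *measurement*: each sequence is observed in m ~ 1 + Poisson(λ)
  cells, every cell lands in bin clamp(round(e_true + Normal(0, sd)), 0, 17),
  and the recorded expression is the mean bin number. Sequences seen in one
  cell are singletons and carry integer readouts, reproducing the structure
  the singleton input channel exists for.

Train tables use λ = 1.5 (≈22% singletons, like the noisy, singleton-heavy
real training data); test tables use λ = 20 to mimic the higher-replication
held-out measurements. The truth table carries oracle values and exists only
for evaluation: the table reader refuses to parse files named ``*.truth.*``
so that training code cannot ingest it by accident.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import substream
from .codec import PromoterRecord, write_gpra_table

__all__ = [
    "SimulatorConfig",
    "Simulator",
    "SimulatedDataset",
    "oracle_expression",
    "simulate_measurement",
    "simulate_dataset",
]

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class SimulatorConfig:
    n_sequences: int = 50_000
    n_test: int = 2_000
    insert_length: int = 80
    n_motifs: int = 5
    motif_length_range: tuple[int, int] = (6, 10)
    # signed effect weights, one per motif; positive = activator
    motif_effects: tuple[float, ...] = (2.0, 1.5, 1.0, -1.0, -1.5)
    strand_policy: str = "forward_only"  # or "both_strands"
    # affine map from raw grammar score to expression; None = auto-calibrated
    expression_scale: tuple[float, float] | None = None
    cells_lambda: float = 1.5
    test_cells_lambda: float = 20.0
    sort_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.insert_length < 1:
            raise ValueError("n_sequences and insert_length must be positive")
        if self.cells_lambda < 0 or self.test_cells_lambda < 0:
            raise ValueError("cell-count rates must be non-negative")
        if self.sort_noise_sd < 0:
            raise ValueError("sort_noise_sd must be non-negative")
        if self.strand_policy not in ("forward_only", "both_strands"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")
        if len(self.motif_effects) != self.n_motifs:
            raise ValueError("need one effect weight per motif")
        if self.motif_length_range[1] > self.insert_length:
            raise ValueError("motif longer than insert")


@dataclass
class SimulatedDataset:
    train: list[PromoterRecord]
    test: list[PromoterRecord]
    truth: dict[str, float]  # sequence -> oracle expression (train + test)

    def write(self, prefix: str | Path) -> tuple[Path, Path, Path]:
        prefix = Path(prefix)
        train_p = prefix.with_name(prefix.name + ".train.tsv")
        test_p = prefix.with_name(prefix.name + ".test.tsv")
        truth_p = prefix.with_name(prefix.name + ".truth.tsv")
        write_gpra_table(self.train, train_p)
        write_gpra_table(self.test, test_p)
        with open(truth_p, "w") as fh:
            for seq, e in self.truth.items():
                fh.write(f"{seq}\t{e:.6f}\n")
        return train_p, test_p, truth_p


class Simulator:
    """Seeded instance of the planted-grammar oracle and measurement model."""

    def __init__(self, cfg: SimulatorConfig):
        self.cfg = cfg
        rng = substream(cfg.seed, "simulator-motifs")
        lo, hi = cfg.motif_length_range
        self.motifs: list[np.ndarray] = []
        for _ in range(cfg.n_motifs):
            w = int(rng.integers(lo, hi + 1))
            # information-rich columns: sparse Dirichlet favours near-consensus
            probs = rng.dirichlet(np.full(4, 0.2), size=w)
            probs = np.clip(probs, 1e-3, None)
            probs /= probs.sum(axis=1, keepdims=True)
            self.motifs.append(np.log(probs / 0.25).astype(np.float64))
        self.effects = np.asarray(cfg.motif_effects, dtype=np.float64)
        if cfg.expression_scale is not None:
            self.offset, self.scale = map(float, cfg.expression_scale)
        else:
            # calibrate the affine map on a fixed reference sample so the
            # oracle uses most of the 0-17 range: mean -> 8.5, +-3 sd -> span
            cal = substream(cfg.seed, "simulator-calibration")
            sample = cal.integers(0, 4, size=(2048, cfg.insert_length))
            raw = self._raw_scores(sample)
            mu, sd = float(raw.mean()), float(raw.std())
            self.scale = 17.0 / (6.0 * sd) if sd > 0 else 0.0
            self.offset = 8.5 - mu * self.scale

    # -- oracle ------------------------------------------------------------
    def _raw_scores(self, codes: np.ndarray) -> np.ndarray:
        """Sum of effect-weighted best window scores; codes (n, L) ints."""
        n, L = codes.shape
        total = np.zeros(n)
        from numpy.lib.stride_tricks import sliding_window_view

        for lo_mat, effect in zip(self.motifs, self.effects):
            w = lo_mat.shape[0]
            wins = sliding_window_view(codes, w, axis=1)  # (n, L-w+1, w)
            scores = lo_mat[np.arange(w), wins].sum(axis=2)
            best = scores.max(axis=1)
            if self.cfg.strand_policy == "both_strands":
                rc = lo_mat[::-1, ::-1][np.arange(w), wins].sum(axis=2)
                best = np.maximum(best, rc.max(axis=1))
            total += effect * best
        return total

    def oracle(self, sequences: Sequence[str] | np.ndarray) -> np.ndarray:
        """True expression in [0, 17] for sequences (strings or code array)."""
        codes = self._to_codes(sequences)
        if codes.shape[1] != self.cfg.insert_length:
            raise ValueError(
                f"expected length {self.cfg.insert_length}, got {codes.shape[1]}"
            )
        return np.clip(self._raw_scores(codes) * self.scale + self.offset, 0.0, 17.0)

    @staticmethod
    def _to_codes(sequences) -> np.ndarray:
        if isinstance(sequences, np.ndarray):
            return sequences
        return np.array(
            [[_CODE[b] for b in s.upper()] for s in sequences], dtype=np.int64
        )

    # -- measurement -------------------------------------------------------
    def measure(
        self, e_true: np.ndarray, rng: np.random.Generator, cells_lambda: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(measured expression, is_singleton) under the sorting-bin model."""
        e_true = np.asarray(e_true, dtype=np.float64)
        lam = self.cfg.cells_lambda if cells_lambda is None else cells_lambda
        m = 1 + rng.poisson(lam, size=e_true.shape)
        measured = np.empty_like(e_true)
        # draw per-cell bins in one flat pass
        reps = np.repeat(e_true, m)
        noise = rng.normal(0.0, self.cfg.sort_noise_sd, size=reps.shape)
        bins = np.clip(np.round(reps + noise), 0, 17)
        splits = np.cumsum(m)[:-1]
        for i, cell_bins in enumerate(np.split(bins, splits)):
            measured[i] = cell_bins.mean()
        return measured, m == 1

    # -- dataset -----------------------------------------------------------
    def dataset(self) -> SimulatedDataset:
        cfg = self.cfg
        rng = substream(cfg.seed, "simulator-dataset")
        n_total = cfg.n_sequences + cfg.n_test
        codes = rng.integers(0, 4, size=(int(n_total * 1.05) + 16, cfg.insert_length))
        # dedupe to keep train/test disjoint
        _, unique_idx = np.unique(
            np.ascontiguousarray(codes).view([("", codes.dtype)] * cfg.insert_length),
            return_index=True,
        )
        codes = codes[np.sort(unique_idx)][:n_total]
        if len(codes) < n_total:
            raise RuntimeError("failed to draw enough unique sequences")
        seqs = ["".join(_ALPHABET[c] for c in row) for row in codes]
        e_true = self.oracle(codes)
        tr_measured, tr_single = self.measure(e_true[: cfg.n_sequences], rng)
        te_measured, te_single = self.measure(
            e_true[cfg.n_sequences :], rng, cells_lambda=cfg.test_cells_lambda
        )
        train = [
            PromoterRecord(s, float(m), bool(f))
            for s, m, f in zip(seqs[: cfg.n_sequences], tr_measured, tr_single)
        ]
        test = [
            PromoterRecord(s, float(m), bool(f))
            for s, m, f in zip(seqs[cfg.n_sequences :], te_measured, te_single)
        ]
        truth = {s: float(e) for s, e in zip(seqs, e_true)}
        return SimulatedDataset(train=train, test=test, truth=truth)


@lru_cache(maxsize=8)
def _simulator(cfg: SimulatorConfig) -> Simulator:
    return Simulator(cfg)


def oracle_expression(sequence: str, cfg: SimulatorConfig) -> float:
    """Deterministic true expression of one insert under the planted grammar."""
    return float(_simulator(cfg).oracle([sequence])[0])


def simulate_measurement(
    e_true: float, cfg: SimulatorConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    """One noisy sorting-bin measurement of a true expression value."""
    if not 0.0 <= e_true <= 17.0:
        raise ValueError("e_true outside [0, 17]")
    measured, single = _simulator(cfg).measure(np.array([e_true]), rng)
    return float(measured[0]), bool(single[0])


def simulate_dataset(cfg: SimulatorConfig) -> SimulatedDataset:
    """Reproducible (train, test, truth) tables; train/test disjoint."""
    return _simulator(cfg).dataset()
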
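"""Training loops, schedules, test-time augmentation and seed ensembling.

The reference regime trains with AdamW (weight decay 0.01) under a two-phase
cosine one-cycle schedule peaking at 0.005, in epochs of 1000 batches of
1024 sequences. Desk-scale presets shrink the batch and epoch counts but
keep the same mechanics. Swapping AdamW for Lion automatically applies the
10-fold rules (lr / 10, weight decay x 10).

Orientation augmentation gives the model each sequence in native or
reverse-complement form (is_reverse channel 0/1). By default each sampled
record is assigned a random orientation per epoch — both forms appear in
expectation, at half the memory of strict doubling; ``augment='double'``
feeds both orientations of every batch for exactness.

Prediction always uses is_singleton = 0 and test-time augmentation:
the reported expression is the mean of the soft-argmax decodings of the
forward and reverse-complement passes.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import spawn_seed, substream
from .arch import LegNet, LegNetConfig, build_legnet
from .codec import (
    CodecError,
    FlankContext,
    PromoterRecord,
    encode_batch,
    reverse_complement_batch,
)
from .labels import N_BINS, expression_to_bins
from .nn.layers import log_softmax, softmax
from .nn.optim import AdamW, Lion, ReduceLROnPlateau, one_cycle_lr

__all__ = [
    "TrainConfig",
    "PredictionSet",
    "make_optimizer",
    "schedule_lr",
    "train_predictor",
    "predict_with_tta",
    "ensemble_predict",
    "kfold_validation",
]

_BIN_INDEX = np.arange(N_BINS, dtype=np.float32)


@dataclass(frozen=True)
class TrainConfig:
    max_lr: float = 0.005
    weight_decay: float = 0.01
    optimizer: str = "adamw"  # or "lion"
    scheduler: str = "one_cycle"  # or "reduce_on_plateau"
    batch_size: int = 1024
    batches_per_epoch: int | None = None  # None: one pass over the data
    epochs: int = 5
    warmup_fraction: float = 0.3
    div_start: float = 25.0
    div_final: float = 1e4
    plateau_factor: float = 0.1
    plateau_patience: int = 3
    seed: int = 0
    loss: str = "kl_soft_classification"  # or "mse_regression"
    augment: str = "random_orientation"  # or "double" or "none"
    # encoded frame length; the assay default is 150 bp (insert + 5' flank).
    # Desk-scale runs on the bundled simulator may train directly on the
    # 80-bp inserts since the default flank is all-N (all-zero columns).
    frame_length: int = 150

    def __post_init__(self) -> None:
        if self.max_lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("max_lr, batch_size and epochs must be positive")
        if self.optimizer not in ("adamw", "lion"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.scheduler not in ("one_cycle", "reduce_on_plateau"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")
        if self.loss not in ("kl_soft_classification", "mse_regression"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.augment not in ("random_orientation", "double", "none"):
            raise ValueError(f"unknown augment mode {self.augment!r}")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must lie in (0, 1)")


@dataclass
class PredictionSet:
    ids: list[str]
    values: np.ndarray  # predicted expression, in [0, 17]
    bin_distributions: np.ndarray | None = None  # (n, 18) TTA-averaged
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def make_optimizer(cfg: TrainConfig, model: LegNet):
    """AdamW as configured; Lion with the automatic 10-fold lr/decay rules."""
    if cfg.optimizer == "adamw":
        return AdamW(model.params(), lr=cfg.max_lr, weight_decay=cfg.weight_decay)
    return Lion(model.params(), lr=cfg.max_lr / 10.0, weight_decay=cfg.weight_decay * 10.0)


def schedule_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """One-cycle learning rate for a step of a run with ``total_steps``."""
    return one_cycle_lr(
        step,
        total_steps,
        max_lr=cfg.max_lr if cfg.optimizer == "adamw" else cfg.max_lr / 10.0,
        warmup_fraction=cfg.warmup_fraction,
        div_start=cfg.div_start,
        div_final=cfg.div_final,
    )


def _loss_and_grad(scores: np.ndarray, targets: np.ndarray, y: np.ndarray, loss: str):
    b = scores.shape[0]
    if loss == "kl_soft_classification":
        logp = log_softmax(scores, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tlogt = np.where(targets > 0, targets * np.log(targets), 0.0)
        value = float(np.mean((tlogt - targets * logp).sum(axis=-1)))
        grad = (softmax(scores, axis=-1) - targets) / b
    else:  # mse_regression through the soft-argmax head
        p = softmax(scores, axis=-1)
        pred = p @ _BIN_INDEX
        resid = pred - y
        value = float(np.mean(resid**2))
        grad = (2.0 * resid / b)[:, None] * p * (_BIN_INDEX[None, :] - pred[:, None])
    return value, grad.astype(np.float32)


def _epoch_index_stream(n: int, needed: int, rng: np.random.Generator) -> np.ndarray:
    """Sample without replacement within permutation chunks until ``needed``."""
    chunks = []
    got = 0
    while got < needed:
        perm = rng.permutation(n)
        chunks.append(perm)
        got += n
    return np.concatenate(chunks)[:needed]


def train_predictor(
    train: Sequence[PromoterRecord],
    cfg: TrainConfig,
    arch: LegNetConfig,
    flank: FlankContext | None = None,
    validation: Sequence[PromoterRecord] | None = None,
) -> tuple[LegNet, list[dict]]:
    """Train a predictor; returns (model, per-epoch log).

    Fully deterministic given ``cfg.seed``: initialisation, shuffling and
    orientation assignment all derive from named substreams of it.
    """
    if not train:
        raise ValueError("empty training set")
    if cfg.scheduler == "reduce_on_plateau" and validation is None:
        raise ValueError("reduce_on_plateau needs a validation split")
    flank = flank or FlankContext()
    X = encode_batch(
        [r.insert for r in train], flank, [r.is_singleton for r in train],
        frame_length=cfg.frame_length,
    )
    y = np.array([r.expression for r in train], dtype=np.float32)
    T = expression_to_bins(y).astype(np.float32)

    model = build_legnet(arch, seed=spawn_seed(cfg.seed, "model-init"))
    model.frame_length = cfg.frame_length
    opt = make_optimizer(cfg, model)
    shuffle_rng = substream(cfg.seed, "shuffle")
    orient_rng = substream(cfg.seed, "orientation")

    n = len(train)
    steps_per_epoch = cfg.batches_per_epoch or int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    plateau = (
        ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience)
        if cfg.scheduler == "reduce_on_plateau"
        else None
    )

    log: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        idx_stream = _epoch_index_stream(n, steps_per_epoch * cfg.batch_size, shuffle_rng)
        losses = []
        lr = opt.lr
        for b in range(steps_per_epoch):
            idx = idx_stream[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            Xb, Tb, yb = X[idx], T[idx], y[idx]
            if cfg.augment == "random_orientation":
                flip = orient_rng.random(len(idx)) < 0.5
                if flip.any():
                    Xb = Xb.copy()
                    Xb[flip] = reverse_complement_batch(Xb[flip])
            elif cfg.augment == "double":
                Xb = np.concatenate([Xb, reverse_complement_batch(Xb)], axis=0)
                Tb = np.concatenate([Tb, Tb], axis=0)
                yb = np.concatenate([yb, yb], axis=0)
            if cfg.scheduler == "one_cycle":
                lr = schedule_lr(step, total_steps, cfg)
                opt.lr = lr
            scores = model.forward(Xb, training=True)
            loss, grad = _loss_and_grad(scores, Tb, yb, cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step} (lr={lr:.3g})"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            step += 1
        entry = {
            "epoch": epoch,
            "mean_loss": float(np.mean(losses)),
            "lr": float(lr),
            "wall_time_s": time.time() - t0,
        }
        if validation:
            val = predict_with_tta(model, [r.insert for r in validation], flank)
            val_y = np.array([r.expression for r in validation])
            val_T = expression_to_bins(val_y).astype(np.float32)
            Xv = encode_batch(
                [r.insert for r in validation], flank, frame_length=cfg.frame_length
            )
            sv = model.forward(Xv, training=False)
            vloss, _ = _loss_and_grad(sv, val_T, val_y.astype(np.float32), cfg.loss)
            entry["val_loss"] = vloss
            if np.std(val_y) > 0 and np.std(val.values) > 0:
                entry["val_pearson"] = float(np.corrcoef(val.values, val_y)[0, 1])
            if plateau is not None:
                opt.lr = plateau.step(vloss)
        log.append(entry)
    return model, log


def _as_id_seq(sequences) -> list[tuple[str, str]]:
    out = []
    for i, s in enumerate(sequences):
        if isinstance(s, tuple):
            out.append((str(s[0]), s[1]))
        else:
            out.append((f"seq{i}", s))
    return out


def predict_with_tta(
    model: LegNet,
    sequences,
    flank: FlankContext | None = None,
    batch_size: int = 512,
    frame_length: int | None = None,
) -> PredictionSet:
    """Expression per sequence, averaged over both orientations.

    ``sequences``: iterable of strings or (id, string) pairs. Invalid
    sequences are skipped with a warning and listed in ``skipped``. The
    frame length defaults to the one the model was trained with.
    """
    flank = flank or FlankContext()
    if frame_length is None:
        frame_length = getattr(model, "frame_length", 150)
    pairs = _as_id_seq(sequences)
    ids, seqs, skipped = [], [], []
    for sid, seq in pairs:
        try:
            PromoterRecord(seq, 0.0)
            ids.append(sid)
            seqs.append(seq)
        except CodecError as err:
            warnings.warn(f"skipping sequence {sid}: {err}")
            skipped.append((sid, str(err)))
    values = np.empty(len(seqs), dtype=np.float64)
    dists = np.empty((len(seqs), N_BINS), dtype=np.float64)
    for start in range(0, len(seqs), batch_size):
        chunk = seqs[start : start + batch_size]
        fwd = encode_batch(chunk, flank, frame_length=frame_length)  # is_singleton stays 0
        rev = reverse_complement_batch(fwd)
        p_fwd = model.predict_proba(fwd)
        p_rev = model.predict_proba(rev)
        d = 0.5 * (p_fwd + p_rev)
        dists[start : start + len(chunk)] = d
        values[start : start + len(chunk)] = 0.5 * (
            p_fwd @ _BIN_INDEX + p_rev @ _BIN_INDEX
        )
    return PredictionSet(ids=ids, values=values, bin_distributions=dists, skipped=skipped)


def ensemble_predict(
    models: Sequence[LegNet],
    sequences,
    flank: FlankContext | None = None,
    batch_size: int = 512,
) -> PredictionSet:
    """Mean of each model's TTA expression prediction, per sequence."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    first = predict_with_tta(models[0], sequences, flank, batch_size)
    acc = first.values.copy()
    dacc = first.bin_distributions.copy()
    kept = [(i, s) for i, s in _as_id_seq(sequences) if i in set(first.ids)]
    for m in models[1:]:
        ps = predict_with_tta(m, kept, flank, batch_size)
        acc += ps.values
        dacc += ps.bin_distributions
    k = len(models)
    return PredictionSet(
        ids=first.ids, values=acc / k, bin_distributions=dacc / k, skipped=first.skipped
    )


def kfold_validation(
    records: Sequence[PromoterRecord], k: int, fold_index: int, seed: int = 0
) -> tuple[list[PromoterRecord], list[PromoterRecord]]:
    """Deterministic contiguous-block k-fold split after a seeded shuffle."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= fold_index < k:
        raise ValueError(f"fold_index {fold_index} outside [0, {k})")
    if len(records) < k:
        raise ValueError(f"need at least {k} records for {k}-fold validation")
    perm = substream(seed, "kfold").permutation(len(records))
    bounds = np.linspace(0, len(records), k + 1).astype(int)
    lo, hi = bounds[fold_index], bounds[fold_index + 1]
    val_idx = set(perm[lo:hi].tolist())
    train = [records[i] for i in perm if i not in val_idx]
    val = [records[i] for i in perm[lo:hi]]
    return train, val
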
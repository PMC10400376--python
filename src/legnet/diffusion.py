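"""Cold-diffusion promoter design.

The degradation process is memoryless point substitution: one mutation event
picks a position uniformly and replaces the current base with one of the
three others uniformly, never checking whether it reverts an earlier edit.
After k events on an L-mer the expected fraction of changed positions has
the closed form (3/4) * (1 - (1 - 4/(3L))^k), approaching 3/4 — a fully
random sequence — as k grows.

A denoiser network ("generator") is trained to invert this process: given a
corrupted sequence, the declared number of mutations n and the expression of
the original sequence (both broadcast as constant input channels), it emits
per-position logits over the four bases and is trained with cross-entropy
against the original sequence, for n drawn uniformly from 0..max_mutations.

Generation runs the restoration loop on a uniformly random sequence while
conditioning on the *target* expression: denoise with declared count n,
decrement n, re-corrupt with max(n - shift, 0) substitutions, repeat until
the counter hits zero. The non-zero shift deliberately overstates the
remaining corruption so the model keeps making edits and drifts away from
the random start. Designs are then verified with a trained predictor.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import spawn_seed, substream
from .arch import Block, LegNet, LegNetConfig
from .codec import FlankContext, PromoterRecord
from .evaluation import correlations
from .nn.layers import log_softmax, softmax
from .nn.optim import AdamW
from .training import PredictionSet, predict_with_tta

__all__ = [
    "DiffusionConfig",
    "GeneratorTrainConfig",
    "DenoiserNet",
    "build_generator",
    "mutate",
    "mutate_codes",
    "expected_changed_fraction",
    "encode_generator_input",
    "train_generator",
    "generate",
    "generate_batch",
    "score_designs",
]

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}

N_BASES = 4
GEN_CHANNELS = 6  # 4 one-hot + mutation-count channel + expression channel


@dataclass(frozen=True)
class DiffusionConfig:
    max_mutations: int = 300
    iterations: int = 100
    shift: int = 30
    insert_length: int = 80
    conditioning: str = "extra_channels"
    stop_rule: str = "declared"  # or "corruption"
    decode: str = "argmax"  # or "sample"
    sample_temperature: float = 1.0  # softmax temperature for decode="sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.shift < self.iterations <= self.max_mutations:
            raise ValueError("require 0 <= shift < iterations <= max_mutations")
        if self.insert_length < 1:
            raise ValueError("insert_length must be positive")
        if self.conditioning != "extra_channels":
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.stop_rule not in ("declared", "corruption"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.decode not in ("argmax", "sample"):
            raise ValueError(f"unknown decode {self.decode!r}")
        if self.sample_temperature <= 0:
            raise ValueError("sample_temperature must be positive")


@dataclass(frozen=True)
class GeneratorTrainConfig:
    epochs: int = 200
    optimizer: str = "adamw"
    lr: float = 0.001
    weight_decay: float = 0.01
    batch_size: int = 1024
    batches_per_epoch: int = 1000
    train_val_ratio: tuple[int, int] = (4, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.batches_per_epoch) < 1:
            raise ValueError("epochs, batch_size, batches_per_epoch must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if min(self.train_val_ratio) < 1:
            raise ValueError("train_val_ratio parts must be positive")


# ---------------------------------------------------------------------------
# the memoryless substitution process


def mutate_codes(codes: np.ndarray, k: np.ndarray | int, rng: np.random.Generator) -> np.ndarray:
    """Apply k memoryless substitution events per row of an (n, L) code array.

    Each event adds a uniform offset from {1, 2, 3} (mod 4) at a uniformly
    chosen position; offsets compose additively, which is distributionally
    identical to sequentially replacing the current base with one of the
    three others.
    """
    codes = np.asarray(codes)
    single = codes.ndim == 1
    if single:
        codes = codes[None, :]
    n, L = codes.shape
    ks = np.full(n, k, dtype=np.int64) if np.isscalar(k) else np.asarray(k, dtype=np.int64)
    if (ks < 0).any():
        raise ValueError("mutation count must be non-negative")
    total = int(ks.sum())
    acc = np.zeros((n, L), dtype=np.int64)
    if total:
        rows = np.repeat(np.arange(n), ks)
        cols = rng.integers(0, L, size=total)
        offs = rng.integers(1, 4, size=total)
        np.add.at(acc, (rows, cols), offs)
    out = (codes + acc) % 4
    return out[0] if single else out


def mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """k memoryless substitution events on a DNA string."""
    if k < 0:
        raise ValueError("mutation count must be non-negative")
    codes = np.array([_CODE[b] for b in seq.upper()], dtype=np.int64)
    return "".join(_ALPHABET[c] for c in mutate_codes(codes, k, rng))


def expected_changed_fraction(length: int, k: int) -> float:
    """Closed-form expected fraction of positions differing after k events."""
    return 0.75 * (1.0 - (1.0 - 4.0 / (3.0 * length)) ** k)


# ---------------------------------------------------------------------------
# conditioned encoding and the denoiser network


def encode_generator_input(
    codes: np.ndarray,
    n_declared: np.ndarray | int,
    expression: np.ndarray | float,
    cfg: DiffusionConfig,
) -> np.ndarray:
    """(n, 6, L) conditioned input: one-hot + n/max_mutations + expression/17."""
    codes = np.atleast_2d(np.asarray(codes))
    n, L = codes.shape
    nd = np.broadcast_to(np.asarray(n_declared, dtype=np.float64), (n,))
    ex = np.broadcast_to(np.asarray(expression, dtype=np.float64), (n,))
    if (nd < 0).any() or (nd > cfg.max_mutations).any():
        raise ValueError("declared mutation count outside [0, max_mutations]")
    if (ex < 0).any() or (ex > 17).any():
        raise ValueError("conditioning expression outside [0, 17]")
    x = np.zeros((n, GEN_CHANNELS, L), dtype=np.float32)
    x[np.arange(n)[:, None], codes, np.arange(L)[None, :]] = 1.0
    x[:, 4] = (nd / cfg.max_mutations)[:, None]
    x[:, 5] = (ex / 17.0)[:, None]
    return x


class DenoiserNet(LegNet):
    """Conditioned denoiser: LegNet trunk, per-position 4-way head, no pooling.

    As is standard for conditional denoising networks, the two conditioning
    channels (mutation count, target expression) are re-injected by
    concatenation at the input of every block rather than seen only by the
    stem — otherwise the reconstruction ("copy") signal dominates training
    and the network learns to ignore the conditioning. The stem consumes
    the full 6-channel input; each block consumes its predecessor's output
    plus the 2 conditioning channels.
    """

    COND_CHANNELS = 2

    def __init__(self, config: LegNetConfig, seed: int = 0):
        from ._rng import substream
        from .nn.layers import BatchNorm1d, Conv1d, Sequential, SiLU

        self.config = config
        self.seed = int(seed)
        rng = substream(seed, "init")
        k = config.kernel_size
        self.stem = Sequential(
            Conv1d(config.in_channels, config.stem_channels, k, bias=False, rng=rng, name="stem"),
            BatchNorm1d(config.stem_channels, name="stem_bn"),
            SiLU(),
        )
        self.blocks = []
        in_ch = config.stem_channels
        for i, out_ch in enumerate(config.block_channels):
            block_in = in_ch + self.COND_CHANNELS
            e = config.expansion_width(block_in)
            if config.conv_mode == "grouped" and e % config.group_size:
                # round up so the grouped spatial conv stays well-formed
                e += config.group_size - e % config.group_size
            self.blocks.append(
                Block(config, block_in, out_ch, rng, f"block{i}", exp_ch=e)
            )
            in_ch = out_ch
        self.head_conv = Conv1d(in_ch, config.n_bins, 1, bias=True, rng=rng, name="head")

    def _stages(self):
        return [self.stem, *self.blocks, self.head_conv]

    def params(self):
        return [p for stage in self._stages() for p in stage.params()]

    def forward(self, x, training: bool = False):
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (batch, {self.config.in_channels}, length) input, got {x.shape}"
            )
        xt = np.ascontiguousarray(np.asarray(x, dtype=np.float32).transpose(1, 0, 2))
        cond = xt[4:6]  # (2, batch, length) conditioning planes
        h = self.stem.forward(xt, training)
        for block in self.blocks:
            h = block.forward(np.concatenate([h, cond], axis=0), training)
        logits = self.head_conv.forward(h, training)
        return logits.transpose(1, 0, 2)  # (batch, 4, length)

    def backward(self, dy):
        dh = self.head_conv.backward(np.ascontiguousarray(dy.transpose(1, 0, 2)))
        dcond_total = None
        for block in reversed(self.blocks):
            dz = block.backward(dh)
            dh = np.ascontiguousarray(dz[: dz.shape[0] - self.COND_CHANNELS])
            dcond = dz[dz.shape[0] - self.COND_CHANNELS :]
            dcond_total = dcond if dcond_total is None else dcond_total + dcond
        dx = self.stem.backward(dh)
        dx[4:6] += dcond_total
        return dx.transpose(1, 0, 2)


def build_generator(arch: LegNetConfig, seed: int = 0) -> DenoiserNet:
    cfg = LegNetConfig(
        **{
            **arch.to_dict(),
            "in_channels": GEN_CHANNELS,
            "n_bins": N_BASES,
            "final_activation_before_pool": False,
        }
    )
    return DenoiserNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# generator training


def _records_to_codes(records: Sequence[PromoterRecord]) -> tuple[np.ndarray, np.ndarray]:
    codes = np.array(
        [[_CODE[b] for b in r.insert] for r in records], dtype=np.int64
    )
    expr = np.array([r.expression for r in records], dtype=np.float64)
    return codes, expr


def train_generator(
    records: Sequence[PromoterRecord],
    diffusion_cfg: DiffusionConfig,
    gen_cfg: GeneratorTrainConfig,
    arch: LegNetConfig,
    n_range: tuple[int, int] | None = None,
) -> tuple[DenoiserNet, list[dict]]:
    """Train the denoiser to reconstruct originals from corrupted inputs.

    Per example: n ~ uniform{n_range or 0..max_mutations}, corrupt with
    ``mutate``, condition on (n, original expression), minimise mean
    per-position cross-entropy. Data are split train:validation by
    ``gen_cfg.train_val_ratio`` after a seeded shuffle.
    """
    if not records:
        raise ValueError("empty training set")
    codes, expr = _records_to_codes(records)
    if codes.shape[1] != diffusion_cfg.insert_length:
        raise ValueError("record length does not match diffusion insert_length")
    lo, hi = n_range if n_range is not None else (0, diffusion_cfg.max_mutations)
    if not 0 <= lo <= hi <= diffusion_cfg.max_mutations:
        raise ValueError("invalid n_range")

    split_rng = substream(gen_cfg.seed, "generator-split")
    perm = split_rng.permutation(len(records))
    a, b = gen_cfg.train_val_ratio
    n_val = max(len(records) * b // (a + b), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("too few records for the requested train/val split")

    model = build_generator(arch, seed=spawn_seed(gen_cfg.seed, "generator-init"))
    opt = AdamW(model.params(), lr=gen_cfg.lr, weight_decay=gen_cfg.weight_decay)
    batch_rng = substream(gen_cfg.seed, "generator-batches")
    noise_rng = substream(gen_cfg.seed, "generator-noise")

    L = codes.shape[1]
    log: list[dict] = []
    for epoch in range(gen_cfg.epochs):
        t0 = time.time()
        losses = []
        for _ in range(gen_cfg.batches_per_epoch):
            idx = batch_rng.choice(train_idx, size=min(gen_cfg.batch_size, len(train_idx)), replace=False)
            orig = codes[idx]
            n_mut = noise_rng.integers(lo, hi + 1, size=len(idx))
            corrupted = mutate_codes(orig, n_mut, noise_rng)
            x = encode_generator_input(corrupted, n_mut, expr[idx], diffusion_cfg)
            logits = model.forward(x, training=True)  # (b, 4, L)
            logp = log_softmax(logits, axis=1)
            bsz = len(idx)
            loss = float(
                -logp[np.arange(bsz)[:, None], orig, np.arange(L)[None, :]].mean()
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite generator loss at epoch {epoch}")
            onehot = np.zeros_like(logits)
            onehot[np.arange(bsz)[:, None], orig, np.arange(L)[None, :]] = 1.0
            grad = ((softmax(logits, axis=1) - onehot) / (bsz * L)).astype(np.float32)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {
            "epoch": epoch,
            "mean_loss": float(np.mean(losses)),
            "wall_time_s": time.time() - t0,
        }
        # validation reconstruction at the same corruption law
        v_orig = codes[val_idx]
        v_n = substream(gen_cfg.seed, f"generator-val-{epoch}").integers(
            lo, hi + 1, size=len(val_idx)
        )
        v_corrupted = mutate_codes(
            v_orig, v_n, substream(gen_cfg.seed, f"generator-valnoise-{epoch}")
        )
        xv = encode_generator_input(v_corrupted, v_n, expr[val_idx], diffusion_cfg)
        v_logits = model.forward(xv, training=False)
        v_logp = log_softmax(v_logits, axis=1)
        entry["val_loss"] = float(
            -v_logp[np.arange(len(val_idx))[:, None], v_orig, np.arange(L)[None, :]].mean()
        )
        entry["val_accuracy"] = float(
            (v_logits.argmax(axis=1) == v_orig).mean()
        )
        log.append(entry)
    return model, log


def reconstruction_accuracy(
    model: DenoiserNet,
    records: Sequence[PromoterRecord],
    diffusion_cfg: DiffusionConfig,
    n_mutations: int,
    seed: int = 0,
) -> float:
    """Per-position accuracy recovering originals corrupted with n events."""
    codes, expr = _records_to_codes(records)
    rng = substream(seed, "reconstruction-eval")
    corrupted = mutate_codes(codes, np.full(len(records), n_mutations), rng)
    x = encode_generator_input(corrupted, n_mutations, expr, diffusion_cfg)
    pred = model.forward(x, training=False).argmax(axis=1)
    return float((pred == codes).mean())


# ---------------------------------------------------------------------------
# the generation loop


def generate_batch(
    generator: DenoiserNet,
    targets: np.ndarray | Sequence[float],
    cfg: DiffusionConfig,
    seed: int | None = None,
    record_schedule: bool = False,
) -> list[str] | tuple[list[str], list[dict]]:
    """Design one insert per target expression by iterative restoration.

    Start from uniformly random sequences with counter n = iterations; each
    step denoises with declared count n, decrements n, stops when n reaches
    0 (``stop_rule='declared'``; ``'corruption'`` stops as soon as the
    re-corruption count max(n - shift, 0) hits 0), otherwise re-corrupts the
    denoised sequences and loops. With ``record_schedule`` the per-step
    declared and introduced counts are returned for instrumentation.
    """
    targets = np.asarray(targets, dtype=np.float64)
    if (targets < 0).any() or (targets > 17).any():
        raise ValueError("target expression outside [0, 17]")
    rng = substream(cfg.seed if seed is None else seed, "generation")
    b, L = len(targets), cfg.insert_length
    codes = rng.integers(0, 4, size=(b, L))
    schedule: list[dict] = []
    n = cfg.iterations
    while True:
        x = encode_generator_input(codes, min(n, cfg.max_mutations), targets, cfg)
        logits = generator.forward(x, training=False)
        if cfg.decode == "argmax":
            denoised = logits.argmax(axis=1)
        else:
            p = softmax(logits / cfg.sample_temperature, axis=1)  # (b, 4, L)
            cum = p.cumsum(axis=1)
            u = rng.random((b, 1, L))
            denoised = (u > cum).sum(axis=1)
        n -= 1
        reintroduce = max(n - cfg.shift, 0)
        if record_schedule:
            schedule.append({"declared_next": n, "reintroduced": reintroduce})
        done = n == 0 if cfg.stop_rule == "declared" else reintroduce == 0
        if done:
            seqs = ["".join(_ALPHABET[c] for c in row) for row in denoised]
            return (seqs, schedule) if record_schedule else seqs
        codes = mutate_codes(denoised, reintroduce, rng)


def generate(
    generator: DenoiserNet,
    target_expression: float,
    cfg: DiffusionConfig,
    seed: int | None = None,
) -> str:
    """One designed insert for one target expression."""
    return generate_batch(generator, [target_expression], cfg, seed=seed)[0]


def score_designs(
    predictor: LegNet,
    sequences: Sequence[str],
    targets: Sequence[float],
    flank: FlankContext | None = None,
) -> dict:
    """Verify designs with a predictor: per-sequence scores + correlations."""
    if len(sequences) != len(targets):
        raise ValueError("sequences and targets must have equal length")
    ps: PredictionSet = predict_with_tta(predictor, sequences, flank)
    out: dict = {"predicted": ps.values, "n": len(ps.values)}
    t = np.asarray(targets, dtype=np.float64)
    if len(ps.values) < 3:
        out["pearson"] = out["spearman"] = float("nan")
        out["reason"] = "fewer than 3 designs"
    elif np.std(t) == 0 or np.std(ps.values) == 0:
        out["pearson"] = out["spearman"] = float("nan")
        out["reason"] = "constant targets or predictions"
    else:
        out["pearson"], out["spearman"] = correlations(ps.values, t)
    return out
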
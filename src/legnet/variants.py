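"""Variant-effect estimation by prediction differencing.

The effect of substitutions on a promoter insert is scored as the change in
predicted expression: effect = predict(alt) - predict(ref), both predictions
made with test-time augmentation and is_singleton = 0. Positive effects mean
the variant raises expression. Multiple substitutions in one record are
applied jointly to give a single alternate sequence, matching drift-style
experiments where each generation carries all accumulated substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .arch import LegNet
from .codec import FlankContext, read_fasta
from .evaluation import correlations
from .training import predict_with_tta

__all__ = [
    "VariantRecord",
    "apply_variants",
    "variant_effect",
    "variant_effects_batch",
    "drift_evaluation",
    "read_variant_table",
]

_VALID = set("ACGT")


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """A reference insert plus joint substitutions (0-based positions)."""

    ref_sequence: str
    substitutions: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        seq = self.ref_sequence.strip().upper()
        object.__setattr__(self, "ref_sequence", seq)
        subs = tuple(
            (int(pos), ref.upper(), alt.upper()) for pos, ref, alt in self.substitutions
        )
        object.__setattr__(self, "substitutions", subs)
        seen = set()
        for pos, ref, alt in subs:
            if not 0 <= pos < len(seq):
                raise VariantError(f"position {pos} outside sequence of length {len(seq)}")
            if pos in seen:
                raise VariantError(f"duplicate substitution position {pos}")
            seen.add(pos)
            if ref not in _VALID or alt not in _VALID:
                raise VariantError(f"invalid base in substitution at position {pos}")
            if seq[pos] != ref:
                raise VariantError(
                    f"reference mismatch at position {pos}: sequence has "
                    f"{seq[pos]}, variant says {ref}"
                )


def apply_variants(v: VariantRecord) -> str:
    """The alternate sequence with all substitutions applied."""
    seq = list(v.ref_sequence)
    for pos, _ref, alt in v.substitutions:
        seq[pos] = alt
    return "".join(seq)


def variant_effect(model: LegNet, v: VariantRecord, flank: FlankContext | None = None) -> float:
    """predict(alt) - predict(ref); exactly 0 when alt equals ref."""
    alt = apply_variants(v)
    if alt == v.ref_sequence:
        return 0.0
    ps = predict_with_tta(model, [("ref", v.ref_sequence), ("alt", alt)], flank)
    return float(ps.values[1] - ps.values[0])


def variant_effects_batch(
    model: LegNet,
    variants: Sequence[VariantRecord],
    flank: FlankContext | None = None,
    batch_size: int = 512,
) -> np.ndarray:
    """Effects for many records with de-duplicated model calls."""
    seqs: dict[str, int] = {}
    for v in variants:
        for s in (v.ref_sequence, apply_variants(v)):
            seqs.setdefault(s, len(seqs))
    order = list(seqs)
    pred = predict_with_tta(model, order, flank, batch_size).values
    out = np.empty(len(variants))
    for i, v in enumerate(variants):
        alt = apply_variants(v)
        out[i] = 0.0 if alt == v.ref_sequence else pred[seqs[alt]] - pred[seqs[v.ref_sequence]]
    return out


def drift_evaluation(
    model: LegNet,
    pairs: Sequence[tuple[str, str, float, int]],
    flank: FlankContext | None = None,
) -> dict[int, dict]:
    """Per-substitution-count agreement with observed expression changes.

    ``pairs``: (ref insert, alt insert, observed delta expression, n_subs
    in {1, 2, 3}). Returns, per n_subs group, the Pearson and Spearman
    correlation between predicted and observed effects plus the group size;
    groups whose correlation is undefined report a reason instead.
    """
    seqs: dict[str, int] = {}
    for ref, alt, _, _ in pairs:
        seqs.setdefault(ref, len(seqs))
        seqs.setdefault(alt, len(seqs))
    pred = predict_with_tta(model, list(seqs), flank).values
    groups: dict[int, list[tuple[float, float]]] = {}
    for ref, alt, observed, n_subs in pairs:
        delta = pred[seqs[alt]] - pred[seqs[ref]]
        groups.setdefault(int(n_subs), []).append((delta, float(observed)))
    report: dict[int, dict] = {}
    for n_subs, vals in sorted(groups.items()):
        d = np.array([v[0] for v in vals])
        o = np.array([v[1] for v in vals])
        entry: dict = {"n": len(vals)}
        if len(vals) < 3:
            entry["reason"] = "fewer than 3 pairs in group"
            entry["pearson"] = entry["spearman"] = float("nan")
        else:
            r, rho = correlations(d, o)
            entry["pearson"], entry["spearman"] = r, rho
            if np.isnan(r):
                entry["reason"] = "constant predictions or observations in group"
        report[n_subs] = entry
    return report


def read_variant_table(
    variants_path: str | Path, ref_fasta_path: str | Path
) -> list[VariantRecord]:
    """Variants from a TSV (id, 0-based position, ref, alt) against a FASTA.

    Rows sharing an id are merged into one jointly-applied record.
    """
    refs = dict(read_fasta(ref_fasta_path))
    grouped: dict[str, list[tuple[int, str, str]]] = {}
    with open(variants_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise VariantError(f"line {lineno}: expected id, pos, ref, alt")
            sid, pos, ref, alt = fields[:4]
            if sid not in refs:
                raise VariantError(f"line {lineno}: unknown sequence id {sid!r}")
            grouped.setdefault(sid, []).append((int(pos), ref, alt))
    return [
        VariantRecord(refs[sid], tuple(subs)) for sid, subs in grouped.items()
    ]
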
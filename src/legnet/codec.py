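"""Promoter sequence records, table IO and the 6-channel input encoding.

A reporter-assay measurement is a short variable insert (typically 80 bp)
placed in a constant plasmid context, with an expression readout equal to the
mean sorting-bin number of the cells carrying it (a real value in [0, 17]).
Inserts observed in a single cell ("singletons") have integer readouts and are
noisier; the model is told about them through a dedicated input channel.

The network consumes a fixed 150-position frame, 6 channels per position:

    0..3  one-hot A, C, G, T (all-zero where the frame is padded with N)
    4     is_singleton  (constant along the frame, 0 or 1)
    5     is_reverse    (constant along the frame; 1 for the reverse
          complement orientation of the padded frame)

Inserts are padded from the 5' end with the constant plasmid flank; the insert
therefore occupies the rightmost positions of the frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "FRAME_LENGTH",
    "N_CHANNELS",
    "PromoterRecord",
    "FlankContext",
    "reverse_complement",
    "encode",
    "inference_encode",
    "encode_batch",
    "decode_nucleotides",
    "read_gpra_table",
    "write_gpra_table",
    "read_fasta",
    "load_flank_config",
]

FRAME_LENGTH = 150
N_CHANNELS = 6

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer codes: A=0 C=1 G=2 T=3, N=4 (encodes as an all-zero column)
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4

_ONEHOT5 = np.zeros((5, 4), dtype=np.float32)
_ONEHOT5[:4] = np.eye(4, dtype=np.float32)

SINGLETON_TOL = 1e-6


class CodecError(ValueError):
    """Raised for malformed sequences, tables or encodings."""


def _normalize(sequence: str, *, allow_n: bool = False) -> str:
    seq = sequence.strip().upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise CodecError(f"invalid base(s) {sorted(bad)} in sequence {seq[:20]!r}...")
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def is_integral(x: float, tol: float = SINGLETON_TOL) -> bool:
    return abs(x - round(x)) <= tol


@dataclass(frozen=True)
class PromoterRecord:
    """One measured promoter: insert, expression bin average, singleton flag."""

    insert: str
    expression: float
    is_singleton: bool = False

    def __post_init__(self) -> None:
        seq = _normalize(self.insert)
        object.__setattr__(self, "insert", seq)
        if not 1 <= len(seq) <= FRAME_LENGTH:
            raise CodecError(
                f"insert length {len(seq)} outside [1, {FRAME_LENGTH}]"
            )
        e = float(self.expression)
        if not np.isfinite(e) or not 0.0 <= e <= 17.0:
            raise CodecError(f"expression {e!r} outside [0, 17]")
        object.__setattr__(self, "expression", e)
        object.__setattr__(self, "is_singleton", bool(self.is_singleton))


@dataclass(frozen=True)
class FlankContext:
    """Constant 5' plasmid segment used to left-pad inserts to 150 bp.

    The true plasmid flank is assay-specific; the default is an all-N policy
    region so that unpadded positions encode as all-zero nucleotide columns
    (no invented sequence content). Supply the real flank for a real assay.
    """

    five_prime_flank: str = "N" * FRAME_LENGTH

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "five_prime_flank", _normalize(self.five_prime_flank, allow_n=True)
        )

    def pad(self, insert: str, frame_length: int = FRAME_LENGTH) -> str:
        """Left-pad ``insert`` with the 3'-most bases of the flank."""
        if len(insert) > frame_length:
            raise CodecError(
                f"insert length {len(insert)} exceeds frame {frame_length}"
            )
        need = frame_length - len(insert)
        flank = self.five_prime_flank
        if len(flank) < need:
            flank = "N" * (need - len(flank)) + flank
        return (flank[len(flank) - need :] if need else "") + insert


def _frame_codes(padded: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(padded.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise CodecError(f"invalid base in padded frame {padded!r}")
    return codes


def encode(
    record: PromoterRecord,
    orientation: str = "forward",
    flank: FlankContext | None = None,
    frame_length: int = FRAME_LENGTH,
) -> np.ndarray:
    """Encode one record into the 6 x frame_length input matrix.

    ``reverse_complement`` orientation encodes the reverse complement of the
    whole padded frame and sets the is_reverse channel to 1.
    """
    if orientation not in ("forward", "reverse_complement"):
        raise CodecError(f"unknown orientation {orientation!r}")
    flank = flank or FlankContext()
    padded = flank.pad(record.insert, frame_length)
    if orientation == "reverse_complement":
        padded = reverse_complement(padded)
    mat = np.zeros((N_CHANNELS, frame_length), dtype=np.float32)
    mat[:4] = _ONEHOT5[_frame_codes(padded)].T
    mat[4] = 1.0 if record.is_singleton else 0.0
    mat[5] = 1.0 if orientation == "reverse_complement" else 0.0
    return mat


def inference_encode(
    sequence: str,
    flank: FlankContext | None = None,
    frame_length: int = FRAME_LENGTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement encodings for prediction.

    Evaluation always uses is_singleton = 0, whatever the training-time flag
    of the sequence was.
    """
    rec = PromoterRecord(insert=sequence, expression=0.0, is_singleton=False)
    return (
        encode(rec, "forward", flank, frame_length),
        encode(rec, "reverse_complement", flank, frame_length),
    )


def encode_batch(
    sequences: Sequence[str],
    flank: FlankContext | None = None,
    singleton: Sequence[bool] | None = None,
    frame_length: int = FRAME_LENGTH,
) -> np.ndarray:
    """Vectorized forward encoding of many inserts -> (n, 6, frame) array."""
    flank = flank or FlankContext()
    n = len(sequences)
    out = np.zeros((n, N_CHANNELS, frame_length), dtype=np.float32)
    for i, seq in enumerate(sequences):
        padded = flank.pad(_normalize(seq), frame_length)
        out[i, :4] = _ONEHOT5[_frame_codes(padded)].T
    if singleton is not None:
        out[:, 4] = np.asarray(singleton, dtype=np.float32)[:, None]
    return out


def reverse_complement_batch(batch: np.ndarray) -> np.ndarray:
    """Reverse complement encoded frames: flip positions, swap A<->T, C<->G.

    The is_reverse channel is set to 1 - its current value; is_singleton is
    kept.
    """
    out = batch[:, :, ::-1].copy()
    out[:, [0, 1, 2, 3]] = out[:, [3, 2, 1, 0]]
    out[:, 4] = batch[:, 4]
    out[:, 5] = 1.0 - batch[:, 5]
    return out


def decode_nucleotides(matrix: np.ndarray) -> str:
    """Read the nucleotide channels of an encoding back into a string.

    All-zero columns decode as N (padding without a known flank base).
    """
    nuc = matrix[:4]
    covered = nuc.sum(axis=0) > 0.5
    idx = nuc.argmax(axis=0)
    return "".join(
        _ALPHABET[i] if cov else "N" for i, cov in zip(idx, covered)
    )


# ---------------------------------------------------------------------------
# Table / FASTA IO


def read_gpra_table(path: str | Path, singleton_mode: str = "auto") -> list[PromoterRecord]:
    """Read a two- or three-column reporter table.

    Dialect: no header, tab-separated ``sequence<TAB>expression`` with an
    optional third 0/1 column used when ``singleton_mode='column'``.
    ``singleton_mode='auto'`` flags integer expressions as singletons;
    ``'none'`` leaves every flag False.
    """
    if singleton_mode not in ("auto", "column", "none"):
        raise CodecError(f"unknown singleton_mode {singleton_mode!r}")
    if ".truth." in Path(path).name:
        raise CodecError(
            "refusing to read a simulator truth table as training data; "
            "oracle values are for evaluation only"
        )
    records: list[PromoterRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise CodecError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
            seq = fields[0]
            try:
                expression = float(fields[1])
            except ValueError as err:
                raise CodecError(f"{path}: line {lineno}: bad expression {fields[1]!r}") from err
            if singleton_mode == "column":
                if len(fields) < 3:
                    raise CodecError(f"{path}: line {lineno}: missing singleton column")
                flag = fields[2].strip() in ("1", "true", "True")
            elif singleton_mode == "auto":
                flag = is_integral(expression)
            else:
                flag = False
            try:
                records.append(PromoterRecord(seq, expression, flag))
            except CodecError as err:
                raise CodecError(f"{path}: line {lineno}: {err}") from err
    return records


def write_gpra_table(
    records: Iterable[PromoterRecord], path: str | Path, singleton_column: bool = True
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if singleton_column:
                fh.write(f"{rec.insert}\t{rec.expression:.6g}\t{int(rec.is_singleton)}\n")
            else:
                fh.write(f"{rec.insert}\t{rec.expression:.6g}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (wrapped lines fine)."""
    return [(r.id, _normalize(str(r.seq))) for r in SeqIO.parse(str(path), "fasta")]


def load_flank_config(path: str | Path) -> FlankContext:
    """Read a YAML/JSON config with a ``five_prime_flank`` key."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return FlankContext(five_prime_flank=data.get("five_prime_flank", "N" * FRAME_LENGTH))
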
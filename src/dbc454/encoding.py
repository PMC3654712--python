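"""Gapped-dinucleotide composition encoding.

Every nucleotide sequence is embedded as a point with integer coordinates
in a 48-dimensional space: for each ordered base pair (b1, b2) in
{A,C,G,T}^2 the encoder counts the occurrences of b1 followed by b2 as an
adjacent pair (gap 0), separated by one base (gap 1) and separated by two
bases (gap 2).  The embedding deliberately ignores alignment: it is cheap,
order-sensitive (the pair (A,T) is distinct from (T,A)) and comparatively
tolerant of the insertion/deletion errors that pyrosequencing produces in
homopolymer runs, because an indel inside a repeated stretch perturbs few
pair counts.

Identical vectors are collapsed into weighted :class:`EncodedPoint` objects;
the multiplicity (number of reads sharing a vector) is what drives the
density clustering downstream, so dereplication loses no information.

All distances are handled as exact integer *squared* Euclidean distances;
a real-valued threshold ``d`` admits a pair iff ``squared_distance <= d**2``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

BASES = "ACGT"
GAPS = (0, 1, 2)
N_DIMS = 48

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Fixed dimension ordering: (b1 in ACGT order) x (b2 in ACGT order) x (g=0,1,2).
DIM_LABELS = tuple(
    f"{b1}{b2}_g{g}" for b1 in BASES for b2 in BASES for g in GAPS
)

_CODE_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i


def dim_index(b1: str, b2: str, gap: int) -> int:
    """Index of the dimension counting ``b1 (gap skipped bases) b2``."""
    if gap not in GAPS:
        raise ValueError(f"gap must be 0, 1 or 2, got {gap}")
    return (_BASE_INDEX[b1] * 4 + _BASE_INDEX[b2]) * 3 + gap


@dataclass(frozen=True)
class SequenceRecord:
    """A single input read: an identifier plus a nucleotide string.

    The sequence is uppercased on construction.  Duplicate sequences (under
    distinct ids) are meaningful and must not be discarded upstream.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class EncodedPoint:
    """One distinct composition vector plus the reads that share it."""

    vector: np.ndarray
    members: tuple[str, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.members)

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.vector)


def encode_sequence(record: SequenceRecord | str) -> np.ndarray:
    """Encode one sequence as a 48-dimensional integer count vector.

    Counts all ordered pairs (position i, position i+1+g) for g in {0,1,2},
    both positions inside the sequence.  Pairs in which either base is not
    one of A/C/G/T (ambiguity codes, N, ...) are skipped entirely.
    """
    if isinstance(record, str):
        record = SequenceRecord(id="<anonymous>", seq=record)
    seq = record.seq
    if len(seq) < 4:
        log.warning(
            "sequence %r has length %d (< 4); some gap classes are empty "
            "and the point sits near the origin",
            record.id,
            len(seq),
        )
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    vec = np.zeros(N_DIMS, dtype=np.int64)
    for g in GAPS:
        off = g + 1
        if len(codes) <= off:
            continue
        a = codes[:-off]
        b = codes[off:]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        idx = (a[ok] * 4 + b[ok]) * 3 + g
        vec += np.bincount(idx, minlength=N_DIMS)
    return vec


def squared_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Exact integer squared Euclidean distance between two count vectors."""
    diff = np.asarray(a, dtype=np.int64) - np.asarray(b, dtype=np.int64)
    return int(diff @ diff)


def encode_dataset(records: Sequence[SequenceRecord]) -> list[EncodedPoint]:
    """Encode and dereplicate a dataset.

    Returns one :class:`EncodedPoint` per distinct vector, members sorted by
    id, points sorted by vector coordinates — a canonical order that makes
    every downstream result independent of the input sequence order.

    Raises ``ValueError`` on duplicate ids.
    """
    seen: dict[str, None] = {}
    groups: dict[tuple[int, ...], list[str]] = {}
    vectors: dict[tuple[int, ...], np.ndarray] = {}
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen[rec.id] = None
        vec = encode_sequence(rec)
        key = tuple(int(x) for x in vec)
        groups.setdefault(key, []).append(rec.id)
        vectors.setdefault(key, vec)
    points = [
        EncodedPoint(vector=vectors[key], members=tuple(sorted(groups[key])))
        for key in sorted(groups)
    ]
    return points


def point_matrix(points: Sequence[EncodedPoint]) -> np.ndarray:
    """Stack point vectors into an (n, 48) int64 matrix."""
    if not points:
        return np.zeros((0, N_DIMS), dtype=np.int64)
    return np.vstack([p.vector for p in points]).astype(np.int64)


def pairwise_squared_distances(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """All-pairs exact integer squared distances via the polarization identity.

    Counts are small integers, so ``|x|^2 + |y|^2 - 2 x.y`` is exact in int64.
    """
    X = np.asarray(X, dtype=np.int64)
    Y = X if Y is None else np.asarray(Y, dtype=np.int64)
    nx = (X * X).sum(axis=1)
    ny = (Y * Y).sum(axis=1)
    d2 = nx[:, None] + ny[None, :] - 2 * (X @ Y.T)
    np.maximum(d2, 0, out=d2)
    return d2


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzip-compressed) multi-line FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = [
            SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(fh, "fasta")
        ]
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.seq
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_vectors_tsv(points: Sequence[EncodedPoint], path: str | Path) -> None:
    """Dump distinct vectors: index, 48 counts, multiplicity, member ids."""
    with open(path, "w") as fh:
        fh.write("vector_index\t" + "\t".join(DIM_LABELS) + "\tmultiplicity\tmembers\n")
        for i, p in enumerate(points):
            counts = "\t".join(str(int(c)) for c in p.vector)
            fh.write(f"{i}\t{counts}\t{p.multiplicity}\t{','.join(p.members)}\n")
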
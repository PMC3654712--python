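"""Labeled synthetic amplicon datasets for testing and benchmarking.

Each dataset holds F sequence families — an ancestor drawn uniformly over
{A,C,G,T} with a length on the ITS1 scale (default 100-300 nt), diversified
into members by independent point substitutions and rare indels — plus a
pool of unrelated random background sequences playing the role of noise.
Low per-member mutation rates keep the members of one family densely packed
in the 48-d composition space while unrelated ancestors sit far apart, the
cluster/noise structure the density clustering assumes.  Some members
receive zero mutations, so exact duplicates (and hence point multiplicity)
are exercised naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assignment import NOISE, Partition
from .encoding import SequenceRecord, encode_dataset, pairwise_squared_distances, point_matrix

_BASES = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic dataset.

    members counts sequences per family; set it above or below the density
    threshold N to probe the validity filter from both sides.
    """

    families: int = 3
    members: int = 150
    length_range: tuple[int, int] = (100, 300)
    substitution_rate: float = 0.01
    indel_rate: float = 0.002
    noise: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.families < 1 or self.members < 1 or self.noise < 0:
            raise ValueError("families, members must be >= 1 and noise >= 0")
        lo, hi = self.length_range
        if not 4 <= lo <= hi:
            raise ValueError("length_range must satisfy 4 <= lo <= hi")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate_member(seq: str, spec: FamilySpec, rng: np.random.Generator) -> str:
    chars = list(seq)
    n_sub = rng.binomial(len(chars), spec.substitution_rate)
    if n_sub:
        for pos in rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False):
            old = chars[pos]
            choices = [b for b in _BASES if b != old]
            chars[pos] = choices[int(rng.integers(3))]
    n_indel = rng.binomial(len(chars), spec.indel_rate)
    for _ in range(n_indel):
        if len(chars) > 4 and rng.random() < 0.5:
            del chars[int(rng.integers(len(chars)))]
        else:
            pos = int(rng.integers(len(chars) + 1))
            chars.insert(pos, _BASES[int(rng.integers(4))])
    return "".join(chars)


def generate_families(spec: FamilySpec) -> tuple[list[SequenceRecord], Partition]:
    """Generate a dataset and its ground-truth partition.

    Family labels are the integers 1..F; background sequences are labeled
    NOISE.  Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    truth: dict[str, int | str] = {}
    for f in range(1, spec.families + 1):
        ancestor = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        for m in range(spec.members):
            sid = f"F{f}_m{m:04d}"
            records.append(
                SequenceRecord(id=sid, seq=_mutate_member(ancestor, spec, rng))
            )
            truth[sid] = f
    for i in range(spec.noise):
        sid = f"noise_{i:04d}"
        records.append(
            SequenceRecord(id=sid, seq=_random_sequence(rng, int(rng.integers(lo, hi + 1))))
        )
        truth[sid] = NOISE
    return records, Partition(assignment=truth)


def family_separation(
    records: list[SequenceRecord], truth: Partition
) -> dict[str, float]:
    """Encoded-space geometry check of a generated dataset.

    Returns the minimum inter-family distance and the maximum intra-family
    pairwise distance (noise excluded).  Recovery tests require the former
    to exceed the latter.
    """
    by_family: dict[int | str, list[SequenceRecord]] = {}
    for rec in records:
        label = truth.assignment[rec.id]
        if label != NOISE:
            by_family.setdefault(label, []).append(rec)
    fam_records = [r for recs in by_family.values() for r in recs]
    points = encode_dataset(fam_records)
    label_of: dict[str, int | str] = {
        r.id: truth.assignment[r.id] for r in fam_records
    }
    point_labels = [label_of[p.members[0]] for p in points]
    X = point_matrix(points)
    d2 = pairwise_squared_distances(X)
    lab = np.asarray([hash(l) for l in point_labels])
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(points), k=1)
    intra = d2[iu][same[iu]]
    inter = d2[iu][~same[iu]]
    return {
        "max_intra_distance": float(np.sqrt(intra.max())) if intra.size else 0.0,
        "min_inter_distance": float(np.sqrt(inter.min())) if inter.size else float("inf"),
    }
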
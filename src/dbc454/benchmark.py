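"""Robustness benchmarking: 454-style error simulation and the ARI.

The error model mimics typical pyrosequencing error statistics: a fixed
fraction of reads is selected for mutation (default 18%); a selected read
receives one, two or three errors (default probabilities 0.61 / 0.17 /
0.22); each error is an insertion, deletion or substitution (default
0.46 / 0.33 / 0.21) applied sequentially at a uniformly random position of
the current string.  Homopolymer bias is deliberately not modeled: the
model is specified purely by error counts and types.

Partitions — original vs. a mutated replicate, or two methods on the same
data — are compared with the adjusted Rand index under two noise
treatments: (i) all noise sequences of a partition form one extra cluster,
or (ii) any sequence that is noise in either partition is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .assignment import NOISE, Partition
from .encoding import SequenceRecord

log = logging.getLogger(__name__)

ERROR_TYPES = ("insertion", "deletion", "substitution")

#: Noise treatment names (CLI aliases in parentheses).
NOISE_AS_CLUSTER = "noise-as-cluster"
EXCLUDE_NOISE = "exclude-noise"
_MODE_ALIASES = {
    NOISE_AS_CLUSTER: NOISE_AS_CLUSTER,
    "single-cluster": NOISE_AS_CLUSTER,
    EXCLUDE_NOISE: EXCLUDE_NOISE,
    "exclude": EXCLUDE_NOISE,
}


@dataclass(frozen=True)
class ErrorModel:
    """Per-read 454 error statistics.

    select_frac: fraction of reads mutated.
    count_probs: probabilities of 1, 2 or 3 errors for a selected read.
    type_probs:  probabilities of insertion, deletion, substitution.
    """

    select_frac: float = 0.18
    count_probs: tuple[float, float, float] = (0.61, 0.17, 0.22)
    type_probs: tuple[float, float, float] = (0.46, 0.33, 0.21)

    def __post_init__(self) -> None:
        if not 0.0 <= self.select_frac <= 1.0:
            raise ValueError("select_frac must be in [0, 1]")
        for name, probs in (("count_probs", self.count_probs), ("type_probs", self.type_probs)):
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be three non-negative probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


@dataclass
class MutationReport:
    """Per-read log of the errors a simulation introduced."""

    errors: dict[str, tuple[str, ...]] = field(default_factory=dict)
    redraws: int = 0

    @property
    def n_selected(self) -> int:
        return len(self.errors)

    def fraction_selected(self, n_total: int) -> float:
        return self.n_selected / n_total if n_total else 0.0

    def fraction_single_error(self) -> float:
        if not self.errors:
            return 0.0
        return sum(1 for e in self.errors.values() if len(e) == 1) / len(self.errors)

    def error_type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in ERROR_TYPES}
        for types in self.errors.values():
            for t in types:
                counts[t] += 1
        return counts

    def fraction_of_type(self, error_type: str) -> float:
        counts = self.error_type_counts()
        total = sum(counts.values())
        return counts[error_type] / total if total else 0.0


_BASES = "ACGT"


def _apply_error(seq: str, error_type: str, rng: np.random.Generator) -> str:
    if error_type == "substitution":
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        choices = [b for b in _BASES if b != old] or list(_BASES)
        new = choices[int(rng.integers(len(choices)))]
        return seq[:pos] + new + seq[pos + 1 :]
    if error_type == "insertion":
        pos = int(rng.integers(len(seq) + 1))
        base = _BASES[int(rng.integers(4))]
        return seq[:pos] + base + seq[pos:]
    if error_type == "deletion":
        pos = int(rng.integers(len(seq)))
        return seq[:pos] + seq[pos + 1 :]
    raise ValueError(f"unknown error type {error_type!r}")


def mutate_dataset(
    seqs: Sequence[SequenceRecord],
    model: ErrorModel | None = None,
    seed: int | np.random.Generator = 0,
    return_report: bool = False,
) -> list[SequenceRecord] | tuple[list[SequenceRecord], MutationReport]:
    """Apply the error model to a dataset, preserving ids and order.

    Errors are applied sequentially, each on the current (possibly already
    mutated) string.  Deleting from a length-1 sequence is impossible, so
    the error type is re-drawn (and logged).  Deterministic for a fixed
    seed.
    """
    model = model or ErrorModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    report = MutationReport()
    selected = rng.random(len(seqs)) < model.select_frac
    out: list[SequenceRecord] = []
    counts = np.asarray(model.count_probs, dtype=float)
    types = np.asarray(model.type_probs, dtype=float)
    for rec, sel in zip(seqs, selected):
        if not sel:
            out.append(rec)
            continue
        n_err = int(rng.choice(3, p=counts)) + 1
        seq = rec.seq
        applied: list[str] = []
        for _ in range(n_err):
            etype = ERROR_TYPES[int(rng.choice(3, p=types))]
            while etype == "deletion" and len(seq) <= 1:
                log.warning(
                    "cannot delete from length-1 sequence %r; re-drawing error type",
                    rec.id,
                )
                report.redraws += 1
                etype = ERROR_TYPES[int(rng.choice(3, p=types))]
            seq = _apply_error(seq, etype, rng)
            applied.append(etype)
        report.errors[rec.id] = tuple(applied)
        out.append(SequenceRecord(id=rec.id, seq=seq))
    if return_report:
        return out, report
    return out


# ---------------------------------------------------------------------------
# Adjusted Rand index


def _as_assignment(p: Partition | Mapping[str, int | str]) -> Mapping[str, int | str]:
    return p.assignment if isinstance(p, Partition) else p


def _comb2(x: np.ndarray | int):
    return x * (x - 1) // 2


def adjusted_rand_index(
    p1: Partition | Mapping[str, int | str],
    p2: Partition | Mapping[str, int | str],
    noise_mode: str = NOISE_AS_CLUSTER,
) -> float:
    """Chance-corrected agreement of two partitions of the same sequences.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) on the contingency table n_ij,
    with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    M = [sum_i C(a_i,2) + sum_j C(b_j,2)] / 2.  The degenerate case M = E
    (e.g. both partitions all singletons, or both one single cluster) is
    defined as 1 when the groupings are identical and 0 otherwise.

    Noise handling: ``noise-as-cluster`` turns the noise of each partition
    into one additional cluster; ``exclude-noise`` drops every sequence
    that is noise in either partition (at least two must survive).
    """
    mode = _MODE_ALIASES.get(noise_mode)
    if mode is None:
        raise ValueError(f"unknown noise mode {noise_mode!r}")
    a1 = _as_assignment(p1)
    a2 = _as_assignment(p2)
    if set(a1) != set(a2):
        raise ValueError("partitions must cover the same sequence ids")
    ids = sorted(a1)
    if mode == EXCLUDE_NOISE:
        ids = [i for i in ids if a1[i] != NOISE and a2[i] != NOISE]
        if len(ids) < 2:
            raise ValueError("fewer than 2 sequences survive noise exclusion")
    lab1 = [f"c{a1[i]}" if a1[i] != NOISE else NOISE for i in ids]
    lab2 = [f"c{a2[i]}" if a2[i] != NOISE else NOISE for i in ids]

    u1 = {l: k for k, l in enumerate(dict.fromkeys(lab1))}
    u2 = {l: k for k, l in enumerate(dict.fromkeys(lab2))}
    table = np.zeros((len(u1), len(u2)), dtype=np.int64)
    for l1, l2 in zip(lab1, lab2):
        table[u1[l1], u2[l2]] += 1

    n = table.sum()
    sum_nij = int(_comb2(table).sum())
    sum_a = int(_comb2(table.sum(axis=1)).sum())
    sum_b = int(_comb2(table.sum(axis=0)).sum())
    total_pairs = int(_comb2(int(n)))
    expected = sum_a * sum_b / total_pairs if total_pairs else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if abs(max_index - expected) < 1e-300:
        groups1 = frozenset(
            frozenset(i for i, l in zip(ids, lab1) if l == lab) for lab in u1
        )
        groups2 = frozenset(
            frozenset(i for i, l in zip(ids, lab2) if l == lab) for lab in u2
        )
        return 1.0 if groups1 == groups2 else 0.0
    return (sum_nij - expected) / (max_index - expected)


def robustness_assay(
    seqs: Sequence[SequenceRecord],
    cluster_fn: Callable[[Sequence[SequenceRecord]], Partition],
    model: ErrorModel | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> list[dict[str, float | str | None]]:
    """Cluster the original data once, then each mutated replicate.

    Returns one record per replicate with the ARI against the original
    partition under both noise treatments (sequences matched by id).  A
    replicate that fails to cluster is reported with its error message and
    does not abort the others.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    model = model or ErrorModel()
    original = cluster_fn(seqs)
    results: list[dict[str, float | str | None]] = []
    for r in range(replicates):
        entry: dict[str, float | str | None] = {
            "replicate": r + 1,
            NOISE_AS_CLUSTER: None,
            EXCLUDE_NOISE: None,
            "error": None,
        }
        try:
            mutated = mutate_dataset(seqs, model, seed=seed + r)
            part = cluster_fn(mutated)
            entry[NOISE_AS_CLUSTER] = adjusted_rand_index(original, part, NOISE_AS_CLUSTER)
            entry[EXCLUDE_NOISE] = adjusted_rand_index(original, part, EXCLUDE_NOISE)
        except Exception as exc:  # propagate per replicate, keep going
            log.error("replicate %d failed: %s", r + 1, exc)
            entry["error"] = str(exc)
        results.append(entry)
    return results


def summarize_aris(results: Sequence[Mapping[str, float | str | None]]) -> dict[str, dict[str, float]]:
    """Min / median / max of the per-replicate ARIs for each noise mode."""
    out: dict[str, dict[str, float]] = {}
    for mode in (NOISE_AS_CLUSTER, EXCLUDE_NOISE):
        vals = [float(r[mode]) for r in results if r.get(mode) is not None]
        if vals:
            out[mode] = {
                "min": float(np.min(vals)),
                "median": float(np.median(vals)),
                "max": float(np.max(vals)),
            }
    return out
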
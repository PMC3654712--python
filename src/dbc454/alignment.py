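"""Pairwise global alignment, percent divergence and the cluster radius.

Divergence between two sequences is 100 minus the percent identity of
their optimal global (Needleman-Wunsch) alignment under unit edit costs
(match 0, mismatch 1, gap 1), with the identity denominator being the full
number of alignment columns, gap columns included.  A cluster's *radius*
is the mean divergence over all unordered sequence pairs in the cluster —
a scalar summary of how tight the cluster is, in percent divergence units.

Among co-optimal alignments the one maximizing matches is chosen, and on
remaining ties a mismatch column is preferred over a pair of gap columns,
so results are deterministic.  The dynamic program runs in O(len1*len2);
radius computation is quadratic in cluster size on top of that, so it is
meant for per-cluster reporting, not as an inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one optimal global alignment."""

    columns: int
    matches: int
    mismatches: int
    gaps: int

    @property
    def edits(self) -> int:
        return self.mismatches + self.gaps

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.columns

    @property
    def percent_divergence(self) -> float:
        return 100.0 - self.percent_identity


def global_align(s1: str, s2: str) -> AlignmentResult:
    """Optimal global alignment of two nucleotide strings, unit edit costs.

    The DP minimizes the composite objective (edits, -matches, gaps)
    lexicographically, encoded as a single integer score; Python integers
    make the weight stacking exact for any sequence length.
    """
    if not s1 or not s2:
        raise ValueError("global_align requires two non-empty sequences")
    s1 = s1.upper()
    s2 = s2.upper()
    n, m = len(s1), len(s2)

    w_gap = 1
    w_match = n + m + 2  # dominates the gap tally
    w_edit = w_match * (min(n, m) + 1) + (n + m + 2)  # dominates the match tally
    gap_cost = w_edit + w_gap
    mismatch_cost = w_edit
    match_cost = -w_match

    prev = [j * gap_cost for j in range(m + 1)]
    rows = [prev]
    for i in range(1, n + 1):
        cur = [i * gap_cost] + [0] * m
        ci = s1[i - 1]
        prev_row = rows[i - 1]
        for j in range(1, m + 1):
            diag = prev_row[j - 1] + (match_cost if ci == s2[j - 1] else mismatch_cost)
            up = prev_row[j] + gap_cost
            left = cur[j - 1] + gap_cost
            cur[j] = diag if diag <= up and diag <= left else (up if up <= left else left)
        rows.append(cur)

    matches = mismatches = gaps = 0
    i, j = n, m
    while i > 0 or j > 0:
        here = rows[i][j]
        if i > 0 and j > 0:
            is_match = s1[i - 1] == s2[j - 1]
            diag = rows[i - 1][j - 1] + (match_cost if is_match else mismatch_cost)
            if diag == here:  # diagonal preferred: mismatch beats gap on ties
                if is_match:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and rows[i - 1][j] + gap_cost == here:
            gaps += 1
            i -= 1
            continue
        gaps += 1
        j -= 1
    return AlignmentResult(
        columns=matches + mismatches + gaps,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
    )


def percent_divergence(s1: str, s2: str) -> float:
    return global_align(s1, s2).percent_divergence


def percent_divergence_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of pairwise percent divergences (zero diagonal)."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.0 if seqs[i] == seqs[j] else percent_divergence(seqs[i], seqs[j])
            mat[i, j] = mat[j, i] = d
    return mat


def cluster_radius(seqs: Sequence[str]) -> float:
    """Mean pairwise percent divergence inside one cluster.

    Size-1 clusters have radius 0 by convention.
    """
    if len(seqs) < 2:
        return 0.0
    mat = percent_divergence_matrix(seqs)
    iu = np.triu_indices(len(seqs), k=1)
    return float(mat[iu].mean())


def cluster_radii(
    seqs_by_cluster: Mapping[int | str, Sequence[str]]
) -> dict[int | str, float]:
    """Radius for each cluster in a label -> sequences mapping."""
    return {label: cluster_radius(list(s)) for label, s in seqs_by_cluster.items()}
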
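"""Tests for the multi-level single-linkage density clustering."""

import math

import numpy as np
import pytest

from dbc454 import (
    DensityParams,
    LevelSchedule,
    SequenceRecord,
    cluster_at_level,
    encode_dataset,
    run_hierarchy,
    squared_distance,
)

from conftest import random_seq


# -- independent oracle ------------------------------------------------------


def oracle_components(points, d, min_size):
    """Brute-force single linkage: O(n^2) pair scan + naive merging."""
    groups = [{i} for i in range(len(points))]
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if squared_distance(points[i].vector, points[j].vector) <= d * d:
                gi = next(g for g in groups if i in g)
                gj = next(g for g in groups if j in g)
                if gi is not gj:
                    groups.remove(gj)
                    gi |= gj
    valid = [
        frozenset(g)
        for g in groups
        if sum(points[i].multiplicity for i in g) >= min_size
    ]
    return sorted(valid, key=min)


def make_points(rng, n_records=60, length=(8, 30)):
    records = [
        SequenceRecord(f"s{i:03d}", random_seq(rng, int(rng.integers(*length))))
        for i in range(n_records)
    ]
    return encode_dataset(records)


# -- schedule ----------------------------------------------------------------


def test_default_schedule_endpoints():
    sched = LevelSchedule.linear_in_squared()
    assert len(sched) == 23
    assert sched.levels[0] == pytest.approx(3.317)
    assert sched.levels[-1] == pytest.approx(7.141)
    assert all(a < b for a, b in zip(sched.squared, sched.squared[1:]))


def test_schedule_rejects_non_increasing():
    with pytest.raises(ValueError):
        LevelSchedule.from_levels([2.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        LevelSchedule.from_levels([])
    with pytest.raises(ValueError):
        LevelSchedule.from_levels([math.inf])


# -- cluster_at_level --------------------------------------------------------


def test_d_zero_needs_repeated_sequence():
    """At d=0 only a sequence present at least N times forms a cluster."""
    repeated = [SequenceRecord(f"r{i}", "ACGTACGTAA") for i in range(10)]
    distinct = [SequenceRecord(f"d{i}", "ACGT" * (i + 3)) for i in range(20)]
    points = encode_dataset(repeated + distinct)
    comps = cluster_at_level(points, d=0.0, min_cluster_size=10)
    assert len(comps) == 1
    (comp,) = comps
    assert sum(points[i].multiplicity for i in comp) == 10
    # all-distinct sequences at d=0 yield nothing for N=2
    assert cluster_at_level(encode_dataset(distinct), 0.0, 2) == []


def test_d_infinite_single_component(rng):
    points = make_points(rng, 40)
    comps = cluster_at_level(points, math.inf, 1)
    assert len(comps) == 1
    assert comps[0] == frozenset(range(len(points)))


def test_components_match_oracle(rng):
    points = make_points(rng, 50)
    for _ in range(10):
        d = float(rng.uniform(0, 25))
        n = int(rng.integers(1, 5))
        assert cluster_at_level(points, d, n) == oracle_components(points, d, n)


def test_empty_input():
    assert cluster_at_level([], 5.0, 1) == []
    tree = run_hierarchy([], LevelSchedule.from_levels([1.0]), DensityParams(1))
    assert tree.n_clusters == 0 and tree.to_newick() == ";"


# -- run_hierarchy -----------------------------------------------------------


def two_family_fixture():
    """Two tight families whose single-linkage gap falls inside the schedule."""
    rng = np.random.default_rng(99)
    anc_a = random_seq(rng, 150)
    # family B: the same backbone with many substitutions => a controlled gap
    chars = list(anc_a)
    for pos in rng.choice(len(chars), size=40, replace=False):
        chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
    anc_b = "".join(chars)
    fam_a = [SequenceRecord(f"a{i:03d}", anc_a) for i in range(30)]
    fam_b = [SequenceRecord(f"b{i:03d}", anc_b) for i in range(30)]
    records = fam_a + fam_b
    points = encode_dataset(records)
    gap = math.sqrt(
        min(
            squared_distance(p.vector, q.vector)
            for p in points
            for q in points
            if p.members[0][0] == "a" and q.members[0][0] == "b"
        )
    )
    return records, gap


def test_two_families_birth_and_merge_level():
    records, gap = two_family_fixture()
    # schedule brackets the inter-family single-linkage distance
    sched = LevelSchedule.from_levels(
        [gap / 4, gap / 2, 0.99 * gap, 1.01 * gap, 2 * gap]
    )
    tree = run_hierarchy(encode_dataset(records), sched, DensityParams(10))
    assert [lvl for lvl, _ in tree.births] == [0, 0]
    assert len(tree.events) == 1
    merge_level, children, parent = tree.events[0][0], tree.events[0][1], tree.events[0][2]
    assert merge_level == 3  # first level admitting the gap
    assert set(children) == {1, 2}
    assert tree.n_clusters == 2
    assert tree.nodes[parent].is_leaf is False


def test_single_tight_family():
    records = [SequenceRecord(f"s{i}", "ACGTACGTACGTAGGT") for i in range(25)]
    tree = run_hierarchy(
        encode_dataset(records), LevelSchedule.from_levels([1.0, 2.0]), DensityParams(10)
    )
    assert len(tree.births) == 1 and not tree.events
    assert tree.n_clusters == 1


def test_hierarchy_matches_per_level_components(rng):
    """Incremental edge sweep agrees with direct per-level clustering.

    At every level the number of live lineages must equal the number of
    valid components computed directly, and at the final level the live
    lineages' member sets must be exactly those components.
    """
    points = make_points(rng, 45, length=(6, 18))
    sched = LevelSchedule.from_levels([2.0, 4.0, 6.0, 9.0])
    params = DensityParams(3)
    tree = run_hierarchy(points, sched, params)
    for k, d in enumerate(sched.levels):
        direct = oracle_components(points, d, params.min_cluster_size)
        live = [
            node
            for node in tree.nodes.values()
            if node.birth_level <= k
            and (node.merge_level is None or node.merge_level > k)
        ]
        assert len(live) == len(direct)
    final = {
        node.members
        for node in tree.nodes.values()
        if node.merge_level is None
    }
    assert final == set(
        oracle_components(points, sched.levels[-1], params.min_cluster_size)
    )


def test_monotone_entry_levels_and_classified_growth(rng):
    points = make_points(rng, 60, length=(6, 20))
    sched = LevelSchedule.from_levels([2.0, 4.0, 7.0, 12.0])
    tree = run_hierarchy(points, sched, DensityParams(2))
    assert all(0 <= k < len(sched) for k in tree.entry_level.values())
    # classified set at level k = entries with entry_level <= k must be
    # non-decreasing by construction; verify against direct clustering
    for k, d in enumerate(sched.levels):
        classified = {i for i, e in tree.entry_level.items() if e <= k}
        direct = set().union(*cluster_at_level(points, d, 2)) if cluster_at_level(points, d, 2) else set()
        assert classified == direct


def test_order_invariance_and_determinism(rng):
    base = [
        SequenceRecord(f"s{i:03d}", random_seq(rng, int(rng.integers(20, 60))))
        for i in range(80)
    ]
    sched = LevelSchedule.from_levels([3.0, 5.0, 8.0, 14.0, 22.0])
    trees = []
    for order in (base, base[::-1], sorted(base, key=lambda r: r.seq)):
        tree = run_hierarchy(encode_dataset(order), sched, DensityParams(2))
        trees.append(tree)
    t0 = trees[0]
    for t in trees[1:]:
        assert t.births == t0.births
        assert t.events == t0.events
        assert t.entry_level == t0.entry_level
        assert t.to_newick() == t0.to_newick()


def test_newick_parses_with_dendropy(rng):
    import dendropy

    points = make_points(rng, 70, length=(10, 40))
    sched = LevelSchedule.from_levels([3.0, 6.0, 10.0, 18.0, 30.0])
    tree = run_hierarchy(points, sched, DensityParams(2))
    nwk = tree.to_newick()
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(parsed.leaf_nodes()) == tree.n_clusters


def test_merge_log_tsv(tmp_path):
    records, gap = two_family_fixture()
    sched = LevelSchedule.from_levels([gap / 2, 1.01 * gap])
    tree = run_hierarchy(encode_dataset(records), sched, DensityParams(10))
    out = tmp_path / "merge_log.tsv"
    tree.write_merge_log(out)
    lines = out.read_text().splitlines()
    assert lines[0] == "level_value\tevent\tcluster_id\tsize\tchildren"
    events = [line.split("\t")[1] for line in lines[1:]]
    assert events.count("birth") == 2 and events.count("merge") == 1
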
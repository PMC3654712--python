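"""End-to-end clustering runs: config, outputs and the run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .alignment import cluster_radii
from .assignment import (
    NOISE,
    Partition,
    SeedCluster,
    filter_small_clusters,
    identify_seeds,
    place_references,
    reassign,
    write_cluster_summary,
)
from .encoding import SequenceRecord, encode_dataset, read_fasta
from .hierarchy import DensityParams, LevelSchedule, MergeTree, default_schedule, run_hierarchy

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one clustering run depends on."""

    input: Path
    out_dir: Path
    min_cluster_size: int = 100
    schedule: LevelSchedule = field(default_factory=default_schedule)
    refs: Path | None = None
    compute_radius: bool = False
    seed: int | None = None


@dataclass
class ClusterResult:
    partition: Partition
    tree: MergeTree
    seeds: list[SeedCluster]


def cluster_sequences(
    records: Sequence[SequenceRecord],
    schedule: LevelSchedule | None = None,
    min_cluster_size: int = 100,
) -> ClusterResult:
    """Encode, run the density hierarchy, re-assign and size-filter.

    The library entry point for clustering a dataset already in memory.
    """
    if not records:
        raise ValueError("no input sequences")
    points = encode_dataset(records)
    tree = run_hierarchy(
        points, schedule or default_schedule(), DensityParams(min_cluster_size)
    )
    seeds = identify_seeds(tree)
    partition = reassign(tree, seeds)
    partition = filter_small_clusters(partition, min_cluster_size)
    return ClusterResult(partition=partition, tree=tree, seeds=seeds)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_cluster_command(config: RunConfig) -> dict:
    """Run a full clustering and write the output bundle.

    Writes partition.tsv, clusters.tsv, merge_log.tsv, hierarchy.nwk and
    manifest.json into the output directory (plus references.tsv when a
    reference FASTA is supplied).  Input problems — unreadable FASTA, empty
    input, duplicate ids — fail before any output is written.
    """
    records = read_fasta(config.input)
    if not records:
        raise ValueError(f"no sequences found in {config.input}")
    refs = read_fasta(config.refs) if config.refs else None

    result = cluster_sequences(
        records, schedule=config.schedule, min_cluster_size=config.min_cluster_size
    )
    partition, tree, seeds = result.partition, result.tree, result.seeds

    placed = None
    if refs is not None:
        placed = place_references(refs, tree, partition)

    radii = None
    if config.compute_radius:
        seq_of = {r.id: r.seq for r in records}
        by_cluster: dict[int | str, list[str]] = {}
        for sid, label in partition.assignment.items():
            if label != NOISE:
                by_cluster.setdefault(label, []).append(seq_of[sid])
        radii = cluster_radii(by_cluster)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partition.to_tsv(out / "partition.tsv")
    write_cluster_summary(tree, seeds, partition, out / "clusters.tsv", radii=radii)
    tree.write_merge_log(out / "merge_log.tsv")
    (out / "hierarchy.nwk").write_text(tree.to_newick() + "\n")
    if placed is not None:
        with open(out / "references.tsv", "w") as fh:
            fh.write("reference_id\tcluster_label\tentry_level_value\n")
            for rid in sorted(placed):
                label, lvl = placed[rid]
                fh.write(f"{rid}\t{label}\t{'' if lvl is None else f'{lvl:.6g}'}\n")

    n = len(records)
    n_noise = partition.n_noise()
    manifest = {
        "input": str(config.input),
        "input_sha256": _sha256(Path(config.input)),
        "references": str(config.refs) if config.refs else None,
        "parameters": {
            "min_cluster_size": config.min_cluster_size,
            "levels": [round(v, 6) for v in config.schedule.levels],
            "seed": config.seed,
        },
        "counts": {
            "sequences": n,
            "distinct_vectors": len(tree.points),
            "clusters": len(partition.labels()),
            "classified_percent": round(100.0 * (n - n_noise) / n, 4),
            "noise_percent": round(100.0 * n_noise / n, 4),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info(
        "clustered %d sequences into %d clusters (%.1f%% classified)",
        n,
        manifest["counts"]["clusters"],
        manifest["counts"]["classified_percent"],
    )
    return manifest
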
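"""Report each cluster's radius: mean pairwise percent divergence.

The radius summarizes how heterogeneous a cluster is in plain alignment
terms (percent divergence from global alignments), independently of the
composition space used for clustering.
"""

from dbc454 import FamilySpec, cluster_radius, cluster_sequences, generate_families

records, _ = generate_families(
    FamilySpec(families=2, members=25, noise=0, substitution_rate=0.01, seed=5)
)
result = cluster_sequences(records, min_cluster_size=20)
seq_of = {r.id: r.seq for r in records}

for label in result.partition.labels():
    members = [
        seq_of[sid]
        for sid, lab in result.partition.assignment.items()
        if lab == label
    ]
    print(f"cluster {label}: {len(members)} sequences, "
          f"radius = {cluster_radius(members):.3f}%")
# With a 1% per-base substitution rate, two members differ at ~2% of their
# positions on average, so radii come out near 2 percent divergence.
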
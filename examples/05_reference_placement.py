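"""Attach annotated reference sequences to a finished clustering.

References never influence cluster discovery: they are placed afterwards,
each to the cluster of its nearest classified sequence, provided that the
distance fits within the loosest clustering threshold; everything farther
is rejected as noise.  The reported entry level says how close to the
cluster core a reference sits.
"""

from dbc454 import (
    FamilySpec,
    SequenceRecord,
    cluster_sequences,
    generate_families,
    place_references,
)

records, _ = generate_families(FamilySpec(families=2, members=120, noise=50, seed=19))
result = cluster_sequences(records, min_cluster_size=100)

refs = [
    SequenceRecord("ref_member_copy", records[0].seq),  # identical to a read
    SequenceRecord("ref_unrelated", "ACGT" * 60),       # nothing like the data
]
placed = place_references(refs, result.tree, result.partition)
for rid, (label, level) in placed.items():
    where = f"cluster {label} at entry level d = {level:.3f}" if level else "rejected as noise"
    print(f"{rid}: {where}")
# The exact copy enters its family's cluster at the first level; the
# unrelated sequence is farther than the last threshold from everything
# classified and is rejected.
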
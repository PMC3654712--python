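"""Measure clustering robustness against simulated pyrosequencing errors.

Mutates the dataset five times with the default 454 error model (18% of
reads get 1-3 errors), re-clusters each replicate and reports the adjusted
Rand index against the original partition under both noise treatments.
"""

from dbc454 import (
    ErrorModel,
    FamilySpec,
    cluster_sequences,
    generate_families,
    robustness_assay,
    summarize_aris,
)

records, _ = generate_families(FamilySpec(families=3, members=150, noise=100, seed=11))
cluster = lambda seqs: cluster_sequences(seqs, min_cluster_size=100).partition

results = robustness_assay(records, cluster, ErrorModel(), replicates=5, seed=3)
for r in results:
    print(
        f"replicate {r['replicate']}: "
        f"ARI(noise-as-cluster) = {r['noise-as-cluster']:.3f}, "
        f"ARI(exclude-noise) = {r['exclude-noise']:.3f}"
    )
print("summary:", summarize_aris(results))
# ARIs near 1 mean the partition barely moves when typical sequencing
# errors are injected — the property the method is built around.
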
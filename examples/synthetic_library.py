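"""Generate a compound library with planted structural families and recover them.

Shows the synthetic-data contract end to end: the generator guarantees a
within/between family Tanimoto margin, and clustering recovers the planted
partition exactly (adjusted Rand index 1.0).
"""

from sklearn.metrics import adjusted_rand_score

from focuspharm import (
    compute_fingerprints,
    detect_component_groups,
    hierarchical_cluster,
    tanimoto_matrix,
)
from focuspharm.synthdata import LibrarySpec, generate_compound_library

spec = LibrarySpec(n_families=3, family_size=5, seed=42)
records, labels = generate_compound_library(spec)
print(f"generated {len(records)} compounds in {spec.n_families} planted families")
for r in records[:3]:
    print(f"  {r.compound_id} ({r.herb}): {r.smiles}")

fps = compute_fingerprints(records)
tree = hierarchical_cluster(tanimoto_matrix(fps))
result = detect_component_groups(tree, records, cut_height=0.6)
assigned = {m: g.group_id for g in result.groups for m in g.members}
ids = [r.compound_id for r in records]
ari = adjusted_rand_score([labels[i] for i in ids],
                          [assigned.get(i, "unassigned") for i in ids])
print(f"recovered {len(result.groups)} groups; adjusted Rand index vs planted: {ari:.2f}")

# ARI 1.0 means the recovered grouping and the planted families agree
# perfectly - the margin contract makes the families separable by design.
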
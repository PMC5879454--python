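"""Component groups: cluster the formula's chemistry and pick representatives.

Fingerprints the group-annotated compounds (fatty acids excluded), clusters
them by Tanimoto similarity, cuts the tree at distance 0.6, and selects one
representative compound per herb-pure group.
"""

from focuspharm import (
    compute_fingerprints,
    detect_component_groups,
    hierarchical_cluster,
    load_mzrw_fixtures,
    select_representative,
    tanimoto_matrix,
)

fx = load_mzrw_fixtures()
member_ids = {c for cs in fx.group_members.values() for c in cs}
members = [r for r in fx.compounds if r.compound_id in member_ids]

fps = compute_fingerprints(members)              # Morgan radius 2, 2048 bits
sim = tanimoto_matrix(fps)
tree = hierarchical_cluster(sim)                 # average linkage on 1 - Tc
result = detect_component_groups(tree, members, cut_height=0.6)

print(f"{len(members)} compounds -> {len(result.groups)} component groups")
for g in result.groups:
    rep = select_representative(g, members)
    print(f"  {g.group_id}: herb {g.dominant_herb}, {len(g.members)} members, "
          f"purity {g.purity:.2f}, representative {rep}")

# Each group is a congeneric series from one herb; the representative (most
# bioavailable, abundant, obtainable member) stands for the whole group in
# downstream pharmacology.
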
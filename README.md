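# focuspharm

Focused network pharmacology for multi-compound herbal formulas.

Multi-herb preparations contain dozens to hundreds of constituents, and
classic network pharmacology maps all of them onto thousands of putative
protein targets — far too many hypotheses to test. `focuspharm` implements
the *focused* alternative for compounds that have been quantitatively
validated in the extract and in biological samples:

1. **Component groups** — Morgan/ECFP4 fingerprints (radius 2), pairwise
   Tanimoto similarity Tc = |A∩B|/|A∪B|, average-linkage hierarchical
   clustering on d = 1 − Tc, and a dendrogram cut that yields clusters of
   structurally similar compounds dominated by a single herb.
2. **Representative compounds** — one member per group, prioritized by
   detection in biological samples, abundance rank, commercial availability
   and pharmacology use.
3. **Most-similar-ligand target prediction** — per target, the query's
   nearest known ligand supplies two features (tc_max, nearest-ligand
   potency) to a per-activity-type logistic model
   P(active) = σ(β₀ + β_sim·tc_max + β_pot·potency); predictions survive
   only if tc_max ≥ 0.45 and p = 1 − P(active) < 0.05, with activity defined
   as pKi/pIC50/pEC50 ≥ 6 and models evaluated by temporal split.
4. **Network assembly** — referenced (literature-curated) and predicted
   targets are merged, filtered against disease evidence, and expanded into
   a typed compound–target–pathway–disorder graph (GraphML/SIF/CSV).

An organ-bath module normalizes smooth-muscle contraction amplitudes to
active tension, force/area = amplitude / [wet weight / (1.05 × L₀)], and
summarizes concentration–response data as mean ± SEM.

The package ships transcription fixtures for its worked example — the
MaZiRenWan (MZRW) six-herb formula studied for functional constipation —
and seeded synthetic generators (planted structural families, planted
ligand–target associations) so every stage is testable without external
databases. Fixture structures are documented stand-ins; see
`src/focuspharm/data/FIXTURES.md`.

## Worked example

```python
from focuspharm import (load_mzrw_fixtures, venn_partition,
                        compute_fingerprints, tanimoto_matrix,
                        hierarchical_cluster, detect_component_groups,
                        select_representative, merge_targets,
                        filter_by_disease, assemble_network, network_summary)

fx = load_mzrw_fixtures()
vp = venn_partition(fx.compounds)
print(len(fx.compounds), vp.set_sizes["plasma"], vp.set_sizes["feces"],
      vp.in_sets("plasma", "feces"))

members = [r for r in fx.compounds
           if r.compound_id in {c for cs in fx.group_members.values() for c in cs}]
tree = hierarchical_cluster(tanimoto_matrix(compute_fingerprints(members)))
groups = detect_component_groups(tree, members, cut_height=0.6).groups
print({g.dominant_herb: select_representative(g, members) for g in groups})

merged = merge_targets(fx.referenced, fx.predicted)
kept = filter_by_disease(merged, fx.evidence).edges
net = assemble_network(kept, fx.evidence, "constipation")
print(network_summary(net)["nodes"], network_summary(net)["compound_degree"])
```

prints

```
97 34 10 9
{'DH': 'emodin', 'KXR': 'amygdalin', 'BS': 'albiflorin', 'HP': 'honokiol', 'ZS': 'naringin'}
{'compound': 4, 'target': 7, 'pathway': 5, 'disorder': 1} {'amygdalin': 1, 'emodin': 1, 'honokiol': 5, 'naringin': 3}
```

meaning: of 97 identified compounds, 34 reach plasma and 10 feces (9 in
both); five herb-pure component groups emerge, represented by emodin,
amygdalin, albiflorin, honokiol and naringin; after requiring
disease evidence, four compounds connect to the disorder through 7 targets
in 5 signaling pathways (albiflorin retains no disease-linked target and
drops out), with honokiol the most connected compound.

Short narrative scripts for each capability live in `examples/`; run e.g.
`python examples/component_groups.py`. The same workflow is scriptable from
the shell:

```sh
focuspharm run -c config.yml          # full pipeline from a YAML config
focuspharm cluster -i compounds.csv -o out/ --cut-height 0.6
focuspharm predict --bioactivity chembl_extract.csv --query q1=SMILES -o pred.csv
focuspharm network --referenced ref.csv --predicted pred.csv --evidence ev.csv -o out/
focuspharm simulate --seed 42 -o sim/
```

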
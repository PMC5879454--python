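# Methods

## The problem and the approach

Classic network pharmacology for multi-herb formulas maps hundreds of
database-retrieved compounds onto thousands of putative targets, producing
more mechanistic hypotheses than can be tested. The *focused* variant
implemented here restricts the analysis to compounds validated
quantitatively in the formula extract (and in biological samples after oral
dosing), abstracts them into a small number of **component groups** of
structurally similar compounds, and carries only one **representative
compound** per group into target prediction and network assembly. The output
is a compact compound-target-pathway-disorder network whose every edge is
auditable: either a curated literature association or a filtered model
prediction.

## Chemical space and component groups

Compounds are fingerprinted with Morgan circular fingerprints of radius 2
(ECFP4-like), 2048 bits. Pairwise similarity is the Tanimoto coefficient
Tc = |A∩B| / |A∪B| over set bits; two empty bit sets are defined maximally
similar (Tc = 1). Agglomerative clustering runs on the distance d = 1 − Tc
with **average linkage** — the conventional choice for similarity-derived
clustermaps; the linkage label travels with the tree so single/complete
alternates stay selectable. Merge ties are resolved by scipy's deterministic
nearest-neighbor-chain order, so identical inputs (including row order)
yield identical trees.

The dendrogram is cut at **cut_height = 0.6** (distance scale, i.e. mean
within-cluster similarity ≳ 0.4). Flat clusters become component groups when
they have at least `min_size = 2` members and a strict majority
(`purity_min = 0.5`, exceeded strictly) from one herb; the modal herb is the
group's dominant herb (ties to the lexicographically smallest code).
Compounds in clusters failing either criterion are reported as unassigned
rather than silently dropped. The 0.6 cut was calibrated once on the
packaged worked-example fixture so that its five congeneric series
(anthraquinone aglycones, cyanogenic glycosides, monoterpene glycosides,
biphenyl neolignans, flavanone glycosides) emerge as exactly five herb-pure
groups; it is exposed as configuration. Fatty acids are excluded by an
explicit id exclusion list in the pipeline configuration, mirroring a
deliberate analytic exclusion rather than an automatic lipid detector.

The representative of a group is chosen by lexicographic priority:
(1) detected in a biological sample (plasma or feces), (2) lowest
within-herb abundance rank, (3) commercially available, (4) frequent use in
pharmacology studies, (5) smallest compound id. "Frequent use in
pharmacology study" has no quantitative definition in the source protocol;
it is modeled as a boolean annotation supplied with the input table. PCA
(for chemical-space maps) operates on the mean-centered, unscaled 0/1 bit
matrix.

## Most-similar-ligand target prediction

Bioactivity records are −log10 molar potencies (pKi, pIC50, pEC50) with a
release tag for temporal splitting. A (ligand, target, type) pair is
**active** iff its (maximum, over duplicates) potency ≥ 6.0 — boundary
inclusive. Temporal validation trains on records at or before a release
cutoff and tests on later releases only.

For a query compound and a target, the target's known ligands are scanned
for the nearest ligand by Tanimoto similarity (ties: higher potency, then
smaller ligand id). The two features (tc_max, nearest-ligand potency) feed a
per-activity-type logistic regression:

    P(active) = sigmoid(β0 + β_sim · tc_max + β_pot · potency_nn)

Training features are computed **leave-one-out** — each training ligand's
nearest neighbor excludes itself — because otherwise every training point
has tc_max = 1 and the similarity coefficient is meaningless. A small L2
penalty (`l2_penalty = 1e-3` per observation; weaker values available for
parameter-recovery studies) keeps coefficients finite on separable data, and
the lbfgs optimizer runs at tolerance 1e-8 with a fixed iteration cap, so
refits are bit-for-bit reproducible. Training requires ≥ 20 usable pairs
with both classes; single-class data is a hard error naming the imbalance.

A prediction survives only if **tc_max ≥ 0.45** and **p < 0.05**, where the
p-value is defined as **1 − P(active)** from the calibrated logistic model —
the filter therefore reads "at least 95% confidence of activity". The
original most-similar-ligand method may construct its p-value differently
(no formula is printed in the protocol this follows); the definition here is
recorded prominently and pluggable via `MostModel.predict_proba`. A target
is reported when *any* activity type passes both filters (union semantics;
the merge rule for the per-compound published lists is unstated and the
union is the simplest consistent choice), and the passing prediction with
the smallest p-value represents the target.

Prediction accuracy is the fraction of held-out pairs whose thresholded
probability (≥ 0.5) matches the label, computed per activity type with
features taken against training-release ligands only. The published
full-scale temporal accuracies (73.5 / 80.4 / 75.5% for pIC50/pEC50/pKi)
require the external ChEMBL releases and are documentation context, not a
test; the packaged synthetic datasets yield accuracies near 1.0 because
their planted classes are widely separated in potency.

## Network assembly

Referenced (curated) and predicted associations are unioned into one edge
per (compound, target) with an evidence attribute (`referenced`,
`predicted`, `both`) retaining both the citation tag and the prediction
statistics. Edges survive only if their target carries disease evidence for
the disorder; dropped targets are reported per compound so a compound's
exclusion from the network is auditable. The graph is typed:
compound − target − pathway − disorder, with the disorder connected through
pathway nodes (not directly to targets), one merged edge per compound-target
pair, and pathway membership taken solely from the evidence table. Orphan
nodes cannot arise by construction; assembly validates this invariant on
every build. In the packaged worked example the evidence table maps
ACHE→acetylcholine, ADORA1→purine, CNR1→cannabinoid, CYP19A1→estrogen,
ESR2→estrogen, PTGS1→prostaglandin, PTGS2→prostaglandin.

## Organ-bath normalization

Contraction amplitudes (g) are normalized to active tension (g/mm²) as

    force/area = amplitude / [wet_weight / (density × L0)]

with the smooth-muscle density constant 1.05 and L0 the optimal segment
length (mm). The formula is implemented literally as printed in the source
protocol, including its unreconciled unit convention (the constant is
conventionally a g/cm³ density while the output is reported in g/mm²); no
unit-conversion layer is added. Per-concentration summaries report n, mean
and SEM = sd/√n, require n ≥ 2 (SEM undefined otherwise), and are invariant
to within-group ordering.

## Synthetic data: what it emulates and what it does not

`generate_compound_library` plants structural families as congeneric series:
each family is one drug-like scaffold (anthraquinone-, flavanone-,
biphenyl-, aryl-glycoside- or chromone-like) with a parent decoration and
single-substituent analogs. The generator enforces a margin contract —
within-family mean Tc exceeds between-family mean Tc by ≥ 0.2 — by bounded
re-sampling, and errors out if the margin is unattainable. This emulates the
family structure of real herbal libraries (tight congeneric series on a few
chemotypes) but not their full diversity: real libraries contain singleton
structures, inter-family bridges (e.g. glycosides sharing sugars across
aglycone classes) and metabolite pairs. Passing recovery tests therefore
demonstrates that the clustering machinery finds well-separated families; it
does not certify performance on libraries whose families overlap.

`generate_bioactivity_dataset` gives each target one activity type (cycling
pKi/pIC50/pEC50) and one home scaffold; actives are analogs of the home
scaffold with potencies truncated-normal above 6.0 (mean 7.5, sd 0.5),
inactives are decoy-scaffold analogs below 6.0 (mean 4.5, sd 0.5), so the
realized active fraction (default 0.5) is planted, not sampled. Release tags
follow a fixed schedule placing ~20% of records in the held-out release.
Planted query compounds are single-atom-edit analogs (homologation or
halogen swap) of each target's most potent active — "near-duplicates" with
high Tc. Real bioactivity data has heavier noise, assay heterogeneity,
potency values straddling the threshold, and targets with few or no ligands;
the planted separation makes recall and accuracy optimistic by design, which
is why those numbers validate machinery, not real-world performance. The
single global seed fans out to per-stage child seeds so stages can be
regenerated independently.

Defaults (6 targets × 20 ligands; 3 families × 5 compounds; n = 2000 for
coefficient recovery) were chosen once as the smallest sizes at which the
statistical contracts are comfortably identifiable, and are the sizes the
acceptance script reports.

## Numerical and design notes

- Tanimoto on two all-zero fingerprints is defined as 1.0 (identical empty
  substructure sets); the matrix is symmetrized and clipped to [0, 1]
  before clustering to absorb floating-point asymmetry.
- Venn accounting treats the record list itself as the universe; a
  metabolite present only in feces (naringenin in the worked example) is a
  legal record with `in_extract = false`.
- Receptor labels that are not single gene symbols (GABA_A, RXR) are
  carried as opaque target ids, never expanded to subunit genes.
- Representative-selection ties after all four criteria resolve to the
  smallest compound id, making selection total and deterministic.
- Pipeline artifacts embed a hash of the stage parameters in a `#` header
  comment; artifact bytes are independent of output location, so identical
  config + inputs give byte-identical artifacts.
- `fcluster`-based cutting means a cluster's cophenetic diameter, not its
  pairwise diameters, respects the cut height — the standard dendrogram
  semantics.

## Known limitations

- No SDF/MOL input, no live database connectivity: ChEMBL/BindingDB-style
  data arrive as local CSV extracts, and the published full-scale
  accuracies are out of reach at package scale.
- The p-value is a calibrated-probability complement, not a null-model tail
  probability; downstream interpretation should treat the 0.05 filter as a
  confidence threshold.
- Whether the published per-compound predicted lists pooled activity types
  by union or intersection is unstated; union is implemented.
- Group membership at member level is fixture-calibrated; concordance with
  the unpublished supplementary membership tables cannot be guaranteed.
- The worked-example compound structures are stand-ins (see
  `data/FIXTURES.md`); conclusions that depend on exact structures — rather
  than on counts, lists and group topology — should not be drawn from the
  fixtures.
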
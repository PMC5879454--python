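# Worked-example fixtures (MZRW / functional constipation)

These CSVs transcribe the published worked example of the focused network
pharmacology workflow for MaZiRenWan (MZRW), a six-herb formula studied for
functional constipation.

**What is transcription and what is stand-in.** The published tables print
compound names, herb origins, detection counts, target gene symbols and
pathway assignments — but no structures and no machine-readable compound
list. Therefore:

- `mzrw_table1_referenced.csv`, `mzrw_table1_predicted.csv` and
  `mzrw_table2_evidence.csv` are direct transcriptions of the printed
  referenced/predicted target lists and the target-constipation evidence
  table (7 targets across 5 signaling pathways). Citation tags are opaque
  labels, not resolvable references.
- `mzrw_compounds.csv` is a **synthetic stand-in** for the 97-compound
  table: well-known named compounds (emodin, amygdalin, albiflorin,
  honokiol, naringin, hesperidin, gallic acid, ...) carry literature-style
  structures; minor congeners are chemotype-consistent analogs
  (anthraquinones, stilbenes, cyanogenic glycosides, monoterpene
  glycosides, biphenyl neolignans, flavanone glycosides, fatty acids). The
  paeoniflorin family uses a simplified monoterpene-glycoside cage. Herb
  counts (7/48/3/14/10/15), detection flags (34 plasma, 10 feces, 9 common,
  naringenin feces-only) and representative annotations follow the
  published counts.
- `mzrw_group_members.csv` is a stand-in for the component-group membership
  supplement (labels SM2-SM6), listing the congeneric series used by the
  grouping analysis; fatty acids (the HMR chemotype) are deliberately not
  members.
- `mzrw_representatives.csv` carries the representative compounds' stand-in
  canonical SMILES.

`checksums.json` pins SHA-256 digests of every fixture; the loader refuses
corrupted files. Regenerate everything with
`python scripts/build_mzrw_fixtures.py` from the repository root.
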
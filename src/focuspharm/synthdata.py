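"""Seeded synthetic data generators and packaged worked-example fixtures.

Two generators make the pipeline testable with no external database:

* a compound-library generator that plants structural families by decorating
  drug-like scaffolds (anthraquinone-, flavanone-, biphenyl-, glycoside- and
  chromone-like templates echoing common herbal chemotypes) with sampled
  substituents, guaranteeing a minimum within-family vs between-family
  Tanimoto margin;
* a bioactivity-table generator that plants ligand-target associations with
  actives above and inactives below the 6.0 potency threshold, release tags
  for temporal splitting, and query compounds that are near-duplicates of
  active ligands of their planted targets.

The module also packages the transcription fixtures for the worked
MaZiRenWan (MZRW) constipation example. The compound structures in those
fixtures are stand-ins assembled for this package (the source tables print
names, not structures); provenance notes live in ``data/FIXTURES.md``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemspace import compute_fingerprints, tanimoto_matrix
from .io_tables import (
    CompoundRecord,
    DiseaseEvidence,
    PredictedTarget,
    ReferencedTarget,
    canonical_smiles,
    read_compound_table,
    read_evidence_table,
    read_predicted_table,
    read_referenced_table,
)
from .most_predict import ACTIVE_THRESHOLD, BioactivityRecord

__all__ = [
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "LibrarySpec",
    "BioactivitySpec",
    "PlantedAssociation",
    "generate_compound_library",
    "generate_bioactivity_dataset",
    "generate_feature_table",
    "MzrwFixtures",
    "load_mzrw_fixtures",
]

# Drug-like templates with numbered substitution slots. Every substituent in
# SUBSTITUENTS must yield a valid molecule in every slot (checked by tests).
SCAFFOLDS: tuple[str, ...] = (
    "O=C1c2cc({0})cc(O)c2C(=O)c2cc({1})c({2})cc12",          # anthraquinone-like
    "O=C1CC(c2ccc({0})c({1})c2)Oc2cc({2})cc(O)c12",          # flavanone-like
    "Oc1cc({0})ccc1-c1ccc({1})c({2})c1O",                    # biphenyl-like
    "OCC1OC(Oc2ccc({0})c({1})c2)C(O)C({2})C1O",              # aryl-glycoside-like
    "O=c1cc({0})oc2cc({1})cc({2})c12",                       # chromone-like
)

SUBSTITUENTS: tuple[str, ...] = (
    "O", "OC", "C", "CC", "N", "Cl", "F", "C(C)C", "CO", "OCC", "C#N", "Br",
)

_DEFAULT_HERBS = ("DH", "ZS", "HP", "BS", "KXR", "OTHER")


@dataclass
class LibrarySpec:
    """Parameters of a planted-family compound library.

    The margin contract — within-family mean Tanimoto exceeding the
    between-family mean by at least ``min_margin`` — is what makes planted
    families recoverable by clustering; substituents are re-sampled (bounded
    retries) until it holds.
    """

    n_families: int = 3
    family_size: int = 5
    scaffolds: tuple[str, ...] = SCAFFOLDS
    substituents: tuple[str, ...] = SUBSTITUENTS
    herbs: tuple[str, ...] = _DEFAULT_HERBS
    min_margin: float = 0.2
    max_retries: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > len(self.scaffolds):
            raise ValueError("n_families must not exceed the number of scaffolds")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")


@dataclass
class BioactivitySpec:
    """Parameters of a planted bioactivity table.

    Each target gets one activity type (cycling pKi/pIC50/pEC50) and one home
    scaffold; its actives are analogs of that scaffold with potencies drawn
    above the active threshold, its inactives are analogs of other scaffolds
    with potencies below. Planted query compounds are near-duplicate analogs
    of one active ligand of their target.
    """

    n_targets: int = 6
    ligands_per_target: int = 20
    active_fraction: float = 0.5
    active_mean: float = 7.5
    inactive_mean: float = 4.5
    noise_sd: float = 0.5
    active_threshold: float = ACTIVE_THRESHOLD
    release_tags: tuple[str, ...] = ("r2013", "r2014", "r2015")
    test_fraction: float = 0.2
    n_planted_queries: int = 3
    scaffolds: tuple[str, ...] = SCAFFOLDS
    substituents: tuple[str, ...] = SUBSTITUENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class PlantedAssociation:
    """Ground truth: this query compound should be predicted to hit this target."""

    query_id: str
    smiles: str
    target_id: str


def _decorate(scaffold: str, subs: tuple[str, ...], rng: np.random.Generator) -> str:
    n_slots = scaffold.count("{")
    chosen = [subs[rng.integers(len(subs))] for _ in range(n_slots)]
    smi = scaffold.format(*chosen)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:  # defensive; templates are validated to accept every substituent
        raise ValueError(f"scaffold decoration produced invalid SMILES {smi!r}")
    return Chem.MolToSmiles(mol)


def _family_margin(records: list[CompoundRecord], labels: dict[str, int]) -> float:
    fps = compute_fingerprints(records)
    sim = tanimoto_matrix(fps).values
    ids = [r.compound_id for r in records]
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            (within if labels[ids[i]] == labels[ids[j]] else between).append(sim[i, j])
    if not within or not between:
        return np.inf
    return float(np.mean(within) - np.mean(between))


def generate_compound_library(
    spec: LibrarySpec,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Generate a compound library with planted structural families.

    Returns (records, labels) where labels maps compound_id to its planted
    family index. Deterministic under ``spec.seed``; raises if the Tanimoto
    margin contract cannot be met within ``spec.max_retries`` re-samples.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(spec.max_retries):
        records: list[CompoundRecord] = []
        labels: dict[str, int] = {}
        used: set[str] = set()
        for fam in range(spec.n_families):
            scaffold = spec.scaffolds[fam]
            herb = spec.herbs[fam % len(spec.herbs)]
            n_slots = scaffold.count("{")
            parent = [spec.substituents[rng.integers(len(spec.substituents))]
                      for _ in range(n_slots)]
            made = 0
            guard = 0
            while made < spec.family_size:
                guard += 1
                if guard > 200 * spec.family_size:
                    break  # fall through to margin check / retry
                # a family is a congeneric series: the parent decoration plus
                # single-substituent analogs of it
                if made == 0:
                    smi = canonical_smiles(scaffold.format(*parent))
                else:
                    smi = _mutate_one_slot(scaffold, parent, spec.substituents, rng)
                if smi in used:
                    continue
                used.add(smi)
                cid = f"SYN{fam:02d}_{made:03d}"
                records.append(
                    CompoundRecord(
                        compound_id=cid,
                        name=f"synthetic family {fam} member {made}",
                        smiles=smi,
                        herb=herb,
                        in_extract=True,
                        in_plasma=bool(made == 0),
                        in_feces=False,
                        abundance_rank=made + 1,
                    )
                )
                labels[cid] = fam
                made += 1
        if len(records) == spec.n_families * spec.family_size:
            if spec.family_size == 1 or spec.n_families == 1:
                return records, labels
            if _family_margin(records, labels) >= spec.min_margin:
                return records, labels
    raise ValueError(
        f"could not reach the within/between Tanimoto margin {spec.min_margin} "
        f"after {spec.max_retries} retries; loosen min_margin or enlarge the "
        f"substituent set"
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float | None, high: float | None
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if (low is None or v >= low) and (high is None or v < high):
            return float(v)
    raise ValueError("truncated normal sampling failed; bounds too tight for mean/sd")


def _mutate_one_slot(
    scaffold: str, chosen: list[str], subs: tuple[str, ...], rng: np.random.Generator
) -> str:
    """Analog of a decorated scaffold differing in exactly one substituent."""
    new = list(chosen)
    slot = int(rng.integers(len(new)))
    options = [s for s in subs if s != new[slot]]
    new[slot] = options[int(rng.integers(len(options)))]
    return canonical_smiles(scaffold.format(*new))


# conservative single-atom edits (homologation, halogen swap) used to plant
# query compounds that stay highly similar to their template ligand
_SIMILAR_SUB = {
    "O": "OC", "OC": "OCC", "OCC": "OC", "C": "CC", "CC": "C(C)C",
    "C(C)C": "CC", "N": "C", "Cl": "Br", "Br": "Cl", "F": "Cl",
    "CO": "OCC", "C#N": "C",
}


def _homologate_one_slot(
    scaffold: str, chosen: list[str], rng: np.random.Generator
) -> str:
    """Near-duplicate analog: one substituent replaced by a chemically close one."""
    new = list(chosen)
    slot = int(rng.integers(len(new)))
    new[slot] = _SIMILAR_SUB.get(new[slot], "C")
    return canonical_smiles(scaffold.format(*new))


def generate_bioactivity_dataset(
    spec: BioactivitySpec,
) -> tuple[list[BioactivityRecord], list[PlantedAssociation]]:
    """Generate a bioactivity table with planted ligand-target associations.

    The realized active fraction matches ``spec.active_fraction`` exactly (per
    target, up to rounding) because active/inactive counts are planted, not
    sampled. Release tags follow a fixed schedule so that roughly
    ``test_fraction`` of records carry the last (held-out) tag.
    """
    from .io_tables import ACTIVITY_TYPES

    rng = np.random.default_rng(spec.seed)
    records: list[BioactivityRecord] = []
    planted: list[PlantedAssociation] = []
    test_period = max(2, round(1.0 / spec.test_fraction)) if spec.test_fraction > 0 else 0
    # remember each target's active decorations for query planting
    target_actives: dict[str, list[tuple[str, list[str]]]] = {}
    counter = 0
    for t in range(spec.n_targets):
        target_id = f"T{t:02d}"
        atype = ACTIVITY_TYPES[t % len(ACTIVITY_TYPES)]
        home = t % len(spec.scaffolds)
        n_active = round(spec.ligands_per_target * spec.active_fraction)
        n_inactive = spec.ligands_per_target - n_active
        used: set[str] = set()
        target_actives[target_id] = []

        def draw(scaffold_idx: int) -> tuple[str, list[str]]:
            scaffold = spec.scaffolds[scaffold_idx]
            for _ in range(500):
                n_slots = scaffold.count("{")
                chosen = [spec.substituents[rng.integers(len(spec.substituents))]
                          for _ in range(n_slots)]
                smi = canonical_smiles(scaffold.format(*chosen))
                if smi not in used:
                    used.add(smi)
                    return smi, chosen
            raise ValueError("could not draw a fresh ligand analog")

        for j in range(n_active):
            smi, chosen = draw(home)
            value = _truncated_normal(rng, spec.active_mean, spec.noise_sd,
                                      low=spec.active_threshold, high=None)
            target_actives[target_id].append((value, smi, chosen))
            tag = (spec.release_tags[-1]
                   if test_period and counter % test_period == test_period - 1
                   else spec.release_tags[counter % (len(spec.release_tags) - 1)])
            counter += 1
            records.append(BioactivityRecord(
                ligand_id=f"{target_id}_A{j:03d}", smiles=smi, target_id=target_id,
                activity_type=atype, value=value, release_tag=tag,
            ))
        for j in range(n_inactive):
            decoy = (home + 1 + int(rng.integers(len(spec.scaffolds) - 1))) % len(spec.scaffolds)
            smi, _ = draw(decoy)
            value = _truncated_normal(rng, spec.inactive_mean, spec.noise_sd,
                                      low=None, high=spec.active_threshold)
            tag = (spec.release_tags[-1]
                   if test_period and counter % test_period == test_period - 1
                   else spec.release_tags[counter % (len(spec.release_tags) - 1)])
            counter += 1
            records.append(BioactivityRecord(
                ligand_id=f"{target_id}_I{j:03d}", smiles=smi, target_id=target_id,
                activity_type=atype, value=value, release_tag=tag,
            ))
    for q in range(spec.n_planted_queries):
        t = q % spec.n_targets
        target_id = f"T{t:02d}"
        # template = the target's most potent active, so the planted query sits
        # next to a strong ligand in feature space
        _, _, chosen = max(target_actives[target_id], key=lambda x: x[0])
        scaffold = spec.scaffolds[t % len(spec.scaffolds)]
        query_smi = _homologate_one_slot(scaffold, chosen, rng)
        planted.append(PlantedAssociation(
            query_id=f"Q{q:02d}", smiles=query_smi, target_id=target_id,
        ))
    return records, planted


def generate_feature_table(
    n: int,
    intercept: float,
    coef_sim: float,
    coef_pot: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (tc_max, potency) features and Bernoulli labels from a known
    logistic model — the parameter-recovery oracle for the activity model."""
    rng = np.random.default_rng(seed)
    tc = rng.uniform(0.05, 1.0, size=n)
    pot = rng.normal(6.0, 1.5, size=n)
    X = np.column_stack([tc, pot])
    z = intercept + coef_sim * tc + coef_pot * pot
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# Worked-example fixtures (MZRW / functional constipation)


@dataclass(frozen=True)
class MzrwFixtures:
    """Parsed transcription fixtures for the MZRW constipation example."""

    compounds: list[CompoundRecord]
    referenced: list[ReferencedTarget]
    predicted: list[PredictedTarget]
    evidence: list[DiseaseEvidence]
    representatives: dict[str, str]  # compound name -> canonical SMILES
    group_members: dict[str, list[str]]  # group label -> compound_ids


def _data_path(name: str) -> Path:
    return Path(__file__).resolve().parent / "data" / name


def _verify_checksums() -> None:
    manifest = json.loads(_data_path("checksums.json").read_text())
    for name, expected in manifest.items():
        actual = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if actual != expected:
            raise ValueError(
                f"fixture {name} is corrupted: checksum {actual[:12]}... "
                f"does not match manifest {expected[:12]}..."
            )


def load_mzrw_fixtures() -> MzrwFixtures:
    """Load and validate the packaged MZRW fixtures.

    Fixture integrity is checked against a shipped checksum manifest before
    parsing; a mismatch is a hard error.
    """
    import csv

    _verify_checksums()
    compounds = read_compound_table(_data_path("mzrw_compounds.csv"))
    referenced = read_referenced_table(_data_path("mzrw_table1_referenced.csv"))
    predicted = read_predicted_table(_data_path("mzrw_table1_predicted.csv"))
    evidence = read_evidence_table(_data_path("mzrw_table2_evidence.csv"))
    reps: dict[str, str] = {}
    with open(_data_path("mzrw_representatives.csv"), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(ln for ln in fh if not ln.startswith("#")):
            reps[row["compound_id"]] = canonical_smiles(row["smiles"])
    members: dict[str, list[str]] = {}
    with open(_data_path("mzrw_group_members.csv"), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(ln for ln in fh if not ln.startswith("#")):
            members.setdefault(row["group_label"], []).append(row["compound_id"])
    return MzrwFixtures(
        compounds=compounds,
        referenced=referenced,
        predicted=predicted,
        evidence=evidence,
        representatives=reps,
        group_members=members,
    )
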
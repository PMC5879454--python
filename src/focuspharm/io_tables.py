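"""Tabular input/output and detection-flag set accounting.

All pipeline inputs are plain CSV (UTF-8, comma separated, first row header,
quoted fields allowed) so that fixtures remain hand-editable. Readers validate
aggressively and fail loudly: a malformed row is an error, never silently
skipped, because every downstream stage assumes clean records.

Lines starting with ``#`` are treated as comments; pipeline outputs embed a
provenance hash in such a header line.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem

__all__ = [
    "TableFormatError",
    "CompoundRecord",
    "ReferencedTarget",
    "PredictedTarget",
    "DiseaseEvidence",
    "VennPartition",
    "canonical_smiles",
    "read_compound_table",
    "write_compound_table",
    "read_bioactivity_table",
    "read_referenced_table",
    "read_predicted_table",
    "read_evidence_table",
    "venn_partition",
    "write_network",
    "read_network_graphml",
]

ACTIVITY_TYPES = ("pKi", "pIC50", "pEC50")

DETECTION_SETS = ("extract", "plasma", "feces")


class TableFormatError(ValueError):
    """A tabular input violates the documented schema."""


def canonical_smiles(smiles: str, context: str = "") -> str:
    """Canonicalize a SMILES string, raising :class:`TableFormatError` if invalid.

    Canonicalization on read means downstream structure identity checks are
    plain string equality.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" ({context})" if context else ""
        raise TableFormatError(f"unparsable SMILES {smiles!r}{where}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """One quantitatively validated compound of the formula.

    Detection flags record where UPLC-MS identified the compound (formula
    extract, rat plasma, rat feces); at least one must be set. ``abundance_rank``
    is 1 for the most abundant compound within its herb. ``available`` and
    ``pharmacology_use`` annotate commercial availability and frequent use in
    pharmacology studies — the representative-selection criteria.
    """

    compound_id: str
    name: str
    smiles: str
    herb: str
    in_extract: bool
    in_plasma: bool
    in_feces: bool
    abundance_rank: int | None = None
    available: bool | None = None
    pharmacology_use: bool | None = None

    def __post_init__(self) -> None:
        if not (self.in_extract or self.in_plasma or self.in_feces):
            raise TableFormatError(
                f"compound {self.compound_id!r}: at least one detection flag must be set"
            )
        if self.abundance_rank is not None and self.abundance_rank < 1:
            raise TableFormatError(
                f"compound {self.compound_id!r}: abundance_rank must be positive"
            )


@dataclass(frozen=True)
class ReferencedTarget:
    """A literature-curated compound-target association."""

    compound_id: str
    target_id: str
    citation_tag: str = ""


@dataclass(frozen=True)
class PredictedTarget:
    """A model- or table-supplied predicted compound-target association.

    Used when predictions come from a transcription table rather than from a
    freshly fitted model; the prediction module produces richer
    :class:`~focuspharm.most_predict.TargetPrediction` objects.
    """

    compound_id: str
    target_id: str
    detail: str = ""


@dataclass(frozen=True)
class DiseaseEvidence:
    """A target with literature evidence linking it to a disorder.

    ``pathway`` places the target in a signaling pathway (e.g. acetylcholine,
    estrogen); the network builder connects the disorder through pathway nodes.
    """

    target_id: str
    disorder: str
    pathway: str
    note: str = ""
    citation_tag: str = ""

    def __post_init__(self) -> None:
        if not self.pathway:
            raise TableFormatError(
                f"evidence for {self.target_id!r}: pathway must be nonempty"
            )


@dataclass(frozen=True)
class VennPartition:
    """Membership-region counts over the three detection sets.

    ``regions`` maps a frozenset over {"extract", "plasma", "feces"} to the
    number of compounds whose flags match exactly that pattern. Region counts
    partition the records: they sum to the number of records, and each set
    size equals the sum of the regions containing it.
    """

    regions: Mapping[frozenset, int]
    set_sizes: Mapping[str, int]

    def region(self, *names: str) -> int:
        """Count of records in exactly the named sets (and no others)."""
        return self.regions.get(frozenset(names), 0)

    def in_sets(self, *names: str) -> int:
        """Count of records in all the named sets (intersection, not exclusive)."""
        want = frozenset(names)
        return sum(n for pat, n in self.regions.items() if want <= pat)

    @property
    def total(self) -> int:
        return sum(self.regions.values())


# ---------------------------------------------------------------------------
# CSV parsing helpers

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_flag(raw: str, column: str, row: int) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise TableFormatError(f"row {row}: column {column!r} has non-boolean value {raw!r}")


def _parse_opt_flag(raw: str, column: str, row: int) -> bool | None:
    if raw.strip() == "":
        return None
    return _parse_flag(raw, column, row)


def _read_rows(path: str | Path, required: Sequence[str]) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
    reader = csv.DictReader(io.StringIO("".join(lines)))
    if reader.fieldnames is None:
        raise TableFormatError(f"{path}: empty file, header row required")
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return list(reader)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table CSV into validated records.

    Required columns: compound_id, name, smiles, herb, in_extract, in_plasma,
    in_feces. Optional: abundance_rank, available, pharmacology_use. SMILES are
    canonicalized; herb codes are upper-cased. Duplicate ids, unparsable
    SMILES and missing columns are hard errors.
    """
    rows = _read_rows(
        path,
        ["compound_id", "name", "smiles", "herb", "in_extract", "in_plasma", "in_feces"],
    )
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):  # 1-based, after header
        cid = row["compound_id"].strip()
        if not cid:
            raise TableFormatError(f"row {i}: empty compound_id")
        if cid in seen:
            raise TableFormatError(f"duplicate compound_id {cid!r} (row {i})")
        seen.add(cid)
        rank_raw = (row.get("abundance_rank") or "").strip()
        try:
            rank = int(rank_raw) if rank_raw else None
        except ValueError:
            raise TableFormatError(
                f"row {i}: abundance_rank {rank_raw!r} is not an integer"
            ) from None
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=row["name"].strip(),
                smiles=canonical_smiles(row["smiles"].strip(), context=f"row {i}, id {cid}"),
                herb=row["herb"].strip().upper(),
                in_extract=_parse_flag(row["in_extract"], "in_extract", i),
                in_plasma=_parse_flag(row["in_plasma"], "in_plasma", i),
                in_feces=_parse_flag(row["in_feces"], "in_feces", i),
                abundance_rank=rank,
                available=_parse_opt_flag(row.get("available", ""), "available", i),
                pharmacology_use=_parse_opt_flag(
                    row.get("pharmacology_use", ""), "pharmacology_use", i
                ),
            )
        )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path,
                         header_comment: str | None = None) -> None:
    """Write records back to the CSV schema read by :func:`read_compound_table`."""
    cols = ["compound_id", "name", "smiles", "herb", "in_extract", "in_plasma",
            "in_feces", "abundance_rank", "available", "pharmacology_use"]

    def cell(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "1" if v else "0"
        return v

    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(cols)
        for r in records:
            w.writerow([cell(getattr(r, c)) for c in cols])


def read_bioactivity_table(path: str | Path):
    """Read a ligand-target bioactivity CSV.

    Columns: ligand_id, smiles, target_id, activity_type, value, release_tag.
    ``activity_type`` must be one of pKi / pIC50 / pEC50 (the -log10 molar
    potency measures the prediction models are trained on); values must be
    finite numbers.
    """
    from .most_predict import BioactivityRecord  # local import avoids a cycle

    rows = _read_rows(
        path, ["ligand_id", "smiles", "target_id", "activity_type", "value", "release_tag"]
    )
    records = []
    for i, row in enumerate(rows, start=2):
        atype = row["activity_type"].strip()
        if atype not in ACTIVITY_TYPES:
            raise TableFormatError(
                f"row {i}: unknown activity_type {atype!r}; expected one of {ACTIVITY_TYPES}"
            )
        try:
            value = float(row["value"])
        except ValueError:
            raise TableFormatError(
                f"row {i}: non-numeric activity value {row['value']!r}"
            ) from None
        if not pd.notna(value) or value in (float("inf"), float("-inf")):
            raise TableFormatError(f"row {i}: activity value must be finite")
        records.append(
            BioactivityRecord(
                ligand_id=row["ligand_id"].strip(),
                smiles=canonical_smiles(row["smiles"].strip(), context=f"row {i}"),
                target_id=row["target_id"].strip(),
                activity_type=atype,
                value=value,
                release_tag=row["release_tag"].strip(),
            )
        )
    return records


def read_referenced_table(path: str | Path) -> list[ReferencedTarget]:
    """Read a literature-curated compound-target table (Table 1 style)."""
    rows = _read_rows(path, ["compound_id", "target_id"])
    out: list[ReferencedTarget] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=2):
        key = (row["compound_id"].strip(), row["target_id"].strip())
        if key in seen:
            raise TableFormatError(f"row {i}: duplicate referenced pair {key}")
        seen.add(key)
        out.append(ReferencedTarget(*key, citation_tag=(row.get("citation_tag") or "").strip()))
    return out


def read_predicted_table(path: str | Path) -> list[PredictedTarget]:
    """Read a table-supplied predicted compound-target list."""
    rows = _read_rows(path, ["compound_id", "target_id"])
    out: list[PredictedTarget] = []
    for row in rows:
        out.append(
            PredictedTarget(
                row["compound_id"].strip(),
                row["target_id"].strip(),
                detail=(row.get("detail") or "").strip(),
            )
        )
    return out


def read_evidence_table(path: str | Path) -> list[DiseaseEvidence]:
    """Read a target-disorder evidence table (Table 2 style).

    One record per (target, disorder); duplicates are hard errors. Pathway
    labels are preserved verbatim.
    """
    rows = _read_rows(path, ["target_id", "disorder", "pathway"])
    out: list[DiseaseEvidence] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=2):
        key = (row["target_id"].strip(), row["disorder"].strip())
        if key in seen:
            raise TableFormatError(f"row {i}: duplicate evidence for target/disorder {key}")
        seen.add(key)
        out.append(
            DiseaseEvidence(
                target_id=key[0],
                disorder=key[1],
                pathway=row["pathway"].strip(),
                note=(row.get("note") or "").strip(),
                citation_tag=(row.get("citation_tag") or "").strip(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Venn accounting


def venn_partition(records: Sequence[CompoundRecord]) -> VennPartition:
    """Partition compounds by their exact detection-flag pattern.

    Every record lands in exactly one membership region over the sets
    {extract, plasma, feces}; a record with no flag set violates the record
    invariant and is an error.
    """
    if not records:
        raise TableFormatError("venn_partition requires at least one record")
    regions: dict[frozenset, int] = {}
    sizes = {name: 0 for name in DETECTION_SETS}
    for r in records:
        pattern = frozenset(
            name
            for name, flag in zip(DETECTION_SETS, (r.in_extract, r.in_plasma, r.in_feces))
            if flag
        )
        if not pattern:
            raise TableFormatError(
                f"compound {r.compound_id!r} has no detection flag set"
            )
        regions[pattern] = regions.get(pattern, 0) + 1
        for name in pattern:
            sizes[name] += 1
    return VennPartition(regions=regions, set_sizes=sizes)


# ---------------------------------------------------------------------------
# Network serialization

NETWORK_FORMATS = ("graphml", "sif", "csv")


def write_network(network, path: str | Path, format: str = "graphml",
                  header_comment: str | None = None):
    """Serialize a pharmacology network.

    graphml round-trips node/edge sets and attributes; sif writes one
    ``source relation target`` line per edge; csv writes separate node and
    edge tables (``<stem>_nodes.csv`` / ``<stem>_edges.csv``). Returns the
    list of files written.
    """
    from .network_build import PharmNetwork

    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if not isinstance(network, PharmNetwork):
        raise TypeError("write_network expects a PharmNetwork")
    g = network.graph
    path = Path(path)
    if format == "graphml":
        out = g.copy()
        if header_comment:
            out.graph["provenance"] = header_comment
        nx.write_graphml(out, path)
        return [path]
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{data.get('kind', 'link')}\t{v}\n")
        return [path]
    # csv: node and edge tables next to each other
    nodes_path = path.with_name(path.stem + "_nodes.csv")
    edges_path = path.with_name(path.stem + "_edges.csv")
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["node_id", "kind", "label"])
        for n, data in sorted(g.nodes(data=True)):
            w.writerow([n, data.get("kind", ""), data.get("label", n)])
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["source", "target", "kind", "evidence", "detail"])
        for u, v, data in sorted(g.edges(data=True)):
            w.writerow([u, v, data.get("kind", ""), data.get("evidence", ""),
                        data.get("detail", "")])
    return [nodes_path, edges_path]


def read_network_graphml(path: str | Path):
    """Read back a graphml network written by :func:`write_network`."""
    from .network_build import PharmNetwork

    g = nx.read_graphml(path)
    g.graph.pop("provenance", None)
    disorder = [n for n, d in g.nodes(data=True) if d.get("kind") == "disorder"]
    return PharmNetwork(graph=nx.Graph(g), disorder=disorder[0] if disorder else None)
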
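"""Chemical-space analysis: fingerprints, similarity, clustering, component groups.

The central abstraction is the *component group*: a cluster of structurally
similar compounds, most of which come from the same herb, that can be treated
as a single pharmacological unit and represented by one member compound.
Groups are found by average-linkage hierarchical clustering of Morgan/ECFP4
Tanimoto similarities, cutting the dendrogram at a fixed distance, and keeping
clusters that are large and herb-pure enough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .io_tables import CompoundRecord

__all__ = [
    "FingerprintSet",
    "SimilarityMatrix",
    "ClusterTree",
    "ComponentGroup",
    "GroupingResult",
    "compute_fingerprints",
    "fingerprint_smiles",
    "tanimoto",
    "tanimoto_matrix",
    "hierarchical_cluster",
    "detect_component_groups",
    "select_representative",
    "pca_projection",
]


@dataclass(frozen=True)
class FingerprintSet:
    """Morgan circular fingerprints for an ordered set of compounds.

    ``bits`` is a (n_compounds, n_bits) 0/1 array, one row per compound in
    ``compound_ids`` order. Radius 2 corresponds to ECFP diameter 4.
    """

    compound_ids: tuple[str, ...]
    bits: np.ndarray
    radius: int
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits.shape != (len(self.compound_ids), self.n_bits):
            raise ValueError("fingerprint matrix shape does not match ids/n_bits")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Dense symmetric Tanimoto matrix over an ordered compound set."""

    compound_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.compound_ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix must be square over compound_ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("Tanimoto values must lie in [0, 1]")

    def pair(self, a: str, b: str) -> float:
        i = self.compound_ids.index(a)
        j = self.compound_ids.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge tree over compounds.

    ``merges`` is the scipy linkage encoding: row k merges clusters with
    indices merges[k, 0] and merges[k, 1] (leaves are 0..n-1, internal nodes
    n+k) at height merges[k, 2], producing a cluster of merges[k, 3] leaves.
    Distances are ``1 - Tanimoto``.
    """

    compound_ids: tuple[str, ...]
    merges: np.ndarray
    linkage_method: str = "average"
    distance: str = "1 - tanimoto"

    def __post_init__(self) -> None:
        n = len(self.compound_ids)
        if n >= 2 and self.merges.shape != (n - 1, 4):
            raise ValueError("a tree over n leaves must contain n - 1 merges")


@dataclass(frozen=True)
class ComponentGroup:
    """A cluster of structurally similar compounds, mostly from one herb."""

    group_id: str
    members: tuple[str, ...]
    dominant_herb: str
    purity: float
    representative_id: str | None = None

    def __post_init__(self) -> None:
        if self.representative_id is not None and self.representative_id not in self.members:
            raise ValueError("representative must be a group member")


@dataclass(frozen=True)
class GroupingResult:
    """Component groups plus the compounds left unassigned by the criteria."""

    groups: tuple[ComponentGroup, ...]
    unassigned: tuple[str, ...]


_FP_CACHE: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_CACHE:
        _FP_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_CACHE[key]


def fingerprint_smiles(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan fingerprint of a single SMILES as a 0/1 uint8 vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    fp = _generator(radius, n_bits).GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def compute_fingerprints(
    records: Sequence[CompoundRecord], radius: int = 2, n_bits: int = 2048
) -> FingerprintSet:
    """Morgan fingerprints (default radius 2, i.e. ECFP4-like) for all records."""
    bits = np.zeros((len(records), n_bits), dtype=np.uint8)
    for i, rec in enumerate(records):
        bits[i] = fingerprint_smiles(rec.smiles, radius=radius, n_bits=n_bits)
    return FingerprintSet(
        compound_ids=tuple(r.compound_id for r in records),
        bits=bits,
        radius=radius,
        n_bits=n_bits,
    )


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two bit vectors.

    Defined as 1.0 when both vectors are all-zero (identical empty
    substructure sets).
    """
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity, computed by vectorized popcounts."""
    if len(fps.compound_ids) == 0:
        raise ValueError("fingerprint set is empty")
    b = fps.bits.astype(np.int64)
    inter = b @ b.T
    pop = b.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(compound_ids=fps.compound_ids, values=sim)


def hierarchical_cluster(sim: SimilarityMatrix, linkage_method: str = "average") -> ClusterTree:
    """Agglomerative clustering on distance ``d = 1 - Tanimoto``.

    Average linkage by default; the method label travels with the tree so
    single/complete alternates remain selectable and auditable.
    """
    d = 1.0 - sim.values
    if np.isnan(d).any():
        raise ValueError("similarity matrix contains NaN")
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    merges = linkage(condensed, method=linkage_method)
    return ClusterTree(
        compound_ids=sim.compound_ids,
        merges=merges,
        linkage_method=linkage_method,
    )


def detect_component_groups(
    tree: ClusterTree,
    records: Sequence[CompoundRecord],
    cut_height: float = 0.6,
    min_size: int = 2,
    purity_min: float = 0.5,
) -> GroupingResult:
    """Cut the dendrogram into flat clusters and keep the herb-pure ones.

    A flat cluster becomes a component group when it has at least ``min_size``
    members and the fraction of members from its modal herb strictly exceeds
    ``purity_min`` (a strict majority at the default 0.5). Modal-herb ties go
    to the lexicographically smallest herb code. Compounds in clusters that
    fail either criterion are reported as unassigned.
    """
    if not 0.0 <= cut_height <= 1.0:
        raise ValueError(f"cut_height must be in [0, 1], got {cut_height}")
    by_id = {r.compound_id: r for r in records}
    missing = [cid for cid in tree.compound_ids if cid not in by_id]
    if missing:
        raise ValueError(f"tree ids missing from records: {missing[:5]}")
    if len(tree.compound_ids) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(tree.merges, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for cid, lab in zip(tree.compound_ids, labels):
        clusters.setdefault(int(lab), []).append(cid)

    groups: list[ComponentGroup] = []
    unassigned: list[str] = []
    # deterministic group order: by first-member position in the input ordering
    order = {cid: i for i, cid in enumerate(tree.compound_ids)}
    for lab in sorted(clusters, key=lambda l: min(order[c] for c in clusters[l])):
        members = sorted(clusters[lab])
        if len(members) < min_size:
            unassigned.extend(members)
            continue
        herbs: dict[str, int] = {}
        for m in members:
            herbs[by_id[m].herb] = herbs.get(by_id[m].herb, 0) + 1
        top = max(herbs.values())
        dominant = min(h for h, n in herbs.items() if n == top)
        purity = top / len(members)
        if purity <= purity_min:
            unassigned.extend(members)
            continue
        groups.append(
            ComponentGroup(
                group_id=f"G{len(groups) + 1}",
                members=tuple(members),
                dominant_herb=dominant,
                purity=purity,
            )
        )
    return GroupingResult(groups=tuple(groups), unassigned=tuple(sorted(unassigned)))


def select_representative(
    group: ComponentGroup, records: Sequence[CompoundRecord]
) -> str:
    """Pick the member that stands for a component group.

    Lexicographic priority: (1) detected in a biological sample (plasma or
    feces), (2) lowest abundance rank, (3) commercially available, (4) frequent
    pharmacology use, (5) smallest compound_id. Mirrors choosing compounds that
    are abundant, obtainable, and well characterized.
    """
    if not group.members:
        raise ValueError("cannot select a representative from an empty group")
    by_id = {r.compound_id: r for r in records}

    def key(cid: str):
        r = by_id[cid]
        in_bio = r.in_plasma or r.in_feces
        rank = r.abundance_rank if r.abundance_rank is not None else math.inf
        return (not in_bio, rank, not bool(r.available), not bool(r.pharmacology_use), cid)

    return min(group.members, key=key)


def pca_projection(fps: FingerprintSet, n_components: int = 2) -> np.ndarray:
    """Project compounds onto the top principal components of the bit matrix.

    The 0/1 matrix is mean-centered but not scaled. Returns an
    (n_compounds, n_components) coordinate array; explained variances are
    non-increasing by construction.
    """
    n = len(fps.compound_ids)
    if n < 2:
        raise ValueError("PCA requires at least 2 compounds")
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds number of compounds {n}")
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(fps.bits.astype(float))
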
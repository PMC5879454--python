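"""Assemble the compound-target-pathway-disorder network.

Referenced (literature-curated) and predicted compound-target associations are
merged into evidence-typed edges, filtered to targets with disease evidence,
and expanded into a typed graph: compound -> target -> pathway -> disorder.
Compounds whose every target lacks disease evidence drop out of the network
entirely (as albiflorin does in the worked constipation example).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .io_tables import DiseaseEvidence, PredictedTarget, ReferencedTarget

__all__ = [
    "CompoundTargetEdge",
    "PharmNetwork",
    "FilterResult",
    "merge_targets",
    "filter_by_disease",
    "assemble_network",
    "network_summary",
]


@dataclass(frozen=True)
class CompoundTargetEdge:
    """One compound-target association with merged evidence provenance."""

    compound_id: str
    target_id: str
    evidence: str  # "referenced" | "predicted" | "both"
    detail: str = ""

    def __post_init__(self) -> None:
        if self.evidence not in ("referenced", "predicted", "both"):
            raise ValueError(f"bad evidence label {self.evidence!r}")


@dataclass
class PharmNetwork:
    """Typed pharmacology network over compounds, targets, pathways, disorder.

    Node attribute ``kind`` is one of compound/target/pathway/disorder; edge
    attribute ``kind`` is one of compound-target/target-pathway/
    pathway-disorder; compound-target edges carry an ``evidence`` attribute.
    """

    graph: nx.Graph
    disorder: str | None = None

    def nodes_of(self, kind: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind
        )

    def edges_of(self, kind: str) -> list[tuple[str, str, dict]]:
        return sorted(
            (u, v, d) for u, v, d in self.graph.edges(data=True) if d.get("kind") == kind
        )

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        for n in self.graph.nodes:
            if self.graph.degree(n) == 0:
                raise ValueError(f"orphan node {n!r}")
        kinds = {"compound", "target", "pathway", "disorder"}
        for n, d in self.graph.nodes(data=True):
            if d.get("kind") not in kinds:
                raise ValueError(f"node {n!r} has unknown kind {d.get('kind')!r}")


@dataclass(frozen=True)
class FilterResult:
    """Edges surviving the disease-evidence filter plus what was dropped."""

    edges: tuple[CompoundTargetEdge, ...]
    dropped: Mapping[str, tuple[str, ...]]  # compound_id -> dropped target_ids


def _pred_fields(p) -> tuple[str, str, str]:
    """Accept PredictedTarget, TargetPrediction, or a (compound, target) tuple."""
    if hasattr(p, "query_id"):  # TargetPrediction
        detail = f"p={p.p_value:.3g};tc={p.tc_max:.3g};type={p.activity_type}"
        return p.query_id, p.target_id, detail
    if hasattr(p, "compound_id"):
        return p.compound_id, p.target_id, getattr(p, "detail", "")
    c, t = p[0], p[1]
    return c, t, ""


def merge_targets(
    referenced: Sequence[ReferencedTarget],
    predicted: Sequence,
) -> list[CompoundTargetEdge]:
    """Union referenced and predicted associations into evidence-typed edges.

    One edge per (compound, target); when both sources name the pair the edge
    is marked ``both`` and the detail retains both the citation and the
    prediction statistics. Duplicates within a source collapse.
    """
    ref: dict[tuple[str, str], str] = {}
    for r in referenced:
        key = (r.compound_id, r.target_id)
        if key not in ref:
            ref[key] = r.citation_tag
    pred: dict[tuple[str, str], str] = {}
    for p in predicted:
        c, t, detail = _pred_fields(p)
        if (c, t) not in pred:
            pred[(c, t)] = detail
    edges = []
    for key in sorted(set(ref) | set(pred)):
        in_ref, in_pred = key in ref, key in pred
        evidence = "both" if (in_ref and in_pred) else ("referenced" if in_ref else "predicted")
        detail = ";".join(x for x in (ref.get(key, ""), pred.get(key, "")) if x)
        edges.append(CompoundTargetEdge(key[0], key[1], evidence, detail))
    return edges


def filter_by_disease(
    edges: Sequence[CompoundTargetEdge], evidence: Sequence[DiseaseEvidence]
) -> FilterResult:
    """Keep only edges whose target carries disease evidence.

    Targets absent from the evidence table are dropped and reported per
    compound, so the exclusion of a compound from the final network is
    auditable.
    """
    keep_targets = {e.target_id for e in evidence}
    kept = tuple(e for e in edges if e.target_id in keep_targets)
    dropped: dict[str, list[str]] = {}
    for e in edges:
        if e.target_id not in keep_targets:
            dropped.setdefault(e.compound_id, []).append(e.target_id)
    return FilterResult(
        edges=kept,
        dropped={c: tuple(sorted(ts)) for c, ts in sorted(dropped.items())},
    )


def assemble_network(
    edges: Sequence[CompoundTargetEdge],
    evidence: Sequence[DiseaseEvidence],
    disorder: str = "constipation",
) -> PharmNetwork:
    """Build the compound-target-pathway-disorder graph.

    Compound nodes are compounds with at least one surviving edge; pathway
    nodes are the distinct pathways of the surviving targets; the disorder is
    reached through pathway nodes (compound - target - pathway - disorder),
    so no orphan node can exist by construction. Every edge's target must have
    an evidence record for the disorder.
    """
    ev_by_target = {e.target_id: e for e in evidence if e.disorder == disorder}
    g = nx.Graph()
    for e in edges:
        if e.target_id not in ev_by_target:
            raise ValueError(
                f"edge {e.compound_id}->{e.target_id}: target has no "
                f"evidence record for disorder {disorder!r}"
            )
    if not edges:
        return PharmNetwork(graph=g, disorder=disorder)
    g.add_node(disorder, kind="disorder", label=disorder)
    for e in edges:
        ev = ev_by_target[e.target_id]
        g.add_node(e.compound_id, kind="compound", label=e.compound_id)
        g.add_node(e.target_id, kind="target", label=e.target_id)
        g.add_node(ev.pathway, kind="pathway", label=ev.pathway)
        g.add_edge(e.compound_id, e.target_id, kind="compound-target",
                   evidence=e.evidence, detail=e.detail)
        g.add_edge(e.target_id, ev.pathway, kind="target-pathway")
        g.add_edge(ev.pathway, disorder, kind="pathway-disorder")
    net = PharmNetwork(graph=g, disorder=disorder)
    net.validate()
    return net


def network_summary(network: PharmNetwork) -> dict:
    """Counts by node/edge type plus per-compound target degree."""
    g = network.graph
    node_counts = {k: len(network.nodes_of(k))
                   for k in ("compound", "target", "pathway", "disorder")}
    edge_counts = {k: len(network.edges_of(k))
                   for k in ("compound-target", "target-pathway", "pathway-disorder")}
    degree = {
        c: sum(1 for _, _, d in g.edges(c, data=True) if d.get("kind") == "compound-target")
        for c in network.nodes_of("compound")
    }
    return {
        "nodes": node_counts,
        "edges": edge_counts,
        "compound_degree": degree,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
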
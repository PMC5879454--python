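"""End-to-end pipeline orchestration.

``run_pipeline`` executes the focused-network-pharmacology procedure:
read compounds -> fingerprint -> cluster -> detect component groups ->
select representatives -> predict targets (or ingest supplied predictions) ->
merge with referenced targets -> filter by disease evidence -> assemble and
write the compound-target-pathway-disorder network.

Outputs are deterministic for identical config and inputs: artifacts contain
no timestamps, and every output file embeds a hash of the parameters that
produced it in a ``#`` header comment for provenance.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import chemspace, most_predict, network_build
from .io_tables import (
    read_bioactivity_table,
    read_compound_table,
    read_evidence_table,
    read_predicted_table,
    read_referenced_table,
    venn_partition,
    write_network,
)

logger = logging.getLogger("focuspharm")

__all__ = ["PipelineConfig", "run_pipeline", "params_hash"]


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    Paths may be None when a stage is skipped: with no ``bioactivity_table``
    but a ``predicted_table``, the prediction stage ingests the supplied
    predicted-target list instead of fitting models (the mode used for the
    packaged worked example, whose predictions are a printed table).
    """

    compound_table: str
    evidence_table: str
    referenced_table: str | None = None
    predicted_table: str | None = None
    bioactivity_table: str | None = None
    output_dir: str = "focuspharm_out"
    # chemical space
    radius: int = 2
    n_bits: int = 2048
    linkage: str = "average"
    cut_height: float = 0.6
    min_size: int = 2
    purity_min: float = 0.5
    exclusion_list: list[str] = field(default_factory=list)  # compound_ids
    restrict_to: list[str] = field(default_factory=list)  # optional id whitelist
    # prediction
    active_threshold: float = most_predict.ACTIVE_THRESHOLD
    tc_min: float = most_predict.TC_MIN
    alpha: float = most_predict.ALPHA
    cutoff_release: str | None = None
    l2_penalty: float = 1e-3
    # network
    disorder: str = "constipation"
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("compound_table", "evidence_table", "referenced_table",
                     "predicted_table", "bioactivity_table"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {attr}: no such file {p!r}")
        if not 0.0 <= self.cut_height <= 1.0:
            raise ValueError("cut_height must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.tc_min <= 1.0:
            raise ValueError("tc_min must be in [0, 1]")


def params_hash(params: dict) -> str:
    """Stable short hash of a parameter dict, embedded in output headers."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(path: Path, fieldnames: list[str], rows: list[dict], phash: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# params_hash: {phash}\n")
        w = csv.DictWriter(fh, fieldnames=fieldnames)
        w.writeheader()
        w.writerows(rows)


def cluster_stage(records, config: PipelineConfig):
    """Fingerprint, cluster and group the (non-excluded) compounds.

    Returns (grouping, representatives) where representatives maps group_id
    to the selected compound_id.
    """
    excluded = set(config.exclusion_list)
    kept = [r for r in records if r.compound_id not in excluded]
    if config.restrict_to:
        allow = set(config.restrict_to)
        kept = [r for r in kept if r.compound_id in allow]
    fps = chemspace.compute_fingerprints(kept, radius=config.radius, n_bits=config.n_bits)
    sim = chemspace.tanimoto_matrix(fps)
    tree = chemspace.hierarchical_cluster(sim, linkage_method=config.linkage)
    grouping = chemspace.detect_component_groups(
        tree, kept, cut_height=config.cut_height,
        min_size=config.min_size, purity_min=config.purity_min,
    )
    reps = {g.group_id: chemspace.select_representative(g, kept) for g in grouping.groups}
    return grouping, reps


def prediction_stage(records, reps: dict[str, str], config: PipelineConfig):
    """Produce compound-target predictions for the representative compounds.

    With a bioactivity table: label, optionally split temporally, train one
    model per activity type, and predict under the Tc/p filters. With only a
    supplied predicted table: ingest it verbatim.
    """
    if config.bioactivity_table:
        bio = read_bioactivity_table(config.bioactivity_table)
        labeled = most_predict.label_activity(bio, config.active_threshold)
        if config.cutoff_release is not None:
            train, _ = most_predict.temporal_split(labeled, config.cutoff_release)
        else:
            train = labeled
        models = most_predict.train_models(
            train, l2_penalty=config.l2_penalty,
            active_threshold=config.active_threshold,
            release_cutoff=config.cutoff_release,
        )
        by_id = {r.compound_id: r for r in records}
        predictions = []
        for gid in sorted(reps):
            rep = by_id[reps[gid]]
            predictions.extend(
                most_predict.predict_targets(
                    rep.smiles, labeled, models,
                    tc_min=config.tc_min, alpha=config.alpha,
                    query_id=rep.compound_id,
                )
            )
        return predictions
    if config.predicted_table:
        return read_predicted_table(config.predicted_table)
    return []


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the artifact bundle.

    Artifacts (in ``config.output_dir``): groups.csv, representatives.csv,
    predictions.csv, network.graphml / network.sif / network_nodes.csv /
    network_edges.csv, summary.json and pipeline.log. Returns the summary
    dict. Identical config + inputs give byte-identical artifacts.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if config.verbosity > 1 else logging.INFO)
    written: list[Path] = []
    try:
        cfg_dict = asdict(config)
        # artifact bytes must not depend on where they are written
        cfg_dict.pop("output_dir")
        cfg_dict.pop("verbosity")
        stage = "read"
        records = read_compound_table(config.compound_table)
        venn = venn_partition(records)
        logger.info("read %d compounds (%s)", len(records), config.compound_table)

        stage = "cluster"
        chash = params_hash({k: cfg_dict[k] for k in (
            "radius", "n_bits", "linkage", "cut_height",
            "min_size", "purity_min", "exclusion_list", "restrict_to")})
        grouping, reps = cluster_stage(records, config)
        groups_rows = [
            {"group_id": g.group_id, "dominant_herb": g.dominant_herb,
             "purity": f"{g.purity:.4f}", "n_members": len(g.members),
             "representative": reps[g.group_id], "members": ";".join(g.members)}
            for g in grouping.groups
        ]
        p = outdir / "groups.csv"
        _write_csv(p, list(groups_rows[0]) if groups_rows else
                   ["group_id", "dominant_herb", "purity", "n_members",
                    "representative", "members"], groups_rows, chash)
        written.append(p)
        by_id = {r.compound_id: r for r in records}
        rep_rows = [
            {"group_id": gid, "compound_id": reps[gid], "herb": by_id[reps[gid]].herb,
             "smiles": by_id[reps[gid]].smiles}
            for gid in sorted(reps)
        ]
        p = outdir / "representatives.csv"
        _write_csv(p, ["group_id", "compound_id", "herb", "smiles"], rep_rows, chash)
        written.append(p)
        logger.info("detected %d component groups, %d unassigned compounds",
                    len(grouping.groups), len(grouping.unassigned))

        stage = "predict"
        phash = params_hash({k: cfg_dict[k] for k in (
            "active_threshold", "tc_min",
            "alpha", "cutoff_release", "l2_penalty")})
        predictions = prediction_stage(records, reps, config)
        pred_rows = []
        for t in predictions:
            if hasattr(t, "query_id"):
                pred_rows.append({
                    "compound_id": t.query_id, "target_id": t.target_id,
                    "activity_type": t.activity_type, "tc_max": f"{t.tc_max:.4f}",
                    "nearest_ligand_id": t.nearest_ligand_id,
                    "nearest_potency": f"{t.nearest_potency:.4f}",
                    "prob_active": f"{t.prob_active:.6f}",
                    "p_value": f"{t.p_value:.6f}", "passes": int(t.passes),
                })
            else:
                pred_rows.append({
                    "compound_id": t.compound_id, "target_id": t.target_id,
                    "activity_type": "", "tc_max": "", "nearest_ligand_id": "",
                    "nearest_potency": "", "prob_active": "", "p_value": "",
                    "passes": 1,
                })
        p = outdir / "predictions.csv"
        _write_csv(p, ["compound_id", "target_id", "activity_type", "tc_max",
                       "nearest_ligand_id", "nearest_potency", "prob_active",
                       "p_value", "passes"], pred_rows, phash)
        written.append(p)

        stage = "network"
        nhash = params_hash({"disorder": cfg_dict["disorder"]})
        referenced = (read_referenced_table(config.referenced_table)
                      if config.referenced_table else [])
        evidence = read_evidence_table(config.evidence_table)
        merged = network_build.merge_targets(referenced, predictions)
        fr = network_build.filter_by_disease(merged, evidence)
        network = network_build.assemble_network(fr.edges, evidence, config.disorder)
        written += write_network(network, outdir / "network.graphml", "graphml",
                                 header_comment=f"params_hash: {nhash}")
        written += write_network(network, outdir / "network.sif", "sif",
                                 header_comment=f"params_hash: {nhash}")
        written += write_network(network, outdir / "network.csv", "csv",
                                 header_comment=f"params_hash: {nhash}")
        summary = {
            "params_hash": params_hash(cfg_dict),
            "config": cfg_dict,
            "n_compounds": len(records),
            "venn": {
                "plasma": venn.set_sizes["plasma"],
                "feces": venn.set_sizes["feces"],
                "plasma_and_feces": venn.in_sets("plasma", "feces"),
                "feces_only": venn.region("feces"),
            },
            "n_component_groups": len(grouping.groups),
            "representatives": {gid: reps[gid] for gid in sorted(reps)},
            "dropped_targets": {c: list(ts) for c, ts in fr.dropped.items()},
            "network": network_build.network_summary(network),
        }
        p = outdir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(p)
        logger.info("network: %s", summary["network"]["nodes"])
        return summary
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        for f in written:  # remove partial outputs
            f.unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
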
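"""Most-similar-ligand target prediction.

For each (target, activity type) a query compound is compared against the
target's known ligands; the nearest ligand by Morgan/ECFP4 Tanimoto similarity
supplies two features, (tc_max, nearest ligand potency), which a per-activity-
type logistic model turns into a calibrated probability that the query is
active (potency >= 6 on the -log10 molar scale). A prediction survives only if
tc_max >= tc_min (default 0.45) and p = 1 - P(active) < alpha (default 0.05).

The p-value here is explicitly 1 minus the calibrated activity probability, so
the filter reads "at least 95% confidence of activity"; other constructions
can be plugged in by replacing :meth:`MostModel.predict_proba`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .chemspace import fingerprint_smiles, tanimoto
from .io_tables import ACTIVITY_TYPES

__all__ = [
    "BioactivityRecord",
    "LabeledPair",
    "MostModel",
    "TargetPrediction",
    "label_activity",
    "temporal_split",
    "extract_features",
    "fit_activity_model",
    "train_most_model",
    "train_models",
    "predict_targets",
    "evaluate_accuracy",
]

ACTIVE_THRESHOLD = 6.0
TC_MIN = 0.45
ALPHA = 0.05


@dataclass(frozen=True)
class BioactivityRecord:
    """One ligand-target potency measurement.

    ``value`` is a -log10 molar potency (pKi, pIC50 or pEC50); ``release_tag``
    is an ordered label (e.g. a database release) used for temporal splits.
    """

    ligand_id: str
    smiles: str
    target_id: str
    activity_type: str
    value: float
    release_tag: str

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(f"activity_type must be one of {ACTIVITY_TYPES}")
        if not np.isfinite(self.value):
            raise ValueError("activity value must be finite")


@dataclass(frozen=True)
class LabeledPair:
    """A deduplicated (ligand, target, activity type) pair with its active label."""

    ligand_id: str
    smiles: str
    target_id: str
    activity_type: str
    value: float
    release_tag: str
    active: bool


@dataclass
class MostModel:
    """Per-activity-type logistic model on (tc_max, nearest potency).

    P(active) = sigmoid(intercept + coef_sim * tc_max + coef_pot * potency).
    """

    activity_type: str
    intercept: float
    coef_sim: float
    coef_pot: float
    active_threshold: float = ACTIVE_THRESHOLD
    n_train: int = 0
    release_cutoff: str | None = None
    train_checksum: str | None = None

    def __post_init__(self) -> None:
        for v in (self.intercept, self.coef_sim, self.coef_pot):
            if not np.isfinite(v):
                raise ValueError("model coefficients must be finite")
        if self.active_threshold <= 0:
            raise ValueError("active_threshold must be positive")

    def predict_proba(self, tc_max: float, potency: float) -> float:
        z = self.intercept + self.coef_sim * tc_max + self.coef_pot * potency
        return float(1.0 / (1.0 + np.exp(-z)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MostModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TargetPrediction:
    """One query-compound -> target call with its features and filter status."""

    query_id: str
    target_id: str
    activity_type: str
    tc_max: float
    nearest_ligand_id: str
    nearest_potency: float
    prob_active: float
    p_value: float
    passes: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.tc_max <= 1.0:
            raise ValueError("tc_max must lie in [0, 1]")
        if abs((self.prob_active + self.p_value) - 1.0) > 1e-12:
            raise ValueError("p_value must equal 1 - prob_active")


def label_activity(
    records: Sequence[BioactivityRecord], active_threshold: float = ACTIVE_THRESHOLD
) -> list[LabeledPair]:
    """Label each (ligand, target, activity type) pair active/inactive.

    Active iff value >= active_threshold (boundary inclusive, default 6.0 on
    the -log10 molar scale). Duplicate measurements of the same pair collapse
    to the one with the maximum value.
    """
    best: dict[tuple[str, str, str], BioactivityRecord] = {}
    for r in records:
        key = (r.ligand_id, r.target_id, r.activity_type)
        if key not in best or r.value > best[key].value:
            best[key] = r
    out = []
    for key in sorted(best):
        r = best[key]
        out.append(
            LabeledPair(
                ligand_id=r.ligand_id,
                smiles=r.smiles,
                target_id=r.target_id,
                activity_type=r.activity_type,
                value=r.value,
                release_tag=r.release_tag,
                active=r.value >= active_threshold,
            )
        )
    return out


def temporal_split(
    records: Sequence, cutoff_release: str
) -> tuple[list, list]:
    """Split records into (train, test) by release tag.

    Train = release_tag <= cutoff; test = later releases. The split is
    exhaustive and disjoint; an empty side only warns, it is not an error.
    """
    train = [r for r in records if r.release_tag <= cutoff_release]
    test = [r for r in records if r.release_tag > cutoff_release]
    if not train or not test:
        warnings.warn(
            f"temporal cutoff {cutoff_release!r} leaves an empty "
            f"{'train' if not train else 'test'} side",
            stacklevel=2,
        )
    return train, test


def _fingerprints_for(pairs: Sequence[LabeledPair], cache: dict) -> None:
    for p in pairs:
        if p.smiles not in cache:
            cache[p.smiles] = fingerprint_smiles(p.smiles)


def extract_features(
    query_smiles: str,
    target_id: str,
    train_pairs: Sequence[LabeledPair],
    exclude_ligand_id: str | None = None,
    _fp_cache: dict | None = None,
):
    """Features of a query against one target's reference ligands.

    Returns (tc_max, nearest_potency, nearest_ligand_id), where the nearest
    ligand maximizes Tanimoto similarity to the query; ties break toward
    higher potency, then lexicographically smaller ligand_id. Returns None
    when the target has no reference ligands (after exclusion), so batch
    prediction can skip the target rather than abort.
    """
    ligands = [
        p for p in train_pairs
        if p.target_id == target_id
        and (exclude_ligand_id is None or p.ligand_id != exclude_ligand_id)
    ]
    if not ligands:
        return None
    cache = _fp_cache if _fp_cache is not None else {}
    if query_smiles not in cache:
        cache[query_smiles] = fingerprint_smiles(query_smiles)
    _fingerprints_for(ligands, cache)
    qfp = cache[query_smiles]
    best = None
    best_key = None
    for p in ligands:
        tc = tanimoto(qfp, cache[p.smiles])
        key = (-tc, -p.value, p.ligand_id)  # max tc, then max potency, then id
        if best_key is None or key < best_key:
            best_key = key
            best = (tc, p.value, p.ligand_id)
    return best


def fit_activity_model(
    features: np.ndarray,
    labels: np.ndarray,
    activity_type: str,
    l2_penalty: float = 1e-3,
    active_threshold: float = ACTIVE_THRESHOLD,
) -> MostModel:
    """Fit the logistic activity model on an (n, 2) feature matrix.

    Columns are (tc_max, nearest_potency). A small L2 penalty keeps
    coefficients finite on separable data; the optimizer is deterministic
    (lbfgs, fixed tolerance), so refitting identical input reproduces the
    coefficients bit-for-bit.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        n_pos = int(labels.sum())
        raise ValueError(
            f"single-class training data for {activity_type}: "
            f"{n_pos} active vs {len(labels) - n_pos} inactive"
        )
    clf = LogisticRegression(
        C=1.0 / (l2_penalty * len(labels)),
        solver="lbfgs",
        tol=1e-8,
        max_iter=5000,
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return MostModel(
        activity_type=activity_type,
        intercept=float(clf.intercept_[0]),
        coef_sim=float(clf.coef_[0, 0]),
        coef_pot=float(clf.coef_[0, 1]),
        active_threshold=active_threshold,
        n_train=len(labels),
    )


def _train_checksum(pairs: Sequence[LabeledPair]) -> str:
    h = hashlib.sha256()
    for p in sorted(pairs, key=lambda q: (q.ligand_id, q.target_id, q.activity_type)):
        h.update(
            f"{p.ligand_id}|{p.target_id}|{p.activity_type}|{p.value}|{p.release_tag}".encode()
        )
    return h.hexdigest()


def train_most_model(
    train_pairs: Sequence[LabeledPair],
    activity_type: str,
    l2_penalty: float = 1e-3,
    active_threshold: float = ACTIVE_THRESHOLD,
    release_cutoff: str | None = None,
) -> MostModel:
    """Train the per-activity-type model with leave-one-out features.

    Each training ligand's features are computed against its target's *other*
    ligands (self excluded), preventing the tc_max = 1 self-match leak. Pairs
    whose target has a single ligand contribute no usable feature and are
    dropped. Requires >= 20 usable pairs with both classes present.
    """
    pairs = [p for p in train_pairs if p.activity_type == activity_type]
    cache: dict = {}
    feats, labels, used = [], [], []
    for p in pairs:
        f = extract_features(
            p.smiles, p.target_id, pairs, exclude_ligand_id=p.ligand_id, _fp_cache=cache
        )
        if f is None:
            continue
        feats.append([f[0], f[1]])
        labels.append(p.active)
        used.append(p)
    if len(feats) < 20:
        raise ValueError(
            f"need at least 20 usable training pairs for {activity_type}, got {len(feats)}"
        )
    model = fit_activity_model(
        np.array(feats), np.array(labels), activity_type,
        l2_penalty=l2_penalty, active_threshold=active_threshold,
    )
    model.release_cutoff = release_cutoff
    model.train_checksum = _train_checksum(used)
    return model


def train_models(
    train_pairs: Sequence[LabeledPair],
    l2_penalty: float = 1e-3,
    active_threshold: float = ACTIVE_THRESHOLD,
    release_cutoff: str | None = None,
) -> dict[str, MostModel]:
    """Train one model per activity type present in the training pairs."""
    models: dict[str, MostModel] = {}
    for atype in ACTIVITY_TYPES:
        if any(p.activity_type == atype for p in train_pairs):
            models[atype] = train_most_model(
                train_pairs, atype, l2_penalty=l2_penalty,
                active_threshold=active_threshold, release_cutoff=release_cutoff,
            )
    return models


def predict_targets(
    query_smiles: str,
    dataset: Sequence[LabeledPair],
    models: Mapping[str, MostModel],
    tc_min: float = TC_MIN,
    alpha: float = ALPHA,
    query_id: str = "query",
    keep_all: bool = False,
) -> list[TargetPrediction]:
    """Predict targets for one query compound.

    For every (target, activity type) with reference ligands in ``dataset``,
    the nearest-ligand features are scored by the matching model; p-value is
    1 - P(active). A target is reported when ANY activity type passes both
    filters (tc_max >= tc_min and p < alpha); for each reported target the
    passing prediction with the smallest p-value is returned. Output is sorted
    by p-value then target_id. ``keep_all=True`` instead returns every scored
    prediction with its ``passes`` flag, for diagnostics.
    """
    if not models:
        raise ValueError("no trained models supplied")
    cache: dict = {}
    all_preds: list[TargetPrediction] = []
    pairs_by = {}
    for p in dataset:
        pairs_by.setdefault((p.target_id, p.activity_type), []).append(p)
    for (target_id, atype) in sorted(pairs_by):
        model = models.get(atype)
        if model is None:
            continue
        f = extract_features(query_smiles, target_id, pairs_by[(target_id, atype)],
                             _fp_cache=cache)
        if f is None:
            continue
        tc_max, potency, nearest = f
        prob = model.predict_proba(tc_max, potency)
        p_value = 1.0 - prob
        all_preds.append(
            TargetPrediction(
                query_id=query_id,
                target_id=target_id,
                activity_type=atype,
                tc_max=tc_max,
                nearest_ligand_id=nearest,
                nearest_potency=potency,
                prob_active=prob,
                p_value=p_value,
                passes=(tc_max >= tc_min and p_value < alpha),
            )
        )
    if keep_all:
        return sorted(all_preds, key=lambda t: (t.p_value, t.target_id))
    best: dict[str, TargetPrediction] = {}
    for t in all_preds:
        if not t.passes:
            continue
        if t.target_id not in best or t.p_value < best[t.target_id].p_value:
            best[t.target_id] = t
    return sorted(best.values(), key=lambda t: (t.p_value, t.target_id))


def evaluate_accuracy(
    models: Mapping[str, MostModel],
    test_pairs: Sequence[LabeledPair],
    reference_pairs: Sequence[LabeledPair],
) -> dict[str, float]:
    """Accuracy of thresholded predictions (P(active) >= 0.5) per activity type.

    Test-pair features are computed against the *reference* (training) ligand
    set, mirroring temporal validation: later-release pairs are scored with
    earlier-release knowledge only. Types with no evaluable test pairs are
    omitted with a warning.
    """
    cache: dict = {}
    by_type: dict[str, list[LabeledPair]] = {}
    for p in test_pairs:
        by_type.setdefault(p.activity_type, []).append(p)
    ref_by_type: dict[str, list[LabeledPair]] = {}
    for p in reference_pairs:
        ref_by_type.setdefault(p.activity_type, []).append(p)
    out: dict[str, float] = {}
    for atype, pairs in sorted(by_type.items()):
        model = models.get(atype)
        if model is None:
            warnings.warn(f"no model for activity type {atype}; omitted", stacklevel=2)
            continue
        correct = total = 0
        for p in pairs:
            f = extract_features(
                p.smiles, p.target_id, ref_by_type.get(atype, []),
                exclude_ligand_id=p.ligand_id, _fp_cache=cache,
            )
            if f is None:
                continue
            pred_active = model.predict_proba(f[0], f[1]) >= 0.5
            correct += int(pred_active == p.active)
            total += 1
        if total == 0:
            warnings.warn(f"no evaluable test pairs for {atype}; omitted", stacklevel=2)
            continue
        out[atype] = correct / total
    return out
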
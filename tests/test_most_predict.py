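"""Most-similar-ligand prediction: labeling, splits, features, model, filters."""

import numpy as np
import pytest

from focuspharm.chemspace import fingerprint_smiles, tanimoto
from focuspharm.most_predict import (
    BioactivityRecord,
    LabeledPair,
    MostModel,
    evaluate_accuracy,
    extract_features,
    fit_activity_model,
    label_activity,
    predict_targets,
    temporal_split,
    train_models,
    train_most_model,
)
from focuspharm.synthdata import (
    BioactivitySpec,
    generate_bioactivity_dataset,
    generate_feature_table,
)


def rec(lig="l1", smi="CCO", target="T1", atype="pKi", value=7.0, tag="r2013"):
    return BioactivityRecord(lig, smi, target, atype, value, tag)


def pair(lig="l1", smi="CCO", target="T1", atype="pKi", value=7.0, tag="r2013"):
    return LabeledPair(lig, smi, target, atype, value, tag, value >= 6.0)


class TestLabelActivity:
    def test_threshold_boundary_inclusive(self):
        labeled = label_activity([rec(value=6.0), rec(lig="l2", value=5.99)])
        by_id = {p.ligand_id: p.active for p in labeled}
        assert by_id == {"l1": True, "l2": False}

    def test_duplicates_keep_maximum(self):
        labeled = label_activity([rec(value=5.0), rec(value=6.5, tag="r2014")])
        assert len(labeled) == 1
        assert labeled[0].value == 6.5 and labeled[0].active

    def test_empty(self):
        assert label_activity([]) == []

    def test_matches_manual_thresholding(self):
        rng = np.random.default_rng(4)
        records = [rec(lig=f"l{i}", value=float(v))
                   for i, v in enumerate(rng.uniform(3, 9, size=10))]
        labeled = label_activity(records)
        for p, r in zip(sorted(labeled, key=lambda x: x.ligand_id),
                        sorted(records, key=lambda x: x.ligand_id)):
            assert p.active == (r.value >= 6.0)


class TestTemporalSplit:
    def test_partition_by_cutoff(self):
        recs = [rec(lig=f"l{t}", tag=f"r{t}") for t in (2013, 2014, 2015)]
        train, test = temporal_split(recs, "r2014")
        assert {r.release_tag for r in train} == {"r2013", "r2014"}
        assert {r.release_tag for r in test} == {"r2015"}
        assert len(train) + len(test) == len(recs)

    def test_all_at_cutoff_warns_empty_test(self):
        recs = [rec(lig=f"l{i}", tag="r2014") for i in range(3)]
        with pytest.warns(UserWarning, match="empty"):
            train, test = temporal_split(recs, "r2014")
        assert len(train) == 3 and test == []

    def test_sizes_match_manual_count(self):
        rng = np.random.default_rng(9)
        tags = [f"r{2010 + int(t)}" for t in rng.integers(0, 6, size=30)]
        recs = [rec(lig=f"l{i}", tag=t) for i, t in enumerate(tags)]
        train, test = temporal_split(recs, "r2012")
        assert len(train) == sum(1 for t in tags if t <= "r2012")
        assert len(test) == sum(1 for t in tags if t > "r2012")


class TestExtractFeatures:
    def test_identical_query_gives_tc_one(self):
        pairs = [pair(lig="a", smi="c1ccccc1O"), pair(lig="b", smi="CCCCCC")]
        tc, pot, nid = extract_features("Oc1ccccc1", "T1", pairs)
        assert tc == 1.0 and nid == "a"

    def test_single_ligand_target(self):
        pairs = [pair(lig="only", smi="CCCC", value=4.0)]
        tc, pot, nid = extract_features("c1ccccc1", "T1", pairs)
        assert nid == "only" and pot == 4.0

    def test_no_reference_ligands_signalled(self):
        assert extract_features("CCO", "T_missing", [pair()]) is None

    def test_self_exclusion(self):
        pairs = [pair(lig="self", smi="CCO"), pair(lig="other", smi="CCN")]
        tc, pot, nid = extract_features("CCO", "T1", pairs, exclude_ligand_id="self")
        assert nid == "other"

    def test_matches_brute_force_argmax(self):
        smis = ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "CCCO"]
        pairs = [pair(lig=f"l{i}", smi=s, value=5.0 + i) for i, s in enumerate(smis)]
        query = "CCCO"
        tc, pot, nid = extract_features(query, "T1", pairs)
        qfp = fingerprint_smiles(query)
        best = max(pairs, key=lambda p: (tanimoto(qfp, fingerprint_smiles(p.smiles)),
                                         p.value, p.ligand_id))
        assert nid == best.ligand_id
        assert tc == pytest.approx(tanimoto(qfp, fingerprint_smiles(best.smiles)))


class TestTrainModel:
    def test_planted_coefficients_positive(self):
        recs, _ = generate_bioactivity_dataset(BioactivitySpec(seed=3))
        labeled = label_activity(recs)
        models = train_models(labeled)
        for m in models.values():
            assert m.coef_pot > 0  # potency of the nearest ligand drives activity

    def test_coefficient_recovery_from_known_model(self):
        X, y = generate_feature_table(2000, -9.0, 4.0, 1.2, seed=7)
        m = fit_activity_model(X, y, "pKi", l2_penalty=1e-6)
        est = np.array([m.intercept, m.coef_sim, m.coef_pot])
        true = np.array([-9.0, 4.0, 1.2])
        assert np.max(np.abs((est - true) / true)) < 0.15

    def test_separable_data_still_finite(self):
        X = np.column_stack([np.linspace(0, 1, 10), np.linspace(4, 8, 10)])
        y = (np.arange(10) >= 5).astype(int)  # perfectly separable
        m = fit_activity_model(X, y, "pKi")
        assert np.isfinite([m.intercept, m.coef_sim, m.coef_pot]).all()

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).uniform(size=(30, 2))
        with pytest.raises(ValueError, match="single-class"):
            fit_activity_model(X, np.ones(30), "pKi")

    def test_too_few_pairs_rejected(self):
        pairs = [pair(lig=f"l{i}", smi="CCO", value=4.0 + 4 * (i % 2))
                 for i in range(6)]
        with pytest.raises(ValueError, match="at least 20"):
            train_most_model(pairs, "pKi")

    def test_refit_is_bit_for_bit_deterministic(self):
        recs, _ = generate_bioactivity_dataset(BioactivitySpec(seed=5))
        labeled = label_activity(recs)
        m1 = train_most_model(labeled, "pKi")
        m2 = train_most_model(labeled, "pKi")
        assert (m1.intercept, m1.coef_sim, m1.coef_pot) == (m2.intercept, m2.coef_sim, m2.coef_pot)
        assert m1.train_checksum == m2.train_checksum

    def test_json_round_trip(self, tmp_path):
        m = MostModel("pKi", -8.0, 3.0, 1.0, n_train=40)
        m.to_json(tmp_path / "m.json")
        assert MostModel.from_json(tmp_path / "m.json") == m


class TestPredictTargets:
    def test_tc_floor_is_hard(self):
        # a wildly confident model cannot rescue a candidate below the Tc floor
        model = MostModel("pKi", intercept=50.0, coef_sim=0.0, coef_pot=0.0)
        pairs = [pair(lig=f"l{i}", smi="c1ccc2ccccc2c1", value=9.0) for i in range(2)]
        preds = predict_targets("CC(N)CC(=O)O", pairs, {"pKi": model})
        all_preds = predict_targets("CC(N)CC(=O)O", pairs, {"pKi": model}, keep_all=True)
        assert all_preds[0].tc_max < 0.45
        assert all_preds[0].p_value < 0.05
        assert preds == []  # excluded despite tiny p

    def test_identical_strong_active_reported(self):
        recs, _ = generate_bioactivity_dataset(BioactivitySpec(seed=2))
        labeled = label_activity(recs)
        models = train_models(labeled)
        strong = max((p for p in labeled if p.active), key=lambda p: p.value)
        preds = predict_targets(strong.smiles, labeled, models, query_id="probe")
        hit = [p for p in preds if p.target_id == strong.target_id]
        assert hit and hit[0].tc_max == 1.0

    def test_planted_associations_recovered_and_filters_sound(self):
        recs, planted = generate_bioactivity_dataset(BioactivitySpec(seed=11))
        labeled = label_activity(recs)
        train, _ = temporal_split(labeled, "r2014")
        models = train_models(train)
        hits = 0
        for pa in planted:
            preds = predict_targets(pa.smiles, labeled, models, query_id=pa.query_id)
            for p in preds:
                assert p.tc_max >= 0.45 and p.p_value < 0.05
                assert p.p_value + p.prob_active == pytest.approx(1.0, abs=1e-12)
            hits += pa.target_id in {p.target_id for p in preds}
        assert hits / len(planted) >= 0.8

    def test_monotone_in_similarity_for_positive_coefficient(self):
        model = MostModel("pKi", intercept=-8.0, coef_sim=5.0, coef_pot=1.0)
        probs = [model.predict_proba(tc, 6.5) for tc in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_no_models_rejected(self):
        with pytest.raises(ValueError, match="model"):
            predict_targets("CCO", [pair()], {})

    def test_output_sorted_by_p_value(self):
        recs, planted = generate_bioactivity_dataset(
            BioactivitySpec(seed=8, n_planted_queries=1))
        labeled = label_activity(recs)
        models = train_models(labeled)
        preds = predict_targets(planted[0].smiles, labeled, models, keep_all=True)
        ps = [p.p_value for p in preds]
        assert ps == sorted(ps)


class TestEvaluateAccuracy:
    def test_all_correct_is_one(self):
        # model that always says active, test pairs all active
        model = MostModel("pKi", intercept=50.0, coef_sim=0.0, coef_pot=0.0)
        ref = [pair(lig=f"r{i}", smi="CCO", value=8.0) for i in range(3)]
        test = [pair(lig=f"t{i}", smi="CCN", value=7.0) for i in range(4)]
        acc = evaluate_accuracy({"pKi": model}, test, ref)
        assert acc == {"pKi": 1.0}

    def test_matches_hand_confusion_count(self):
        # 8 test pairs scored against one reference ligand; potency-driven model
        model = MostModel("pKi", intercept=-6.0, coef_sim=0.0, coef_pot=1.0)
        ref = [pair(lig="hi", smi="c1ccccc1", value=8.0),
               pair(lig="lo", smi="CCCCC", value=4.0)]
        test = []
        for i, (smi, value) in enumerate([
            ("c1ccccc1C", 9.0), ("c1ccccc1O", 7.0), ("c1ccccc1N", 5.0),
            ("CCCCCC", 8.0), ("CCCCO", 3.0), ("CCCCN", 5.5),
            ("c1ccc(CC)cc1", 6.5), ("CCCC(C)C", 4.5),
        ]):
            test.append(pair(lig=f"q{i}", smi=smi, value=value))
        acc = evaluate_accuracy({"pKi": model}, test, ref)
        # hand count: nearest aromatic queries -> potency 8 -> predicted active;
        # nearest aliphatic queries -> potency 4 -> predicted inactive
        predictions = {"q0": True, "q1": True, "q2": True, "q3": False,
                       "q4": False, "q5": False, "q6": True, "q7": False}
        labels = {"q0": True, "q1": True, "q2": False, "q3": True,
                  "q4": False, "q5": False, "q6": True, "q7": False}
        hand = np.mean([predictions[q] == labels[q] for q in predictions])
        assert acc["pKi"] == pytest.approx(hand)

    def test_missing_type_omitted_with_warning(self):
        model = MostModel("pKi", 0.0, 1.0, 1.0)
        test = [pair(atype="pIC50")]
        with pytest.warns(UserWarning):
            acc = evaluate_accuracy({"pKi": model}, test, [pair(atype="pIC50")])
        assert "pIC50" not in acc or acc == {}


class TestTemporalHygiene:
    def test_test_records_do_not_influence_training(self):
        recs, _ = generate_bioactivity_dataset(BioactivitySpec(seed=6))
        labeled = label_activity(recs)
        train, test = temporal_split(labeled, "r2014")
        m_full = train_most_model(train, "pKi")
        # perturb every held-out record heavily; training must be unchanged
        perturbed = train + [
            LabeledPair(p.ligand_id, p.smiles, p.target_id, p.activity_type,
                        p.value + 100, p.release_tag, p.active)
            for p in test
        ]
        train2, _ = temporal_split(perturbed, "r2014")
        m_again = train_most_model(train2, "pKi")
        assert m_full.train_checksum == m_again.train_checksum
        assert m_full.intercept == m_again.intercept
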
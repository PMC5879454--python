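"""Fingerprints, Tanimoto similarity, clustering, groups, representatives, PCA."""

import numpy as np
import pytest

from focuspharm.chemspace import (
    FingerprintSet,
    compute_fingerprints,
    detect_component_groups,
    fingerprint_smiles,
    hierarchical_cluster,
    pca_projection,
    select_representative,
    tanimoto,
    tanimoto_matrix,
)
from focuspharm.synthdata import LibrarySpec, generate_compound_library

from conftest import make_record


def _fpset(bit_lists, n_bits=16):
    bits = np.zeros((len(bit_lists), n_bits), dtype=np.uint8)
    for i, on in enumerate(bit_lists):
        bits[i, list(on)] = 1
    return FingerprintSet(
        compound_ids=tuple(f"c{i}" for i in range(len(bit_lists))),
        bits=bits, radius=2, n_bits=n_bits,
    )


class TestFingerprints:
    def test_identical_smiles_identical_vectors(self):
        recs = [make_record("a", smiles="OCC"), make_record("b", smiles="CCO")]
        fps = compute_fingerprints(recs)
        assert np.array_equal(fps.bits[0], fps.bits[1])

    def test_ethane_environment_count(self):
        # hand enumeration for CC: one distinct atom type at radius 0 (both
        # carbons equivalent), one distinct bond environment at radius 1 (the
        # C-C bond, identical from either end), nothing new at radius 2
        assert int(fingerprint_smiles("CC").sum()) == 2

    def test_default_radius_is_two(self):
        recs = [make_record("a", smiles="CCO")]
        assert compute_fingerprints(recs).radius == 2

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError, match="SMILES"):
            fingerprint_smiles("xyz(")


class TestTanimoto:
    def test_identity(self):
        sim = tanimoto_matrix(_fpset([{1, 2, 3}, {1, 2, 3}]))
        assert sim.values[0, 1] == 1.0

    def test_disjoint(self):
        sim = tanimoto_matrix(_fpset([{1, 2}, {3, 4}]))
        assert sim.values[0, 1] == 0.0

    def test_popcount_arithmetic(self):
        sim = tanimoto_matrix(_fpset([{1, 2, 3}, {2, 3, 4}]))
        assert sim.values[0, 1] == pytest.approx(0.5)  # |{2,3}| / |{1,2,3,4}|

    def test_all_zero_vectors_defined_as_one(self):
        sim = tanimoto_matrix(_fpset([set(), set()]))
        assert sim.values[0, 1] == 1.0

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        bits = (rng.uniform(size=(50, 64)) < 0.3).astype(np.uint8)
        fps = FingerprintSet(tuple(f"c{i}" for i in range(50)), bits, 2, 64)
        fast = tanimoto_matrix(fps).values
        for i in range(50):
            for j in range(50):
                a, b = bits[i].astype(bool), bits[j].astype(bool)
                union = int((a | b).sum())
                expected = 1.0 if union == 0 else int((a & b).sum()) / union
                assert fast[i, j] == pytest.approx(expected, abs=0), (i, j)


def _naive_average_linkage(dist):
    """Independent oracle: textbook agglomeration with pairwise-average update."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def test_two_compounds_merge_at_one_minus_tc(self):
        sim = tanimoto_matrix(_fpset([{1, 2, 3, 4, 5, 6, 7}, {1, 2, 3}]))
        tc = sim.values[0, 1]
        tree = hierarchical_cluster(sim)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(1 - tc)

    def test_matches_manual_average_linkage(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 0.9, size=(4, 4))
        sim = np.clip((vals + vals.T) / 2, 0, 1)
        np.fill_diagonal(sim, 1.0)
        from focuspharm.chemspace import SimilarityMatrix
        tree = hierarchical_cluster(SimilarityMatrix(("a", "b", "c", "d"), sim))
        oracle = _naive_average_linkage(1 - sim)
        for k, (a, b, d, size) in enumerate(oracle):
            assert {int(tree.merges[k, 0]), int(tree.merges[k, 1])} == {a, b}
            assert tree.merges[k, 2] == pytest.approx(d)
            assert int(tree.merges[k, 3]) == size

    def test_leaf_relabeling_gives_same_tree_shape(self, mzrw_members):
        fps = compute_fingerprints(mzrw_members)
        sim = tanimoto_matrix(fps)
        tree1 = hierarchical_cluster(sim)
        perm = np.random.default_rng(0).permutation(len(mzrw_members))
        from focuspharm.chemspace import SimilarityMatrix
        sim2 = SimilarityMatrix(
            tuple(sim.compound_ids[i] for i in perm), sim.values[np.ix_(perm, perm)])
        tree2 = hierarchical_cluster(sim2)
        # identical multiset of merge heights = same tree up to label permutation
        assert np.allclose(np.sort(tree1.merges[:, 2]), np.sort(tree2.merges[:, 2]))

    def test_nan_rejected(self):
        from focuspharm.chemspace import SimilarityMatrix
        sim = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        sim.values[0, 1] = np.nan
        sim.values[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_cluster(sim)


class TestComponentGroups:
    def test_mzrw_five_groups_with_expected_herbs(self, mzrw_members):
        fps = compute_fingerprints(mzrw_members)
        tree = hierarchical_cluster(tanimoto_matrix(fps))
        res = detect_component_groups(tree, mzrw_members, cut_height=0.6)
        assert len(res.groups) == 5
        assert {g.dominant_herb for g in res.groups} == {"DH", "KXR", "BS", "HP", "ZS"}

    def test_identical_structures_one_pure_group(self):
        recs = [make_record(f"c{i}", smiles="CCO", herb="DH") for i in range(4)]
        fps = compute_fingerprints(recs)
        tree = hierarchical_cluster(tanimoto_matrix(fps))
        res = detect_component_groups(tree, recs, cut_height=0.6)
        assert len(res.groups) == 1
        assert res.groups[0].purity == 1.0
        assert set(res.groups[0].members) == {f"c{i}" for i in range(4)}

    def test_planted_families_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        recs, labels = generate_compound_library(LibrarySpec(seed=42))
        fps = compute_fingerprints(recs)
        tree = hierarchical_cluster(tanimoto_matrix(fps))
        res = detect_component_groups(tree, recs, cut_height=0.6)
        assigned = {m: g.group_id for g in res.groups for m in g.members}
        ids = [r.compound_id for r in recs]
        assert not res.unassigned
        ari = adjusted_rand_score([labels[i] for i in ids], [assigned[i] for i in ids])
        assert ari == pytest.approx(1.0)

    def test_groups_disjoint_and_meet_criteria(self, mzrw):
        fps = compute_fingerprints(mzrw.compounds)
        tree = hierarchical_cluster(tanimoto_matrix(fps))
        res = detect_component_groups(tree, mzrw.compounds, cut_height=0.6,
                                      min_size=2, purity_min=0.5)
        seen = set()
        for g in res.groups:
            assert len(g.members) >= 2
            assert g.purity > 0.5
            assert not (set(g.members) & seen)
            seen |= set(g.members)

    def test_determinism(self, mzrw_members):
        def run():
            fps = compute_fingerprints(mzrw_members)
            tree = hierarchical_cluster(tanimoto_matrix(fps))
            return detect_component_groups(tree, mzrw_members, cut_height=0.6)
        assert run() == run()

    def test_cut_height_range_checked(self, mzrw_members):
        fps = compute_fingerprints(mzrw_members)
        tree = hierarchical_cluster(tanimoto_matrix(fps))
        with pytest.raises(ValueError, match="cut_height"):
            detect_component_groups(tree, mzrw_members, cut_height=1.5)


class TestSelectRepresentative:
    def test_mzrw_representatives(self, mzrw, mzrw_members):
        fps = compute_fingerprints(mzrw_members)
        tree = hierarchical_cluster(tanimoto_matrix(fps))
        res = detect_component_groups(tree, mzrw_members, cut_height=0.6)
        reps = {g.dominant_herb: select_representative(g, mzrw_members)
                for g in res.groups}
        assert reps == {"DH": "emodin", "KXR": "amygdalin", "BS": "albiflorin",
                        "HP": "honokiol", "ZS": "naringin"}

    def test_singleton_group(self):
        from focuspharm.chemspace import ComponentGroup
        g = ComponentGroup("G1", ("only",), "DH", 1.0)
        assert select_representative(g, [make_record("only")]) == "only"

    def test_tie_breaks_by_compound_id(self):
        from focuspharm.chemspace import ComponentGroup
        recs = [make_record("b2", plasma=True, rank=1, available=True, pharm=True),
                make_record("a1", plasma=True, rank=1, available=True, pharm=True)]
        g = ComponentGroup("G1", ("a1", "b2"), "DH", 1.0)
        assert select_representative(g, recs) == "a1"

    def test_biological_detection_outranks_abundance(self):
        from focuspharm.chemspace import ComponentGroup
        recs = [make_record("abundant", plasma=False, rank=1),
                make_record("detected", plasma=True, rank=9)]
        g = ComponentGroup("G1", ("abundant", "detected"), "DH", 1.0)
        assert select_representative(g, recs) == "detected"


class TestPCA:
    def test_identical_compounds_identical_coordinates(self):
        recs = [make_record(f"c{i}", smiles="CCO") for i in range(3)]
        coords = pca_projection(compute_fingerprints(recs))
        assert np.allclose(coords[0], coords[1])
        assert np.allclose(coords[0], coords[2])

    def test_component_variances_non_increasing(self):
        rng = np.random.default_rng(12)
        bits = (rng.uniform(size=(30, 128)) < 0.2).astype(np.uint8)
        fps = FingerprintSet(tuple(f"c{i}" for i in range(30)), bits, 2, 128)
        coords = pca_projection(fps, n_components=3)
        var = coords.var(axis=0)
        assert var[0] >= var[1] >= var[2]

    def test_projected_coordinates_centered(self, mzrw_members):
        coords = pca_projection(compute_fingerprints(mzrw_members))
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_too_many_components_rejected(self):
        recs = [make_record(f"c{i}", smiles="CCO") for i in range(3)]
        with pytest.raises(ValueError, match="n_components"):
            pca_projection(compute_fingerprints(recs), n_components=5)
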
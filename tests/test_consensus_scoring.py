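import numpy as np
import pandas as pd
import pytest

import modefit.consensus_scoring as cs
from modefit.structure_io import Structure

from conftest import single_atom_structure


def make_pool(coord_sets, scores=None, features=None):
    poses = []
    for k, xyz in enumerate(coord_sets):
        f = dict(features[k]) if features else {}
        if scores is not None:
            f["shape_score"] = scores[k]
        poses.append(cs.ScoredPose(pose_id=f"p{k}", coords=np.asarray(xyz, float),
                                   features=f))
    return cs.PosePool(poses=poses)


# ---------------------------------------------------------------------------
# truncation and clustering


def test_truncate_keeps_top_scores_stable_order():
    pool = make_pool([np.zeros((1, 3))] * 5, scores=[1, 2, 3, 4, 5])
    out = cs.truncate_by_shape(pool, 3)
    assert [p.features["shape_score"] for p in out.poses] == [3, 4, 5]
    # small pool unchanged
    assert len(cs.truncate_by_shape(pool, 50000).poses) == 5


def test_truncate_boundary_tie_keeps_earlier_pose():
    pool = make_pool([np.zeros((1, 3))] * 4, scores=[5, 3, 3, 1])
    out = cs.truncate_by_shape(pool, 2)
    assert [p.pose_id for p in out.poses] == ["p0", "p1"]


def test_truncate_missing_score_raises():
    pool = make_pool([np.zeros((1, 3))])
    with pytest.raises(cs.ScoringError, match="shape_score"):
        cs.truncate_by_shape(pool, 1)


def greedy_reference(coord_sets, cutoff):
    """Independent re-statement of the greedy rule used for the oracle."""
    reps, assign = [], []
    for xyz in coord_sets:
        for ci, rep in enumerate(reps):
            if np.sqrt(np.mean(np.sum((xyz - rep) ** 2, axis=1))) <= cutoff:
                assign.append(ci)
                break
        else:
            reps.append(xyz)
            assign.append(len(reps) - 1)
    return assign


def test_cluster_identical_poses_single_cluster():
    pool = make_pool([np.zeros((2, 3))] * 6, scores=[0] * 6)
    clusters = cs.cluster_poses(pool)
    assert len(clusters) == 1 and clusters[0].size == 6


def test_cluster_distant_poses_all_singletons():
    pool = make_pool([np.full((2, 3), 10.0 * k) for k in range(5)], scores=[0] * 5)
    clusters = cs.cluster_poses(pool)
    assert len(clusters) == 5
    assert all(c.size == 1 for c in clusters)


def test_cluster_matches_greedy_oracle(rng):
    coord_sets = [rng.normal(scale=3.0, size=(4, 3)) for _ in range(20)]
    pool = make_pool(coord_sets, scores=[0] * 20)
    clusters = cs.cluster_poses(pool, cutoff=4.0)
    expected = greedy_reference(coord_sets, 4.0)
    got = []
    index_of = {id(c.representative): i for i, c in enumerate(clusters)}
    for p in pool.poses:
        for ci, c in enumerate(clusters):
            if any(m is p for m in c.members):
                got.append(ci)
    assert got == expected
    # partition property: every pose in exactly one cluster
    assert sum(c.size for c in clusters) == 20
    # representatives pairwise beyond cutoff
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            assert cs.pose_rmsd(a.representative, b.representative) > 4.0


def test_cluster_atom_mismatch_raises():
    pool = cs.PosePool(poses=[
        cs.ScoredPose("a", np.zeros((2, 3))),
        cs.ScoredPose("b", np.zeros((3, 3))),
    ])
    with pytest.raises(cs.ScoringError, match="different atom sets"):
        cs.cluster_poses(pool)


# ---------------------------------------------------------------------------
# occupancies and BSC terms


@pytest.fixture()
def bsc_toy():
    """Receptor of 3 single-atom residues on a line; poses are 2-atom ligands
    (2 residues) at controlled distances."""
    receptor = single_atom_structure("R", [[0.0, 0, 0], [8.0, 0, 0], [16.0, 0, 0]])
    # pose atoms: atom0 → ligand residue 0, atom1 → ligand residue 1
    lig_res_idx = np.array([0, 1])
    pose1 = [[3.0, 0, 0], [11.0, 0, 0]]   # near residues R1,R2 / R2,R3
    pose2 = [[3.0, 0, 0], [100.0, 0, 0]]  # atom1 far away
    pose3 = [[200.0, 0, 0], [300.0, 0, 0]]  # nothing interacts
    pool = make_pool([pose1, pose2, pose3], scores=[3, 2, 1])
    return receptor, lig_res_idx, pool


def test_occupancies_match_bruteforce(bsc_toy):
    receptor, lig_res_idx, pool = bsc_toy
    occ = cs.occupancies(pool, receptor, lig_res_idx)
    # brute force double loop
    rec_xyz = receptor.coords()
    for c in cs.BSC_CUTOFFS:
        rec_expect = np.zeros(3, dtype=int)
        lig_expect = np.zeros(2, dtype=int)
        for pose in pool.poses:
            rhit, lhit = set(), set()
            for li, lx in enumerate(pose.coords):
                for ri, rx in enumerate(rec_xyz):
                    if np.linalg.norm(lx - rx) <= c:
                        rhit.add(ri)
                        lhit.add(int(lig_res_idx[li]))
            for r in rhit:
                rec_expect[r] += 1
            for l in lhit:
                lig_expect[l] += 1
        np.testing.assert_array_equal(occ.receptor[c], rec_expect)
        np.testing.assert_array_equal(occ.ligand[c], lig_expect)


def test_occupancy_identical_interacting_poses(bsc_toy):
    receptor, lig_res_idx, _ = bsc_toy
    pose = [[3.0, 0, 0], [11.0, 0, 0]]
    pool = make_pool([pose] * 4, scores=[0] * 4)
    occ = cs.occupancies(pool, receptor, lig_res_idx)
    assert set(occ.receptor[5.0]) <= {0, 4}
    np.testing.assert_array_equal(occ.receptor[5.0], [4, 4, 4])
    np.testing.assert_array_equal(occ.ligand[5.0], [4, 4])


def test_bsc_terms_hand_enumerated(bsc_toy):
    """All six BSC values of pose 1 equal the hand-computed sums."""
    receptor, lig_res_idx, pool = bsc_toy
    occ = cs.occupancies(pool, receptor, lig_res_idx)
    terms = cs.bsc_terms(pool.poses[0], receptor, lig_res_idx, occ)
    # at 5 Å (inclusive): pose1 atoms at 3/11 touch R@0 (d=3), R@8 (d=5 and
    # d=3), R@16 (d=5); pose2 atom at 3 touches R@0, R@8; pose3 nothing.
    # → receptor occupancies [2, 2, 1], ligand occupancies [2, 1].
    # pose1 interacts with all three receptor and both ligand residues:
    assert terms["bsc_receptor_5"] == 2 + 2 + 1
    assert terms["bsc_ligand_5"] == 2 + 1
    assert terms["bsc_both_5"] == terms["bsc_receptor_5"] + terms["bsc_ligand_5"]
    # at 10 Å the sets happen to be identical (11→0 is 11, 3→16 is 13)
    assert terms["bsc_receptor_10"] == 2 + 2 + 1
    assert terms["bsc_ligand_10"] == 2 + 1
    assert terms["bsc_both_10"] == terms["bsc_receptor_10"] + terms["bsc_ligand_10"]


def test_bsc_zero_for_noninteracting_model(bsc_toy):
    receptor, lig_res_idx, pool = bsc_toy
    occ = cs.occupancies(pool, receptor, lig_res_idx)
    terms = cs.bsc_terms(pool.poses[2], receptor, lig_res_idx, occ)
    assert all(v == 0.0 for v in terms.values())


def test_bsc_both_additivity_on_random_pools(rng):
    receptor = single_atom_structure("R", rng.uniform(0, 20, size=(5, 3)))
    pool = make_pool([rng.uniform(0, 20, size=(4, 3)) for _ in range(6)],
                     scores=range(6))
    idx = np.array([0, 0, 1, 1])
    occ = cs.occupancies(pool, receptor, idx)
    for pose in pool.poses:
        t = cs.bsc_terms(pose, receptor, idx, occ)
        for c in cs.BSC_CUTOFFS:
            assert t[f"bsc_both_{c:g}"] == t[f"bsc_receptor_{c:g}"] + t[f"bsc_ligand_{c:g}"]


# ---------------------------------------------------------------------------
# standardization / order stats / logistic combination


def test_zscores_identical_poses_all_zero():
    df = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 1.0, 1.0]})
    z = cs.standardize_and_order_stats(df)
    assert (z[["a", "b", "z1", "z2", "z3"]] == 0.0).all().all()


def test_zscore_two_pose_population_sd():
    """Values 0 and 2 standardize to ∓1 with the population sd."""
    df = pd.DataFrame({"a": [0.0, 2.0]})
    z = cs.standardize_and_order_stats(df)
    assert z["a"].tolist() == [-1.0, 1.0]


def test_order_stats_sorted(rng):
    df = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
    z = cs.standardize_and_order_stats(df)
    assert (z["z1"] <= z["z2"]).all() and (z["z2"] <= z["z3"]).all()
    # z1..z3 are exactly the three smallest standardized entries per row
    raw = cs.standardize(df).to_numpy()
    np.testing.assert_allclose(np.sort(raw, axis=1)[:, :3],
                               z[["z1", "z2", "z3"]].to_numpy(), atol=1e-12)


def test_order_stats_singleton_pool_raises():
    with pytest.raises(cs.ScoringError, match="at least 2"):
        cs.standardize_and_order_stats(pd.DataFrame({"a": [1.0]}))


def test_combined_score_closed_form(rng):
    names = ("a", "b", "c")
    w = rng.normal(size=3)
    model = cs.ScoringModel(feature_names=names, weights=w, intercept=0.3)
    feats = dict(zip(names, rng.normal(size=3)))
    expected = 1.0 / (1.0 + np.exp(-(0.3 + sum(w[i] * feats[n] for i, n in enumerate(names)))))
    assert cs.combined_score(feats, model) == pytest.approx(expected, abs=1e-12)


def test_combined_score_zero_weights_is_half():
    model = cs.ScoringModel(("a",), np.zeros(1), 0.0)
    assert cs.combined_score({"a": 123.0}, model) == 0.5


def test_combined_score_monotone_in_positive_weight():
    model = cs.ScoringModel(("a",), np.array([2.0]), 0.0)
    assert cs.combined_score({"a": 1.0}, model) > cs.combined_score({"a": 0.0}, model)


def test_combined_score_manifest_mismatch():
    model = cs.ScoringModel(("a", "missing"), np.ones(2), 0.0)
    with pytest.raises(cs.ScoringError, match="manifest"):
        cs.combined_score({"a": 1.0}, model)


def test_score_invariant_to_raw_feature_rescaling(rng):
    feats = [{"a": float(v), "b": float(w)} for v, w in rng.normal(size=(8, 2))]
    pool1 = make_pool([np.zeros((1, 3))] * 8, scores=rng.normal(size=8), features=feats)
    pool2 = make_pool([np.zeros((1, 3))] * 8,
                      scores=[p.features["shape_score"] for p in pool1.poses],
                      features=[{"a": f["a"] * 10.0, "b": f["b"]} for f in feats])
    model = cs.ScoringModel(("shape_score", "a", "b", "z1", "z2", "z3"),
                            rng.normal(size=6), 0.1)
    s1 = cs.score_pool(pool1, model)["combined"]
    s2 = cs.score_pool(pool2, model)["combined"]
    np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)


def test_model_save_load_roundtrip(tmp_path):
    model = cs.ScoringModel(("a", "b"), np.array([0.5, -1.5]), 0.25)
    model.save(tmp_path / "w.yaml")
    back = cs.ScoringModel.load(tmp_path / "w.yaml")
    assert back.feature_names == model.feature_names
    np.testing.assert_allclose(back.weights, model.weights)
    assert back.intercept == model.intercept


# ---------------------------------------------------------------------------
# training


def test_train_separable_features_perfect_training_auc(rng):
    X = pd.DataFrame({"f": np.r_[rng.normal(-2, 0.3, 20), rng.normal(2, 0.3, 20)]})
    y = np.r_[np.zeros(20), np.ones(20)]
    model = cs.train_weights(X, y)
    scores = [cs.combined_score({"f": v}, model) for v in X["f"]]
    assert min(scores[20:]) > max(scores[:20])  # AUC = 1 on training pool


def test_train_null_labels_shrink_weights(rng):
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    y = rng.integers(0, 2, size=60)
    model = cs.train_weights(X, y, l2_strength=50.0)
    assert np.max(np.abs(model.weights)) < 0.5


def test_train_permutation_invariance(rng):
    X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
    y = (X["a"] + rng.normal(scale=0.1, size=30) > 0).astype(int)
    m1 = cs.train_weights(X, y)
    perm = rng.permutation(30)
    m2 = cs.train_weights(X.iloc[perm], y.to_numpy()[perm])
    np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-6)
    assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)


def test_train_single_class_raises():
    X = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(cs.ScoringError, match="single class"):
        cs.train_weights(X, [1, 1])


# ---------------------------------------------------------------------------
# selection and carry-over


def test_select_top_matches_sort_oracle(rng):
    scores = rng.normal(size=12)
    pool = make_pool([np.zeros((1, 3))] * 12, scores=scores)
    for p in pool.poses:
        p.features["combined"] = p.features["shape_score"]
    out = cs.select_top(pool, 4)
    expected = sorted(range(12), key=lambda i: (-scores[i], i))[:4]
    assert [p.pose_id for p in out.poses] == [f"p{i}" for i in sorted(expected)]
    assert len(cs.select_top(pool, 100).poses) == 12
    best = cs.select_top(pool, 1).poses[0]
    assert best.features["combined"] == max(scores)


def test_carry_over_bsc_combiners():
    a = {f"bsc_{s}_{c:g}": 2.0 for s in cs.BSC_SIDES for c in cs.BSC_CUTOFFS}
    b = {f"bsc_{s}_{c:g}": 6.0 for s in cs.BSC_SIDES for c in cs.BSC_CUTOFFS}
    assert set(cs.carry_over_bsc(a, b, "mean").values()) == {4.0}
    assert set(cs.carry_over_bsc(a, b, "sum").values()) == {8.0}
    assert set(cs.carry_over_bsc(a, b, "max").values()) == {6.0}
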
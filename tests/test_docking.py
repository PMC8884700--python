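import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from sklearn.cluster import DBSCAN
from sklearn.metrics import adjusted_rand_score

from vhhforge.annotation import AntibodyAnnotation
from vhhforge.docking import (ComplexPose, DistanceMatrix, DomainDefinition,
                              dbscan_precomputed, embed_2d, filter_poses,
                              interacting_residues, irmsd_matrix,
                              summarize_clusters)
from vhhforge.structure import RigidTransform, StructureModel


def grid_pose(ab_z, pose_id="p", n_res=20, spacing=5.0):
    """Antigen chain A: CA-only residues along x at z=0 (plus flanking N/C so
    Kabsch sets are non-degenerate); antibody chain B residue i sits at height
    ab_z[i] above antigen residue i, so each pair distance is exact."""
    atoms = []
    for i in range(n_res):
        x = i * spacing
        y = 1.0 if i % 2 else -1.0
        atoms.append(("A", i + 1, "", "GLY", "CA", "C", (x, y, 0.0)))
    for i, z in enumerate(ab_z):
        x = i * spacing
        y = 1.0 if i % 2 else -1.0
        atoms.append(("B", i + 1, "", "GLY", "CA", "C", (x, y, float(z))))
    return ComplexPose(pose_id, StructureModel.from_atoms(atoms), "B", "A")


def full_span_annotation(n_res=20):
    # spans covering residues 0..n-1 in three blocks => every antibody residue is CDR
    third = n_res // 3
    return AntibodyAnnotation("A" * n_res, (0, third), (third, 2 * third),
                              (2 * third, n_res), source="manual")


DOMAINS = DomainDefinition([("domain1", 1, 10), ("domain2", 11, 20)])


def brute_force_summary(pose, annotation, domains, cutoff=4.0):
    """Independent all-atom-pair double loop oracle."""
    m = pose.model
    ab_idx = [i for i in range(m.n_atoms) if m.chains[i] == pose.antibody_chain]
    ag_idx = [i for i in range(m.n_atoms) if m.chains[i] == pose.antigen_chain]
    ab_hit, ag_hit = set(), set()
    for i in ab_idx:
        for j in ag_idx:
            if np.linalg.norm(m.xyz[i] - m.xyz[j]) < cutoff:
                ab_hit.add(int(m.resnums[i]))
                ag_hit.add(int(m.resnums[j]))
    order = [rn for _, rn, _, _, _ in m.residues(pose.antibody_chain)]
    cdr = {order[i] for i in annotation.cdr_index_set()}
    return ab_hit, ab_hit & cdr, ag_hit


class TestInteractingResidues:
    def test_strict_cutoff_399_400(self):
        pose = grid_pose([3.99, 4.00, 4.01] + [50.0] * 17)
        s = interacting_residues(pose, full_span_annotation(), DOMAINS)
        assert s.antibody_residues == frozenset({1})
        assert s.antigen_residues == frozenset({1})

    def test_far_pose_class_none(self):
        pose = grid_pose([100.0] * 20)
        s = interacting_residues(pose, full_span_annotation(), DOMAINS)
        assert s.antibody_residues == frozenset()
        assert s.domain_class == "none"

    def test_exactly_12_cdr_residues(self):
        z = [3.5 if i < 12 else 50.0 for i in range(20)]
        pose = grid_pose(z)
        s = interacting_residues(pose, full_span_annotation(), DOMAINS)
        brute_ab, brute_cdr, brute_ag = brute_force_summary(
            pose, full_span_annotation(), DOMAINS)
        assert len(s.cdr_residues) == 12
        assert s.cdr_residues == frozenset(brute_cdr)

    def test_matches_brute_force_on_random_poses(self):
        rng = np.random.default_rng(17)
        ann = full_span_annotation()
        for k in range(20):
            z = rng.uniform(2.5, 6.0, size=20)
            pose = grid_pose(z, pose_id=f"p{k}")
            s = interacting_residues(pose, ann, DOMAINS)
            brute_ab, brute_cdr, brute_ag = brute_force_summary(pose, ann, DOMAINS)
            assert s.antibody_residues == frozenset(brute_ab)
            assert s.cdr_residues == frozenset(brute_cdr)
            assert s.antigen_residues == frozenset(brute_ag)

    def test_contact_symmetry(self):
        rng = np.random.default_rng(18)
        pose = grid_pose(rng.uniform(3.0, 5.0, size=20))
        s = interacting_residues(pose, full_span_annotation(), DOMAINS)
        # each interacting antibody residue has a partner antigen residue
        assert bool(s.antibody_residues) == bool(s.antigen_residues)

    def test_domain_counts_and_class(self):
        # contacts only over antigen residues 1-10 -> class "first"
        z = [3.0] * 10 + [50.0] * 10
        s = interacting_residues(grid_pose(z), full_span_annotation(), DOMAINS)
        assert s.domain_counts == {"domain1": 10, "domain2": 0}
        assert s.domain_class == "first"
        z = [50.0] * 10 + [3.0] * 10
        s = interacting_residues(grid_pose(z), full_span_annotation(), DOMAINS)
        assert s.domain_class == "second"
        s = interacting_residues(grid_pose([3.0] * 20), full_span_annotation(), DOMAINS)
        assert s.domain_class == "both"

    def test_annotation_too_long_raises(self):
        pose = grid_pose([3.0] * 20)
        ann = AntibodyAnnotation("A" * 40, (0, 10), (15, 25), (30, 40),
                                 source="manual")
        with pytest.raises(ValueError, match="exceed"):
            interacting_residues(pose, ann, DOMAINS)


class TestFilterPoses:
    @staticmethod
    def summary_with_n_cdr(n, pose_id="p"):
        z = [3.0 if i < n else 50.0 for i in range(20)]
        return interacting_residues(grid_pose(z, pose_id), full_span_annotation(),
                                    DOMAINS)

    def test_nine_dropped_ten_kept(self):
        s9 = self.summary_with_n_cdr(9, "nine")
        s10 = self.summary_with_n_cdr(10, "ten")
        assert s9.n_cdr == 9 and s10.n_cdr == 10
        kept, report = filter_poses([s9, s10])
        assert kept == ["ten"]
        assert report == {"input": 2, "stage1_dropped": 0,
                          "stage2_dropped": 1, "kept": 1}

    def test_zero_contact_dropped_at_stage1(self):
        s0 = self.summary_with_n_cdr(0, "zero")
        kept, report = filter_poses([s0], min_cdr_contacts=0)
        assert kept == []
        assert report["stage1_dropped"] == 1

    def test_threshold_zero_keeps_stage1_survivors(self):
        summaries = [self.summary_with_n_cdr(n, f"p{n}") for n in (0, 1, 5, 15)]
        kept, _ = filter_poses(summaries, min_cdr_contacts=0)
        assert kept == ["p1", "p5", "p15"]

    def test_monotone_in_threshold(self):
        summaries = [self.summary_with_n_cdr(n, f"p{n}") for n in range(0, 20, 3)]
        prev = None
        for thr in range(0, 15):
            kept, _ = filter_poses(summaries, min_cdr_contacts=thr)
            if prev is not None:
                assert set(kept) <= set(prev)
            prev = kept


class TestIrmsdMatrix:
    def test_identical_poses_zero(self):
        poses = [grid_pose([4.0] * 20, f"p{i}") for i in range(3)]
        mat = irmsd_matrix(poses, full_span_annotation())
        assert np.allclose(mat.values, 0.0, atol=1e-12)

    def test_global_rigid_transform_invariance(self):
        rng = np.random.default_rng(23)
        base = grid_pose(rng.uniform(3, 8, size=20), "a")
        other = grid_pose(rng.uniform(3, 8, size=20), "b")
        mat0 = irmsd_matrix([base, other], full_span_annotation())
        rot = Rotation.random(random_state=rng).as_matrix()
        transform = RigidTransform(rot, rng.normal(size=3) * 20)
        moved = ComplexPose("b", other.model.transformed(transform), "B", "A")
        mat1 = irmsd_matrix([base, moved], full_span_annotation())
        assert np.abs(mat0.values - mat1.values).max() <= 1e-6

    def test_pure_antibody_translation_exact(self):
        base = grid_pose([4.0] * 20, "a")
        moved_model = base.model.copy()
        mask = moved_model.chain_mask("B")
        moved_model.xyz[mask] += np.array([0.0, 0.0, 10.0])
        moved = ComplexPose("b", moved_model, "B", "A")
        mat = irmsd_matrix([base, moved], full_span_annotation())
        assert mat.values[0, 1] == pytest.approx(10.0, abs=1e-9)

    def test_symmetry_and_zero_diag(self):
        rng = np.random.default_rng(24)
        poses = [grid_pose(rng.uniform(3, 9, size=20), f"p{i}") for i in range(5)]
        mat = irmsd_matrix(poses, full_span_annotation())
        assert np.abs(mat.values - mat.values.T).max() <= 1e-6
        assert np.abs(np.diag(mat.values)).max() == 0.0

    def test_missing_ca_raises(self):
        pose = grid_pose([4.0] * 20, "a")
        atoms = [("A", i + 1, "", "GLY", "CA", "C", (i * 5.0, i % 2, 0.0))
                 for i in range(20)]
        atoms += [("B", i + 1, "", "GLY", "CB" if i == 3 else "CA", "C",
                   (i * 5.0, i % 2, 4.0)) for i in range(20)]
        bad = ComplexPose("b", StructureModel.from_atoms(atoms), "B", "A")
        with pytest.raises(ValueError, match="missing CA"):
            irmsd_matrix([pose, bad], full_span_annotation())


def matrix_from_points(points, ids=None):
    d = cdist(points, points)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    ids = ids or [f"m{i}" for i in range(len(points))]
    return DistanceMatrix(ids, d)


class TestDbscan:
    def test_all_zero_distance_one_cluster(self):
        mat = DistanceMatrix([f"p{i}" for i in range(5)], np.zeros((5, 5)))
        res = dbscan_precomputed(mat)
        assert set(res.labels) == {0}
        assert set(res.status) == {"core"}

    def test_two_groups_plus_outlier(self):
        pts = ([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]]
               + [[100, 0, 0], [101, 0, 0], [100, 1, 0], [100.5, 0.5, 0]]
               + [[500, 500, 0]])
        res = dbscan_precomputed(matrix_from_points(np.array(pts, dtype=float)),
                                 eps=9.0, min_samples=3)
        assert res.n_clusters == 2
        assert list(res.labels[:4]) == [0] * 4
        assert list(res.labels[4:8]) == [1] * 4 or list(res.labels[4:8]) == [0] * 4
        assert res.labels[8] == -1
        assert res.status[8] == "outlier"

    def test_labels_sorted_by_size(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0],
               [100, 0, 0], [101, 0, 0], [100, 1, 0], [100, 0, 1], [101, 1, 0]]
        res = dbscan_precomputed(matrix_from_points(np.array(pts, dtype=float)),
                                 eps=5.0, min_samples=3)
        # bigger group gets label 0
        assert list(res.labels) == [1, 1, 1, 0, 0, 0, 0, 0]

    def test_every_cluster_has_a_core(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 50, size=(40, 3))
        res = dbscan_precomputed(matrix_from_points(pts), eps=8.0, min_samples=3)
        for c in range(res.n_clusters):
            assert any(st == "core" for st, l in zip(res.status, res.labels) if l == c)

    def test_matches_sklearn_on_tie_free_matrices(self):
        rng = np.random.default_rng(77)
        checked = 0
        attempts = 0
        while checked < 50 and attempts < 400:
            attempts += 1
            n = int(rng.integers(15, 45))
            pts = rng.uniform(0, 30, size=(n, 5))
            d = cdist(pts, pts)
            np.fill_diagonal(d, 0.0)
            eps = float(np.quantile(d[np.triu_indices(n, 1)], 0.15))
            if eps <= 0:
                continue
            mat = DistanceMatrix(list(map(str, range(n))), d)
            ours = dbscan_precomputed(mat, eps=eps, min_samples=3)
            # exclude border ties: non-core point adjacent to cores of 2 clusters
            within = d <= eps
            core = within.sum(axis=1) >= 3
            tie = False
            for i in range(n):
                if core[i]:
                    continue
                nbr = {int(ours.labels[j]) for j in np.nonzero(within[i] & core)[0]}
                if len(nbr) > 1:
                    tie = True
                    break
            if tie:
                continue
            ref = DBSCAN(eps=eps, min_samples=3, metric="precomputed").fit(d)
            assert set(np.nonzero(ours.labels == -1)[0]) == \
                set(np.nonzero(ref.labels_ == -1)[0])
            mask = ours.labels >= 0
            if mask.sum() > 0:
                assert adjusted_rand_score(ours.labels[mask], ref.labels_[mask]) == 1.0
            checked += 1
        assert checked == 50

    def test_default_parameters(self):
        import inspect
        sig = inspect.signature(dbscan_precomputed)
        assert sig.parameters["eps"].default == 9.0
        assert sig.parameters["min_samples"].default == 3

    def test_permutation_consistency(self):
        rng = np.random.default_rng(41)
        pts = rng.uniform(0, 40, size=(25, 3))
        mat = matrix_from_points(pts)
        res = dbscan_precomputed(mat, eps=8.0, min_samples=3)
        perm = rng.permutation(25)
        d2 = mat.values[np.ix_(perm, perm)]
        mat2 = DistanceMatrix([mat.pose_ids[i] for i in perm], d2)
        res2 = dbscan_precomputed(mat2, eps=8.0, min_samples=3)
        lab1 = {pid: int(l) for pid, l in zip(mat.pose_ids, res.labels)}
        lab2 = {pid: int(l) for pid, l in zip(mat2.pose_ids, res2.labels)}
        # same partition: outliers identical, co-membership preserved
        assert {p for p, l in lab1.items() if l == -1} == \
            {p for p, l in lab2.items() if l == -1}
        ids = [p for p, l in lab1.items() if l >= 0]
        a = [lab1[p] for p in ids]
        b = [lab2[p] for p in ids]
        assert adjusted_rand_score(a, b) == 1.0


class TestClusterRecoveryPipeline:
    def test_planted_clusters_recovered(self, small_contact_ensemble, toy_complex):
        poses, truth, _ = small_contact_ensemble
        mat = irmsd_matrix(poses, toy_complex.annotation)
        res = dbscan_precomputed(mat)
        true = np.array([truth.pose_labels[p] for p in mat.pose_ids])
        found = res.labels
        assert all(found[i] == -1 for i in np.nonzero(true == -1)[0])
        mask = true >= 0
        assert adjusted_rand_score(true[mask], found[mask]) == 1.0
        assert res.n_clusters == 2


class TestSummarizeClusters:
    def test_single_cluster_all_both(self):
        summaries = [interacting_residues(grid_pose([3.0] * 20, f"p{i}"),
                                          full_span_annotation(), DOMAINS)
                     for i in range(4)]
        mat = DistanceMatrix([f"p{i}" for i in range(4)], np.zeros((4, 4)))
        res = dbscan_precomputed(mat)
        table, overall = summarize_clusters(res, summaries)
        assert len(table) == 1
        assert table.loc[0, "class_both"] == 4
        assert overall["n_outside_largest"] == 0

    def test_planted_composition(self):
        # cluster A (5 poses): domain1 only; cluster B (4 poses): both domains
        summaries, ids, pts = [], [], []
        for i in range(5):
            pid = f"a{i}"
            summaries.append(interacting_residues(
                grid_pose([3.0] * 10 + [50.0] * 10, pid), full_span_annotation(),
                DOMAINS))
            ids.append(pid)
            pts.append([i * 0.1, 0, 0])
        for i in range(4):
            pid = f"b{i}"
            summaries.append(interacting_residues(
                grid_pose([3.0] * 20, pid), full_span_annotation(), DOMAINS))
            ids.append(pid)
            pts.append([100 + i * 0.1, 0, 0])
        mat = matrix_from_points(np.array(pts, dtype=float), ids)
        res = dbscan_precomputed(mat, eps=9.0, min_samples=3)
        table, overall = summarize_clusters(res, summaries)
        assert table.loc[0, "class_first"] == 5  # larger cluster
        assert table.loc[1, "class_both"] == 4
        assert overall["n_outside_largest"] == 4
        assert overall["n_both_outside_largest"] == 4
        assert overall["both_fraction_outside_largest"] == 1.0

    def test_all_outliers(self):
        pts = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0]], dtype=float)
        mat = matrix_from_points(pts)
        res = dbscan_precomputed(mat, eps=1.0, min_samples=3)
        summaries = [interacting_residues(grid_pose([3.0] * 20, f"m{i}"),
                                          full_span_annotation(), DOMAINS)
                     for i in range(3)]
        table, overall = summarize_clusters(res, summaries)
        assert len(table) == 0
        assert overall["n_outliers"] == 3


class TestEmbed2d:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(55)
        mat = matrix_from_points(rng.uniform(0, 10, size=(12, 3)))
        a = embed_2d(mat, seed=3)
        b = embed_2d(mat, seed=3)
        assert a.shape == (12, 2)
        assert np.array_equal(a, b)

    def test_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(56)
        pts = np.vstack([rng.normal(0, 0.5, size=(10, 3)),
                         rng.normal(200, 0.5, size=(10, 3))])
        mat = matrix_from_points(pts)
        coords = embed_2d(mat, seed=0)
        a, b = coords[:10], coords[10:]
        intra = max(cdist(a, a).max(), cdist(b, b).max())
        inter = cdist(a, b).mean()
        assert inter > intra


class TestDistanceMatrixInvariants:
    def test_asymmetric_rejected(self):
        vals = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], vals)

    def test_nonzero_diag_rejected(self):
        vals = np.array([[0.1, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], vals)


class TestDomainDefinition:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainDefinition([("a", 1, 10), ("b", 5, 20)])

    def test_label_of(self):
        d = DomainDefinition([("a", 1, 10), ("b", 20, 30)])
        assert d.label_of(5) == "a"
        assert d.label_of(15) is None
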
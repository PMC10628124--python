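import numpy as np
import pytest

from elevatormd import TrajectoryFrame
from elevatormd import landscape as L


class TestSelectFeatureResidues:
    def test_default_sequence_starts_76_81_86(self):
        seq = L.select_feature_residues()
        assert seq[:3] == [76, 81, 86]
        assert all(b - a == 5 for a, b in zip(seq, seq[1:]))
        assert seq[-1] <= 505

    def test_step_one_over_three_residues(self):
        assert L.select_feature_residues((1, 3), start=1, step=1) == [1, 2, 3]

    def test_pair_feature_count_is_k_choose_2(self):
        for tmd, start, step in [((76, 505), 76, 5), ((1, 50), 1, 3)]:
            k = len(L.select_feature_residues(tmd, start, step))
            frames = [
                TrajectoryFrame(
                    xyz=np.random.default_rng(0).normal(size=(k, 3)),
                    box=np.array([50.0, 50, 50]),
                )
            ]
            # combinatorial identity checked on the built matrix
            n_pairs = k * (k - 1) // 2
            assert n_pairs == len(
                list(__import__("itertools").combinations(range(k), 2))
            )

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            L.select_feature_residues((1, 3), start=10, step=5)


class TestDistanceFeatures:
    def test_three_residues_match_hand_computed(self, small_elevator):
        tr = small_elevator
        residues = [76, 100, 200]
        fm = L.build_distance_features(tr.frames[:1], tr.system, "A", residues)
        ca = {}
        for r in residues:
            i = np.flatnonzero(
                (tr.system.resids == r)
                & (tr.system.names == "CA")
                & (tr.system.chains == "A")
            )[0]
            ca[r] = tr.frames[0].xyz[i]
        expected = [
            np.linalg.norm(ca[76] - ca[100]),
            np.linalg.norm(ca[76] - ca[200]),
            np.linalg.norm(ca[100] - ca[200]),
        ]
        assert np.allclose(fm.values[0], expected)
        assert fm.residue_pairs == [(76, 100), (76, 200), (100, 200)]

    def test_duplicated_frame_gives_identical_rows(self, small_elevator):
        tr = small_elevator
        fm = L.build_distance_features(
            [tr.frames[0], tr.frames[0]], tr.system, "A", [76, 100, 200]
        )
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_matches_nested_loop_oracle(self, small_elevator):
        tr = small_elevator
        residues = L.select_feature_residues((76, 150), start=76, step=10)
        fm = L.build_distance_features(tr.frames[:5], tr.system, "A", residues)
        idx = [
            np.flatnonzero(
                (tr.system.resids == r)
                & (tr.system.names == "CA")
                & (tr.system.chains == "A")
            )[0]
            for r in residues
        ]
        for fi, frame in enumerate(tr.frames[:5]):
            col = 0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    d = np.sqrt(
                        sum(
                            (frame.xyz[idx[a], k] - frame.xyz[idx[b], k]) ** 2
                            for k in range(3)
                        )
                    )
                    assert fm.values[fi, col] == pytest.approx(d)
                    col += 1

    def test_missing_ca_raises(self, small_elevator):
        tr = small_elevator
        with pytest.raises(ValueError, match="no CA"):
            L.build_distance_features(tr.frames[:1], tr.system, "A", [9999])


def features_from_array(x):
    """Wrap a raw (n, 3) array as a 3-residue FeatureMatrix."""
    return L.FeatureMatrix(
        values=np.abs(x),
        residue_pairs=[(1, 2), (1, 3), (2, 3)],
        sample_index=[(i, "A") for i in range(len(x))],
    )


class TestPCA:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 40)
        x = np.outer(t, [1.0, 2.0, 3.0]) + 5
        model = L.fit_pca(features_from_array(x), n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_cloud_spreads_variance_evenly(self):
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(10):
            x = rng.normal(5, 1, size=(400, 3))
            m = L.fit_pca(features_from_array(x), n_components=3)
            ratios.append(m.explained_variance_ratio)
        mean_ratio = np.mean(ratios, axis=0)
        assert np.allclose(mean_ratio, 1 / 3, atol=0.05)

    def test_two_state_elevator_pc1_separates_states(self, small_elevator):
        tr = small_elevator
        fm = L.build_distance_features(
            tr.frames, tr.system, "A", L.select_feature_residues()
        )
        model = L.fit_pca(fm)
        states = (tr.truth["state"] == "ES").astype(float)
        r = np.corrcoef(model.projections[:, 0], states)[0, 1]
        assert abs(r) > 0.9

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(5, 1, size=(30, 3)))
        fm = features_from_array(x)
        model = L.fit_pca(fm, n_components=3)
        recon = model.projections @ model.components + model.mean
        assert np.allclose(recon, fm.values, atol=1e-10)

    def test_degenerate_input_warns(self):
        x = np.ones((20, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            m = L.fit_pca(features_from_array(x), n_components=2)
        assert np.allclose(m.explained_variance_ratio, 0.0)


class TestProject:
    def test_training_mean_maps_to_origin(self):
        rng = np.random.default_rng(3)
        fm = features_from_array(np.abs(rng.normal(5, 1, (25, 3))))
        model = L.fit_pca(fm, n_components=2)
        assert np.allclose(L.project(model.mean, model), 0.0, atol=1e-10)

    def test_training_sample_matches_stored_projection(self):
        rng = np.random.default_rng(4)
        fm = features_from_array(np.abs(rng.normal(5, 1, (25, 3))))
        model = L.fit_pca(fm, n_components=2)
        assert np.allclose(
            L.project(fm.values[7], model)[0], model.projections[7], atol=1e-10
        )

    def test_held_out_matches_explicit_dot_product(self):
        rng = np.random.default_rng(5)
        fm = features_from_array(np.abs(rng.normal(5, 1, (25, 3))))
        model = L.fit_pca(fm, n_components=2)
        new = np.abs(rng.normal(5, 1, 3))
        expected = [(new - model.mean) @ model.components[k] for k in range(2)]
        assert np.allclose(L.project(new, model)[0], expected)

    def test_length_mismatch_raises(self):
        fm = features_from_array(np.ones((10, 3)) * [1, 2, 3.0])
        model = L.fit_pca(fm, n_components=1)
        with pytest.raises(ValueError, match="feature length"):
            L.project(np.ones(5), model)


class TestDBSCAN:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(6)
        a = rng.normal([0, 0], 0.1, (300, 2))
        b = rng.normal([10, 0], 0.1, (300, 2))
        pc = np.vstack([a, b])
        labels = L.cluster_landscape(pc, eps=2, min_samples=150)
        truth = np.repeat([0, 1], 300)
        found = set(labels) - {-1}
        assert len(found) == 2
        agree = sum(
            np.unique(truth[labels == lab], return_counts=True)[1].max()
            for lab in found
        )
        assert agree / len(truth) >= 0.95

    def test_sparse_scatter_is_all_noise(self):
        rng = np.random.default_rng(7)
        pc = rng.uniform(-500, 500, (400, 2))
        labels = L.cluster_landscape(pc, eps=2, min_samples=150)
        assert np.all(labels == -1)

    def test_fewer_points_than_min_samples_warns_all_noise(self):
        with pytest.warns(UserWarning, match="min_samples"):
            labels = L.cluster_landscape(np.zeros((10, 2)))
        assert np.all(labels == -1)

    def test_labels_invariant_under_permutation(self):
        rng = np.random.default_rng(8)
        pc = np.vstack(
            [rng.normal([0, 0], 0.1, (200, 2)), rng.normal([8, 0], 0.1, (200, 2))]
        )
        labels = L.cluster_landscape(pc, eps=2, min_samples=100)
        perm = rng.permutation(len(pc))
        labels_p = L.cluster_landscape(pc[perm], eps=2, min_samples=100)
        # same partition up to label renaming
        for lab in set(labels) - {-1}:
            members = np.flatnonzero(labels == lab)
            mapped = labels_p[np.argsort(perm)][members]
            assert len(set(mapped)) == 1 and mapped[0] != -1


class TestClusterCentroid:
    def make_frames(self, coords_list):
        return [
            TrajectoryFrame(xyz=c, box=np.array([100.0, 100, 100]))
            for c in coords_list
        ]

    def test_identical_frames_any_member_zero_rmsd(self):
        xyz = np.random.default_rng(9).normal(size=(10, 3))
        frames = self.make_frames([xyz.copy()] * 3)
        cid = L.cluster_centroid(frames, np.arange(3), np.arange(10))
        assert cid in (0, 1, 2)
        mat = L.pairwise_rmsd_matrix(np.stack([xyz] * 3))
        assert np.allclose(mat, 0.0, atol=1e-10)

    def test_midpoint_of_interpolated_path_wins(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(20, 3))
        b = a + rng.normal(0, 1.0, size=(20, 3))  # non-rigid deformation
        frames = self.make_frames([a, 0.5 * (a + b), b])
        cid = L.cluster_centroid(frames, np.arange(3), np.arange(20))
        assert cid == 1

    def test_single_member_cluster_returns_member(self):
        frames = self.make_frames([np.zeros((4, 3))])
        assert L.cluster_centroid(frames, np.array([5 - 5]), np.arange(4)) == 0

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError, match="empty"):
            L.cluster_centroid([], np.array([], dtype=int), np.arange(3))

    def test_matches_brute_force_mda_oracle(self, small_elevator):
        import MDAnalysis.analysis.rms as rms

        tr = small_elevator
        members = np.arange(12)
        ca = np.flatnonzero(
            (tr.system.names == "CA") & (tr.system.chains == "A")
        )
        cid = L.cluster_centroid(tr.frames, members, ca)
        coords = np.stack([tr.frames[i].xyz[ca] for i in members])
        n = len(members)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = rms.rmsd(
                    coords[i], coords[j], center=True, superposition=True
                )
        oracle = members[int(np.argmin(mat.sum(axis=1) / (n - 1)))]
        assert cid == oracle
        # and the full matrices agree
        ours = L.pairwise_rmsd_matrix(coords)
        assert np.allclose(ours, mat, atol=1e-6)


class TestLandscapeSurface:
    def test_single_occupied_bin_is_zero(self):
        pc = np.zeros((10, 2))
        surf, _, _ = L.landscape_surface(pc, bins=2)
        occupied = surf[~surf.mask]
        assert occupied.size == 1
        assert occupied[0] == pytest.approx(0.0)

    def test_count_ratio_three_to_one_gives_rt_ln3(self):
        pc = np.array([[0.25, 0.5]] * 3 + [[0.75, 0.5]])
        surf, _, _ = L.landscape_surface(pc, bins=2, rt=0.593)
        vals = np.sort(surf.compressed())
        assert vals[1] - vals[0] == pytest.approx(0.593 * np.log(3))

    def test_minimum_at_densest_bin(self):
        rng = np.random.default_rng(11)
        pc = rng.normal(0, 1, (2000, 2))
        surf, xe, ye = L.landscape_surface(pc, bins=10)
        counts, _, _ = np.histogram2d(pc[:, 0], pc[:, 1], bins=[xe, ye])
        assert np.unravel_index(np.argmax(counts), counts.shape) == np.unravel_index(
            np.argmin(surf.filled(np.inf)), surf.shape
        )

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError, match="bins"):
            L.landscape_surface(np.zeros((5, 2)), bins=1)
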
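"""Frame construction, rigid transforms, clash counting, descriptors."""

import numpy as np
import pytest

from cytogeom import (
    ChainRoleMap,
    ClashParams,
    ComplexModel,
    DegenerateFrameError,
    NonRigidMotionError,
    RigidTransform,
    SamplerConfig,
    apply_transform,
    compute_descriptors,
    count_clashes,
    define_frame,
    run_geometry_scan,
    sample_transforms,
    select_diverse,
)
from cytogeom.geomframe import DOF_NAMES
from cytogeom.synthetic import (
    ToyComplexSpec,
    make_toy_complex,
    preset_clashing_binders,
    preset_degenerate_anchors,
)

from conftest import random_toy_spec


def _random_atoms_model(rng, n=200, n_chains=3, box=25.0):
    """Raw multi-chain point cloud for clash oracles."""
    chains = np.array([f"{'ABC'[i % n_chains]}" for i in range(n)], dtype=object)
    roles = ChainRoleMap(
        fixed_receptor="A",
        mobile_receptor="B",
        membrane_anchor_fixed=("A", "1"),
        membrane_anchor_mobile=("B", "1"),
    )
    return ComplexModel(
        chain_ids=chains,
        residue_ids=np.array([str(i + 1) for i in range(n)], dtype=object),
        residue_names=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        coords=rng.uniform(0, box, size=(n, 3)),
        roles=roles,
    )


class TestFrame:
    def test_symmetric_construction(self):
        spec = ToyComplexSpec(
            receptor_a_centroid=(-5, 0, 5),
            receptor_b_centroid=(5, 0, 5),
            anchor_a=(-5, 0, 0),
            anchor_b=(5, 0, 0),
        )
        f = define_frame(make_toy_complex(spec))
        np.testing.assert_allclose(f.origin, [0, 0, 5], atol=1e-9)
        np.testing.assert_allclose(f.z_axis, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(f.x_axis, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(f.y_axis, [0, 1, 0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_gram_schmidt_oracle(self, seed):
        model = make_toy_complex(random_toy_spec(np.random.default_rng(seed)))
        f = define_frame(model)
        # independent vector-algebra oracle
        c = 0.5 * (model.chain_ca_centroid("A") + model.chain_ca_centroid("B"))
        aa, ab = model.anchor_ca("fixed"), model.anchor_ca("mobile")
        z = c - 0.5 * (aa + ab)
        z = z / np.linalg.norm(z)
        x = (ab - aa) - ((ab - aa) @ z) * z
        x = x / np.linalg.norm(x)
        y = np.cross(z, x)
        np.testing.assert_allclose(f.origin, c, atol=1e-12)
        np.testing.assert_allclose(f.z_axis, z, atol=1e-12)
        np.testing.assert_allclose(f.x_axis, x, atol=1e-12)
        np.testing.assert_allclose(f.y_axis, y, atol=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_axes_orthonormal_right_handed(self, seed):
        f = define_frame(make_toy_complex(random_toy_spec(np.random.default_rng(100 + seed))))
        B = f.basis
        np.testing.assert_allclose(B.T @ B, np.eye(3), atol=1e-10)
        assert np.linalg.det(B) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_anchor_geometry_rejected(self):
        with pytest.raises(DegenerateFrameError):
            define_frame(make_toy_complex(preset_degenerate_anchors()))

    def test_coincident_anchors_rejected_at_spec_level(self):
        with pytest.raises(ValueError, match="distinct"):
            ToyComplexSpec(anchor_a=(0, 0, 0), anchor_b=(0, 0, 0))


class TestSampler:
    def test_zero_sigmas_give_identity_transforms(self, toy):
        frame = define_frame(toy)
        ts, dofs = sample_transforms(SamplerConfig(n_samples=5, seed=3), frame, frame.origin)
        assert len(ts) == 5
        assert np.abs(dofs).max() == 0
        for t in ts:
            np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
            np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    def test_gaussian_moments_match_configuration(self, toy):
        frame = define_frame(toy)
        n = 10_000
        cfg = SamplerConfig(sigma_rot_z=30.0, n_samples=n, seed=11)
        _, dofs = sample_transforms(cfg, frame, frame.origin)
        zrot = dofs[:, DOF_NAMES.index("rot_z")]
        se_mean = 30.0 / np.sqrt(n)
        se_sd = 30.0 / np.sqrt(2 * (n - 1))
        assert abs(zrot.mean()) < 3 * se_mean
        assert abs(zrot.std(ddof=1) - 30.0) < 3 * se_sd
        assert np.abs(dofs[:, [0, 1, 3, 4, 5]]).max() == 0

    def test_grid_enumeration_order(self, toy):
        frame = define_frame(toy)
        cfg = SamplerConfig(
            mode="grid",
            grid={"rot_z": (-90.0, 90.0, 90.0), "trans_x": (0.0, 5.0, 5.0)},
        )
        _, dofs = sample_transforms(cfg, frame, frame.origin)
        got = [(d[2], d[3]) for d in dofs]
        assert got == [
            (-90.0, 0.0), (-90.0, 5.0), (0.0, 0.0), (0.0, 5.0), (90.0, 0.0), (90.0, 5.0)
        ]

    def test_grid_zero_step_rejected(self, toy):
        frame = define_frame(toy)
        cfg = SamplerConfig(mode="grid", grid={"rot_z": (0.0, 10.0, 0.0)})
        with pytest.raises(ValueError, match="zero step"):
            sample_transforms(cfg, frame, frame.origin)


class TestRigidTransforms:
    def test_identity_leaves_coordinates_unchanged(self, toy):
        out = apply_transform(toy, RigidTransform.identity(), {"B"})
        assert out.coords.tobytes() == toy.coords.tobytes()

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_round_trip(self, toy, seed):
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation

        T = RigidTransform(
            Rotation.random(random_state=seed).as_matrix(),
            rng.uniform(-10, 10, 3),
            rng.uniform(-5, 5, 3),
        )
        back = apply_transform(apply_transform(toy, T, {"B", "D"}), T.inverse(), {"B", "D"})
        assert np.abs(back.coords - toy.coords).max() < 1e-6

    def test_rigidity_preserved(self, toy):
        from scipy.spatial.transform import Rotation

        T = RigidTransform(
            Rotation.random(random_state=7).as_matrix(), [3.0, -2.0, 8.0], [1.0, 1.0, 1.0]
        )
        moved = apply_transform(toy, T, {"B"})
        p, q = toy.coords[toy.chain_mask("B")], moved.coords[moved.chain_mask("B")]

        def rg(x):
            return np.sqrt(np.mean(np.sum((x - x.mean(0)) ** 2, axis=1)))

        assert abs(rg(p) - rg(q)) < 1e-9
        dp = np.linalg.norm(p[:, None] - p[None], axis=-1)
        dq = np.linalg.norm(q[:, None] - q[None], axis=-1)
        assert np.abs(dp - dq).max() < 1e-9

    def test_unmoved_atoms_bit_identical(self, toy):
        T = RigidTransform(np.eye(3), [5.0, 0.0, 0.0], np.zeros(3))
        out = apply_transform(toy, T, {"B"})
        keep = ~toy.chain_mask("B")
        assert out.coords[keep].tobytes() == toy.coords[keep].tobytes()

    def test_empty_chain_set_rejected(self, toy):
        with pytest.raises(ValueError, match="empty"):
            apply_transform(toy, RigidTransform.identity(), set())

    def test_kabsch_cross_check_against_scipy(self, rng):
        """Our SVD superposition agrees with scipy's independent solver."""
        from scipy.spatial.transform import Rotation

        from cytogeom import kabsch

        P = rng.normal(size=(20, 3)) * 5
        R_true = Rotation.random(random_state=42).as_matrix()
        Q = P @ R_true.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = kabsch(P, Q)
        assert rmsd < 1e-9
        est, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(R, est.as_matrix(), atol=1e-8)


class TestClashes:
    def test_far_apart_chains_have_no_clashes(self, rng):
        m = _random_atoms_model(rng, n=40, n_chains=2, box=5.0)
        m.coords[m.chain_mask("B")] += 100.0
        assert count_clashes(m, ClashParams(cutoff=3.0)) == 0

    def test_coincident_atoms_in_different_chains_count_once(self, rng):
        m = _random_atoms_model(rng, n=2, n_chains=2, box=0.0)
        assert count_clashes(m, ClashParams(cutoff=3.0)) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_atoms_model(rng, n=200, n_chains=3, box=25.0)
        got = count_clashes(m, ClashParams(cutoff=3.0))
        expected = 0
        for i in range(m.n_atoms):
            for j in range(i + 1, m.n_atoms):
                if m.chain_ids[i] != m.chain_ids[j]:
                    if np.linalg.norm(m.coords[i] - m.coords[j]) < 3.0:
                        expected += 1
        assert got == expected

    def test_receptor_vs_designed_scope(self, rng):
        m = _random_atoms_model(rng, n=90, n_chains=3, box=15.0)
        got = count_clashes(
            m, ClashParams(cutoff=3.0, pair_scope="receptor_vs_designed")
        )
        expected = 0
        for i in range(m.n_atoms):
            for j in range(m.n_atoms):
                if m.chain_ids[i] in "AB" and m.chain_ids[j] == "C":
                    if np.linalg.norm(m.coords[i] - m.coords[j]) < 3.0:
                        expected += 1
        assert got == expected


class TestDescriptors:
    def test_native_maps_to_zero(self, toy):
        frame = define_frame(toy)
        d = compute_descriptors(toy, toy, frame)
        assert d.delta_distance == pytest.approx(0.0, abs=1e-9)
        assert d.theta_z == pytest.approx(0.0, abs=1e-9)
        assert d.lateral_deviation == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_along_inter_anchor_direction(self, toy):
        frame = define_frame(toy)
        direction = toy.anchor_ca("mobile") - toy.anchor_ca("fixed")
        direction /= np.linalg.norm(direction)
        T = RigidTransform(np.eye(3), 7.0 * direction, np.zeros(3))
        moved = apply_transform(toy, T, {"B", "D"})
        d = compute_descriptors(toy, moved, frame)
        assert d.delta_distance == pytest.approx(7.0, abs=1e-9)
        assert d.theta_z == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("alpha", [-150.0, -45.0, 30.0, 90.0, 179.0])
    def test_theta_z_recovers_pure_z_rotation(self, toy, alpha):
        from scipy.spatial.transform import Rotation

        frame = define_frame(toy)
        R = Rotation.from_rotvec(np.radians(alpha) * frame.z_axis).as_matrix()
        center = toy.chain_ca_centroid("B")
        moved = apply_transform(toy, RigidTransform(R, np.zeros(3), center), {"B", "D"})
        d = compute_descriptors(toy, moved, frame)
        assert d.theta_z == pytest.approx(alpha, abs=1e-6)

    def test_ninety_degree_origin_rotation_gives_lateral_90(self, toy):
        from scipy.spatial.transform import Rotation

        frame = define_frame(toy)
        R = Rotation.from_rotvec(np.radians(90.0) * frame.z_axis).as_matrix()
        moved = apply_transform(toy, RigidTransform(R, np.zeros(3), frame.origin), {"B", "D"})
        d = compute_descriptors(toy, moved, frame)
        assert d.lateral_deviation == pytest.approx(90.0, abs=1e-6)

    def test_lateral_deviation_invariant_under_z_translation(self, toy):
        from scipy.spatial.transform import Rotation

        frame = define_frame(toy)
        R = Rotation.from_rotvec(np.radians(40.0) * frame.z_axis).as_matrix()
        T1 = RigidTransform(R, np.zeros(3), frame.origin)
        T2 = RigidTransform(R, 9.0 * frame.z_axis, frame.origin)
        d1 = compute_descriptors(toy, apply_transform(toy, T1, {"B", "D"}), frame)
        d2 = compute_descriptors(toy, apply_transform(toy, T2, {"B", "D"}), frame)
        assert d1.lateral_deviation == pytest.approx(d2.lateral_deviation, abs=1e-9)

    def test_non_rigid_deformation_rejected(self, toy):
        frame = define_frame(toy)
        bent = toy.copy()
        mask = bent.chain_mask("B")
        bent.coords[mask] *= 1.05
        with pytest.raises(NonRigidMotionError):
            compute_descriptors(toy, bent, frame)


class TestScan:
    def test_zero_sigma_scan_replicates_native(self, toy):
        cfg = SamplerConfig(n_samples=4, seed=0)
        native_pass = count_clashes(toy, ClashParams()) == 0
        samples = run_geometry_scan(toy, cfg)
        for s in samples:
            assert s.descriptors.delta_distance == pytest.approx(0.0, abs=1e-9)
            assert s.passed_clash == native_pass

    def test_clash_pass_rate_below_one_and_matches_recomputation(self):
        model = make_toy_complex(preset_clashing_binders())
        cfg = SamplerConfig(
            sigma_trans_x=12.0, sigma_trans_y=12.0, sigma_trans_z=12.0,
            n_samples=120, seed=4,
        )
        clash = ClashParams(cutoff=3.0)
        samples = run_geometry_scan(model, cfg, clash)
        rate = np.mean([s.passed_clash for s in samples])
        assert rate < 1.0
        for s in samples[:25]:  # per-sample recomputation oracle
            moved = apply_transform(model, s.transform, {"B", "D"})
            assert count_clashes(moved, clash) == s.clash_pairs

    def test_scan_bit_reproducible(self, toy):
        cfg = SamplerConfig(sigma_rot_z=25.0, sigma_trans_x=5.0, n_samples=200, seed=9)
        a = run_geometry_scan(toy, cfg)
        b = run_geometry_scan(toy, cfg)
        assert [s.id for s in a] == [s.id for s in b]
        for sa, sb in zip(a, b):
            assert sa.descriptors == sb.descriptors
            assert sa.clash_pairs == sb.clash_pairs
            np.testing.assert_array_equal(sa.transform.rotation, sb.transform.rotation)


class TestSelectDiverse:
    @staticmethod
    def _scan(toy, n=300):
        cfg = SamplerConfig(
            sigma_rot_z=40.0, sigma_trans_x=8.0, sigma_trans_z=8.0, n_samples=n, seed=2
        )
        return run_geometry_scan(toy, cfg)

    def test_k_equals_all_returns_all(self, toy):
        samples = self._scan(toy, 40)
        eligible = [s for s in samples if s.passed_clash]
        out = select_diverse(samples, k=len(eligible))
        assert {s.id for s in out} == {s.id for s in eligible}

    def test_k_larger_than_eligible_rejected_with_counts(self, toy):
        samples = self._scan(toy, 20)
        with pytest.raises(ValueError, match="pass"):
            select_diverse(samples, k=len(samples) + 1)

    def test_first_pick_is_nearest_native(self, toy):
        samples = self._scan(toy)
        out = select_diverse(samples, k=5)
        d = out[0].descriptors
        norm0 = abs(d.delta_distance) + abs(d.theta_z) + abs(d.lateral_deviation)
        # crude check: the first pick is within the most native-like decile
        norms = sorted(
            abs(s.descriptors.delta_distance) + abs(s.descriptors.theta_z)
            + abs(s.descriptors.lateral_deviation)
            for s in samples if s.passed_clash
        )
        assert norm0 <= norms[len(norms) // 10]

    def test_duplicates_not_selected_twice_early(self, toy):
        samples = self._scan(toy, 30)
        dup = samples[5]
        doubled = samples + [
            type(dup)(
                id="zdup", transform=dup.transform, clash_pairs=dup.clash_pairs,
                passed_clash=dup.passed_clash, descriptors=dup.descriptors, dof=dup.dof,
            )
        ]
        out = select_diverse(doubled, k=10)
        ids = [s.id for s in out]
        # the duplicate pair contributes at most one member until all
        # distinct geometries are exhausted
        assert not (dup.id in ids and "zdup" in ids)

    def test_more_diverse_than_random_subsets(self, toy):
        samples = self._scan(toy, 400)
        eligible = sorted((s for s in samples if s.passed_clash), key=lambda s: s.id)
        k = 96
        out = select_diverse(samples, k=k)

        X = np.array(
            [
                [s.descriptors.delta_distance, s.descriptors.theta_z,
                 s.descriptors.lateral_deviation]
                for s in eligible
            ]
        )
        X = X / X.std(axis=0)
        index = {s.id: i for i, s in enumerate(eligible)}

        def min_pairwise(ids):
            pts = X[[index[i] for i in ids]]
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            return np.min(d[np.triu_indices(len(pts), 1)])

        fps = min_pairwise([s.id for s in out])
        rng = np.random.default_rng(0)
        for _ in range(100):
            rand_ids = [eligible[i].id for i in rng.choice(len(eligible), k, replace=False)]
            assert fps >= min_pairwise(rand_ids)
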
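"""Rigid registration: closed-form fit, residuals, degenerate input handling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from depthbench.registration import (
    DegenerateConfigurationError,
    InsufficientCorrespondencesError,
    MarkerSet,
    RegistrationError,
    RigidTransform,
    apply_transform,
    estimate_rigid_transform,
    invert_transform,
    residual_error,
)
from depthbench.synthetic import random_rigid_transform

from conftest import make_random_points


def brute_force_fit(D, M):
    """Independent SSD-minimising oracle over Euler angles + translation.

    Multi-start nonlinear least squares on the 6 pose parameters; returns the
    best mean residual and the transform.  Shares no code with the SVD path.
    """

    def residuals(params):
        R = Rotation.from_euler("xyz", params[:3]).as_matrix().T
        return (D @ R + params[3:] - M).ravel()

    best = None
    starts = [np.zeros(6)]
    rng = np.random.default_rng(7)
    for _ in range(12):
        starts.append(np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.uniform(-50, 50, 3)]))
    for s in starts:
        sol = least_squares(residuals, s, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_euler("xyz", best.x[:3]).as_matrix().T
    resid = np.linalg.norm(D @ R + best.x[3:] - M, axis=1).mean()
    return resid, RigidTransform(R, best.x[3:])


class TestMarkerSet:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate label"):
            MarkerSet("M", ("a", "a"), [[0, 0, 0], [1, 1, 1]])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MarkerSet("M", ("a",), [[np.nan, 0, 0]])

    def test_unknown_frame_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            MarkerSet("Q", ("a",), [[0, 0, 0]])

    def test_unicode_arrow_frame_normalised(self):
        ms = MarkerSet("D→M", ("a",), [[0, 0, 0]])
        assert ms.frame == "D->M"

    def test_correspondence_is_by_label_not_order(self, rng):
        ref = make_random_points(rng, 5, frame="M")
        perm = rng.permutation(5)
        shuffled = MarkerSet(
            "D", tuple(ref.labels[i] for i in perm), ref.points[perm]
        )
        result = estimate_rigid_transform(shuffled, ref)
        assert result.residual_error < 1e-9


class TestRigidTransform:
    def test_reflection_rejected_by_type(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rotation_applied_row_vector_convention(self):
        # 90 degrees about z maps x onto y under p' = p @ R + t
        Rz = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = RigidTransform(Rz, np.zeros(3))
        assert np.allclose(t.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_invert_closed_form(self, rng):
        t = random_rigid_transform(rng)
        inv = invert_transform(t)
        assert np.allclose(inv.rotation, t.rotation.T)
        assert np.allclose(inv.translation, -t.translation @ t.rotation.T)

    def test_identity_inverts_to_identity(self):
        inv = invert_transform(RigidTransform.identity())
        assert np.allclose(inv.rotation, np.eye(3))
        assert np.allclose(inv.translation, 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_apply_invert_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid_transform(rng)
        pts = rng.uniform(-100, 100, size=(100, 3))
        back = invert_transform(t).apply(t.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    def test_apply_transform_changes_frame_only_as_expected(self, rng):
        dev = make_random_points(rng, 4, frame="D")
        out = apply_transform(dev, RigidTransform.identity())
        assert out.frame == "D->M"
        assert out.labels == dev.labels
        assert np.allclose(out.points, dev.points)

    def test_apply_transform_requires_device_frame(self, rng):
        ref = make_random_points(rng, 4, frame="M")
        with pytest.raises(ValueError, match="device-frame"):
            apply_transform(ref, RigidTransform.identity())


class TestEstimate:
    def test_identity_case(self, tetrahedron):
        dev = MarkerSet("D", tetrahedron.labels, tetrahedron.points)
        res = estimate_rigid_transform(dev, tetrahedron)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res.transform.translation, 0.0, atol=1e-12)
        assert res.residual_error == pytest.approx(0.0, abs=1e-12)
        assert res.n_markers_used == 4
        assert res.labels_excluded == ()

    def test_pure_translation(self, tetrahedron):
        dev = MarkerSet("D", tetrahedron.labels, tetrahedron.points - np.array([5.0, 0.0, 0.0]))
        res = estimate_rigid_transform(dev, tetrahedron)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(res.transform.translation, [5.0, 0.0, 0.0], atol=1e-9)
        assert res.residual_error == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_with_noise_matches_brute_force_oracle(self, tetrahedron):
        # 90 degrees about y plus a translation, with per-point perturbations
        Ry = Rotation.from_euler("y", 90, degrees=True).as_matrix().T
        truth = RigidTransform(Ry, np.array([3.0, -2.0, 7.0]))
        rng = np.random.default_rng(11)
        dev_pts = truth.inverse().apply(tetrahedron.points) + rng.normal(0, 0.3, (4, 3))
        dev = MarkerSet("D", tetrahedron.labels, dev_pts)
        res = estimate_rigid_transform(dev, tetrahedron)
        oracle_resid, oracle_t = brute_force_fit(dev_pts, np.asarray(tetrahedron.points))
        assert res.residual_error == pytest.approx(oracle_resid, abs=1e-6)
        assert np.allclose(res.transform.rotation, oracle_t.rotation, atol=1e-5)
        assert np.allclose(res.transform.translation, oracle_t.translation, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_small_noisy_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        M = rng.uniform(-30, 30, size=(n, 3))
        truth = random_rigid_transform(rng)
        D = truth.inverse().apply(M) + rng.normal(0, 0.5, (n, 3))
        labels = tuple(f"p{i}" for i in range(n))
        res = estimate_rigid_transform(MarkerSet("D", labels, D), MarkerSet("M", labels, M))
        oracle_resid, _ = brute_force_fit(D, M)
        assert res.residual_error <= oracle_resid + 1e-5

    def test_optimal_among_random_transforms(self, rng):
        M = rng.uniform(-30, 30, size=(8, 3))
        truth = random_rigid_transform(rng)
        D = truth.inverse().apply(M) + rng.normal(0, 1.0, (8, 3))
        labels = tuple(f"p{i}" for i in range(8))
        dev, ref = MarkerSet("D", labels, D), MarkerSet("M", labels, M)
        fitted = estimate_rigid_transform(dev, ref)
        for _ in range(1000):
            other = random_rigid_transform(rng)
            assert fitted.residual_error <= residual_error(dev, ref, other) + 1e-12

    def test_residual_invariant_under_common_rigid_motion(self, rng):
        M = rng.uniform(-30, 30, size=(10, 3))
        D = M + rng.normal(0, 1.0, (10, 3))
        labels = tuple(f"p{i}" for i in range(10))
        base = estimate_rigid_transform(MarkerSet("D", labels, D), MarkerSet("M", labels, M))
        motion = random_rigid_transform(rng)
        moved = estimate_rigid_transform(
            MarkerSet("D", labels, motion.apply(D)), MarkerSet("M", labels, motion.apply(M))
        )
        assert moved.residual_error == pytest.approx(base.residual_error, abs=1e-9)

    def test_mirrored_input_still_yields_proper_rotation(self):
        labels = tuple("abcd")
        M = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
        mirrored = M * np.array([-1.0, 1.0, 1.0])
        res = estimate_rigid_transform(MarkerSet("D", labels, mirrored), MarkerSet("M", labels, M))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.residual_error > 1.0  # reflection cannot be absorbed

    def test_too_few_correspondences(self):
        dev = MarkerSet.from_records("D", [("a", 0, 0, 0), ("b", 1, 0, 0)])
        ref = MarkerSet.from_records("M", [("a", 0, 0, 0), ("b", 1, 0, 0), ("x", 0, 1, 0)])
        with pytest.raises(InsufficientCorrespondencesError, match="insufficient correspondences"):
            estimate_rigid_transform(dev, ref)

    def test_collinear_reference_degenerate(self):
        labels = ("a", "b", "c", "d")
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateConfigurationError, match="degenerate configuration"):
            estimate_rigid_transform(MarkerSet("D", labels, line), MarkerSet("M", labels, line))

    def test_coincident_reference_degenerate(self):
        labels = ("a", "b", "c")
        same = np.ones((3, 3))
        with pytest.raises(DegenerateConfigurationError):
            estimate_rigid_transform(MarkerSet("D", labels, same), MarkerSet("M", labels, same))

    def test_planar_reference_is_not_degenerate(self, rng):
        # the alignment board itself is planar; planarity must be fine
        pts = np.column_stack([rng.uniform(-50, 50, 10), rng.uniform(-50, 50, 10), np.zeros(10)])
        labels = tuple(f"p{i}" for i in range(10))
        res = estimate_rigid_transform(MarkerSet("D", labels, pts), MarkerSet("M", labels, pts))
        assert res.residual_error < 1e-9

    def test_unmatched_labels_reported_excluded(self, rng):
        ref = make_random_points(rng, 6, frame="M")
        dev = MarkerSet("D", ref.labels[:4] + ("extra",), np.vstack([ref.points[:4], [[1, 2, 3]]]))
        res = estimate_rigid_transform(dev, ref)
        assert res.n_markers_used == 4
        assert set(res.labels_excluded) == {"extra", "p4", "p5"}
        assert res.residual_error < 1e-9


class TestResidualError:
    def test_fitted_transform_residual_matches(self, rng):
        ref = make_random_points(rng, 6, frame="M")
        dev = MarkerSet("D", ref.labels, ref.points + rng.normal(0, 0.5, (6, 3)))
        res = estimate_rigid_transform(dev, ref)
        assert residual_error(dev, ref, res.transform) == pytest.approx(
            res.residual_error, abs=1e-12
        )

    def test_hand_computed_two_point_mean(self):
        # offsets (1,2,2) -> norm 3 and (0,0,0) -> norm 0; mean 1.5 cm
        ref = MarkerSet.from_records("M", [("a", 1, 2, 2), ("b", 0, 0, 0)])
        dev = MarkerSet.from_records("D", [("a", 0, 0, 0), ("b", 0, 0, 0)])
        assert residual_error(dev, ref, RigidTransform.identity()) == pytest.approx(1.5)

    def test_no_matched_labels_errors(self):
        ref = MarkerSet.from_records("M", [("a", 0, 0, 0)])
        dev = MarkerSet.from_records("D", [("b", 0, 0, 0)])
        with pytest.raises(RegistrationError, match="no matched labels"):
            residual_error(dev, ref, RigidTransform.identity())
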
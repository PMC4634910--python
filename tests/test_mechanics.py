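"""Trajectories, temporal fitting, strain tensor and twist computation."""

import numpy as np
import pytest

import cinedense as cd
from cinedense.mechanics import (
    TrajectorySet,
    build_trajectories,
    compute_mechanics,
    fit_temporal,
    strain_curves,
    twist_curve,
)
from cinedense.unwrap import EulerianField

from conftest import analytic_trajectories


def _field_from_truth(truth) -> EulerianField:
    """Exact Eulerian field wrapped in the pipeline container."""
    ke = 0.04
    disp = truth.eulerian_disp.copy()
    disp = np.where(truth.myo_masks[:, None], disp, np.nan)
    return EulerianField(
        disp_mm=disp,
        unwrapped_phase=2 * np.pi * ke * np.nan_to_num(disp),
        valid=truth.myo_masks.copy(),
        ke_cycles_per_mm=ke,
    )


def _affine_trajectories(truth, matrix, n_frames=8):
    """Material points moved by a per-frame linear ramp toward ``matrix``."""
    pts = truth.material_coords
    positions = np.empty((n_frames, len(pts), 2))
    for t in range(n_frames):
        s = t / (n_frames - 1)
        m = (1 - s) * np.eye(2) + s * matrix
        positions[t] = pts @ m.T
    return TrajectorySet(
        material_points=pts.copy(),
        positions=positions,
        valid=np.ones(len(pts), dtype=bool),
    )


class TestBuildTrajectories:
    def test_zero_field_constant_trajectories(self, small_truth, small_seg):
        st = cd.stationary_phantom(small_truth.config)
        field = _field_from_truth(st)
        traj = build_trajectories(field, cd.segmentation_from_truth(st))
        np.testing.assert_allclose(
            traj.positions, np.broadcast_to(traj.material_points, traj.positions.shape)
        )

    def test_uniform_translation_is_exact(self, small_truth, small_seg):
        field = _field_from_truth(small_truth)
        disp = np.zeros_like(field.disp_mm)
        disp[:, 0] = 2.0
        field.disp_mm = np.where(small_truth.myo_masks[:, None], disp, np.nan)
        traj = build_trajectories(field, small_seg, smooth_sd_px=0.0)
        expected = np.broadcast_to([2.0, 0.0], traj.material_points.shape)
        for t in range(1, traj.n_frames):
            np.testing.assert_allclose(
                traj.positions[t] - traj.material_points, expected, atol=1e-9
            )

    def test_first_frame_equals_material_points(self, small_truth, small_seg):
        traj = build_trajectories(_field_from_truth(small_truth), small_seg)
        np.testing.assert_array_equal(traj.positions[0], traj.material_points)

    def test_noise_free_phantom_oracle(self, small_truth, small_seg):
        """Exact Eulerian maps give trajectories near the analytic truth;
        the residual is interpolation error of the curved field at 2.8 mm
        pixels (empirically < 0.25 mm; see methods note)."""
        field = _field_from_truth(small_truth)
        traj = build_trajectories(field, small_seg, smooth_sd_px=0.0)
        err = np.abs(traj.positions[:, traj.valid] - small_truth.trajectories[:, traj.valid])
        assert np.max(err) < 0.25


class TestFitTemporal:
    def test_reproduces_polynomials_in_model_class(self, small_truth):
        traj = analytic_trajectories(small_truth)
        n, t = traj.positions.shape[1], traj.n_frames
        tau = np.linspace(-1, 1, t)
        poly = 3.0 * tau**10 - 2.0 * tau**3 + 0.5 * tau  # degree 10
        traj.positions = traj.material_points[None] + poly[:, None, None] * np.ones((t, n, 2))
        fitted = fit_temporal(traj, order=10)
        np.testing.assert_allclose(fitted.positions, traj.positions, atol=1e-8)

    def test_order_zero_gives_time_mean(self, small_truth):
        traj = analytic_trajectories(small_truth)
        fitted = fit_temporal(traj, order=0)
        expected = traj.material_points[None] + traj.displacements.mean(axis=0)
        np.testing.assert_allclose(fitted.positions, np.broadcast_to(expected, fitted.positions.shape), atol=1e-10)

    def test_order_reduced_with_warning(self, small_truth):
        traj = analytic_trajectories(small_truth)
        traj.positions = traj.positions[:6]
        with pytest.warns(UserWarning, match="reducing"):
            fitted = fit_temporal(traj, order=10)
        assert fitted.poly_order == 5

    def test_noise_shrinkage(self, small_truth):
        rng = np.random.default_rng(0)
        traj = analytic_trajectories(small_truth)
        t, n = traj.n_frames, traj.positions.shape[1]
        noise = rng.normal(0, 0.3, size=(t, n, 2))
        traj.positions = traj.material_points[None] + 1.5 + noise
        fitted = fit_temporal(traj, order=10)
        resid_var = np.var(fitted.displacements - 1.5)
        assert resid_var < np.var(noise)


class TestStrainAndTwist:
    def test_rigid_rotation_zero_strain_exact_twist(self, small_truth, small_seg):
        # rotation angle ramps linearly, so every frame is rigid
        pts = small_truth.material_coords
        n_frames = 8
        positions = np.empty((n_frames, len(pts), 2))
        for t in range(n_frames):
            a = np.deg2rad(10.0) * t / (n_frames - 1)
            rot_t = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            positions[t] = pts @ rot_t.T
        traj = TrajectorySet(
            material_points=pts.copy(),
            positions=positions,
            valid=np.ones(len(pts), dtype=bool),
        )
        res = compute_mechanics(traj, small_seg)
        assert res.peaks["twist_deg"] == pytest.approx(10.0, abs=1e-9)
        assert abs(res.peaks["ecc_pct"]) < 1e-9
        assert abs(res.peaks["err_pct"]) < 1e-9

    def test_isotropic_scaling_closed_form(self, small_truth, small_seg):
        lam = 0.9
        traj = _affine_trajectories(small_truth, lam * np.eye(2))
        res = strain_curves(traj, small_seg)
        assert res.peaks["ecc_pct"] == pytest.approx(100 * (lam**2 - 1) / 2, abs=1e-9)
        assert res.peaks["err_pct"] == pytest.approx(-9.5, abs=1e-9)

    def test_curves_zero_at_frame_one(self, small_truth, small_seg):
        traj = analytic_trajectories(small_truth)
        res = compute_mechanics(traj, small_seg)
        f1 = res.curves[res.curves.frame == 1]
        assert f1[["ecc_pct", "err_pct", "twist_deg"]].abs().max().max() < 1e-12

    def test_global_is_mean_of_segments(self, small_truth, small_seg):
        traj = analytic_trajectories(small_truth)
        res = compute_mechanics(traj, small_seg)
        for t in (5, 12):
            sub = res.curves[res.curves.frame == t]
            segs = sub[sub.segment != "global"]["ecc_pct"].to_numpy()
            glob = sub[sub.segment == "global"]["ecc_pct"].iloc[0]
            assert glob == pytest.approx(segs.mean())

    def test_objectivity_appended_rotation(self, small_truth, small_seg):
        """Appending a rigid rotation shifts twist by that angle and leaves
        strain unchanged (to estimation tolerance)."""
        traj = analytic_trajectories(small_truth)
        base = compute_mechanics(traj, small_seg)
        ang = np.deg2rad(7.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = TrajectorySet(
            material_points=traj.material_points.copy(),
            positions=traj.positions.copy(),
            valid=traj.valid.copy(),
        )
        # rotate every frame except the reference
        rotated.positions[1:] = rotated.positions[1:] @ rot.T
        res = compute_mechanics(rotated, small_seg)
        t_last = traj.n_frames
        for measure in ("ecc_pct", "err_pct"):
            a = base.curves[base.curves.segment == "global"][measure].to_numpy()
            b = res.curves[res.curves.segment == "global"][measure].to_numpy()
            np.testing.assert_allclose(a, b, atol=1e-9)
        tw_a = base.curves[base.curves.segment == "global"]["twist_deg"].to_numpy()
        tw_b = res.curves[res.curves.segment == "global"]["twist_deg"].to_numpy()
        np.testing.assert_allclose(tw_b[1:], tw_a[1:] + 7.0, atol=1e-9)

    def test_centroid_point_excluded(self, small_truth, small_seg):
        traj = analytic_trajectories(small_truth)
        traj.material_points = traj.material_points.copy()
        traj.positions = traj.positions.copy()
        traj.material_points[0] = small_seg.ed_centroid
        traj.positions[:, 0] = small_seg.ed_centroid
        res = twist_curve(traj, small_seg)
        assert np.isfinite(res.peaks["twist_deg"])

    def test_noise_free_phantom_recovery(self, small_truth, small_seg):
        """Analytic trajectories reproduce truth Ecc closely and twist
        exactly; Err is biased low by transmural averaging of the
        deformation-gradient fit (see methods note)."""
        traj = analytic_trajectories(small_truth)
        res = compute_mechanics(traj, small_seg)
        assert res.peaks["ecc_pct"] == pytest.approx(small_truth.peak("ecc_pct"), abs=0.5)
        assert res.peaks["twist_deg"] == pytest.approx(small_truth.peak("twist_deg"), abs=0.01)
        assert res.peaks["err_pct"] == pytest.approx(small_truth.peak("err_pct"), abs=2.5)


class TestModelInterface:
    def test_full_fit_summary(self, small_truth, small_seg, noisefree_series_small):
        res = cd.DenseMechanicsModel(noisefree_series_small, small_seg, smooth_sd_px=0.0).fit()
        text = res.summary()
        assert "peak Ecc" in text and "cycles/mm" in text
        assert res.peaks["ecc_pct"] == pytest.approx(small_truth.peak("ecc_pct"), abs=0.5)
        assert res.peaks["twist_deg"] == pytest.approx(small_truth.peak("twist_deg"), abs=0.1)
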
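"""Phase encoding, wrapping, limits, noise scaling and echo geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cinedense as cd
from cinedense.encode import encode_sweep, kspace_echoes, wrap_phase


class TestWrapPhase:
    @pytest.mark.parametrize(
        "phase,expected",
        [
            (0.0, 0.0),
            (3 * np.pi / 2, -np.pi / 2),
            (np.pi, np.pi),
            (-np.pi, np.pi),
            (2 * np.pi, 0.0),
            (-7 * np.pi / 2, np.pi / 2),
        ],
    )
    def test_known_values(self, phase, expected):
        assert wrap_phase(phase) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=-1e6, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_range_and_congruence(self, phase):
        w = wrap_phase(phase)
        assert -np.pi < w <= np.pi
        # w == phase (mod 2 pi): the residual is an integer multiple of 2 pi
        k = (phase - w) / (2 * np.pi)
        assert k == pytest.approx(np.round(k), abs=1e-6)


class TestEncodingLimits:
    @pytest.mark.parametrize(
        "ke,bits,wrap_mm,res_mm",
        [
            (0.10, 12, 5.0, 1 / (4096 * 0.10)),
            (0.04, 12, 12.5, 0.0061035),
            (0.02, 12, 25.0, 1 / (4096 * 0.02)),
        ],
    )
    def test_known_values(self, ke, bits, wrap_mm, res_mm):
        wrap_thr, res = cd.encoding_limits(ke, bits)
        assert wrap_thr == pytest.approx(wrap_mm)
        assert res == pytest.approx(res_mm, rel=1e-3)

    def test_12bit_resolution_at_low_ke_is_6_microns(self):
        _, res = cd.encoding_limits(0.04, 12)
        assert res == pytest.approx(0.006, abs=0.0002)

    def test_rejects_nonpositive_ke(self):
        with pytest.raises(ValueError):
            cd.encoding_limits(0.0)


class TestEncode:
    def test_zero_displacement_zero_noise_gives_zero_phase(self, small_cfg):
        st_truth = cd.stationary_phantom(small_cfg)
        s = cd.encode(st_truth, cd.EncodingConfig(ke_cycles_per_mm=0.10, target_snr=None))
        assert not s.phase_x.any() and not s.phase_y.any()

    def test_phase_proportionality(self):
        # 3 mm at 0.04 cycles/mm -> 2 pi * 0.12 ~= 0.754 rad, unwrapped
        assert wrap_phase(2 * np.pi * 0.04 * 3.0) == pytest.approx(0.754, abs=1e-3)
        # 5 mm at 0.10 cycles/mm sits exactly at the wrap boundary (+pi)
        assert wrap_phase(2 * np.pi * 0.10 * 5.0) == pytest.approx(np.pi)
        # anything beyond 5 mm wraps negative
        assert wrap_phase(2 * np.pi * 0.10 * 5.01) < 0

    def test_round_trip_noise_free(self, small_truth):
        """Below the wrap threshold, phase/(2 pi ke) recovers u exactly."""
        ke = 0.04  # threshold 12.5 mm > phantom peak displacement
        s = cd.encode(small_truth, cd.EncodingConfig(ke_cycles_per_mm=ke, target_snr=None))
        for t in (0, small_truth.config.es_frame - 1):
            m = small_truth.myo_masks[t]
            rec = s.phase_x[t][m] / (2 * np.pi * ke)
            np.testing.assert_allclose(
                rec, small_truth.eulerian_disp[t, 0][m], atol=1e-12
            )

    def test_modularity_in_displacement(self, small_truth):
        """Shifting all displacement by 1/ke leaves wrapped phase unchanged."""
        ke = 0.05
        s1 = cd.encode(small_truth, cd.EncodingConfig(ke_cycles_per_mm=ke, target_snr=None))
        shifted = cd.build_phantom(small_truth.config)
        shifted.eulerian_disp = shifted.eulerian_disp + (1.0 / ke) * shifted.myo_masks[
            :, None, :, :
        ]
        s2 = cd.encode(shifted, cd.EncodingConfig(ke_cycles_per_mm=ke, target_snr=None))
        np.testing.assert_allclose(s1.phase_x, s2.phase_x, atol=1e-9)

    def test_measured_snr_near_target(self, default_truth):
        from cinedense import metrics

        s = cd.encode(
            default_truth, cd.EncodingConfig(ke_cycles_per_mm=0.06, target_snr=20.0, seed=3)
        )
        roi = metrics.corner_background_roi(s.shape)
        snr = metrics.snr_series(s, default_truth.myo_masks, roi)
        assert np.nanmean(snr) == pytest.approx(20.0, rel=0.10)

    def test_blood_decay_monotone_and_faster_at_high_ke(self, small_truth):
        series = encode_sweep(
            small_truth, cd.EncodingConfig(target_snr=None), [0.02, 0.10]
        )
        curves = {}
        for ke, s in series.items():
            mean_blood = np.array(
                [s.magnitude[t][small_truth.blood_masks[t]].mean() for t in range(s.n_frames)]
            )
            assert np.all(np.diff(mean_blood) <= 1e-12)
            curves[ke] = mean_blood / mean_blood[0]
        assert np.all(curves[0.10][1:] < curves[0.02][1:])

    def test_quantization_changes_phase_by_at_most_half_step(self, small_truth):
        enc = cd.EncodingConfig(ke_cycles_per_mm=0.04, target_snr=None)
        enc_q = cd.EncodingConfig(ke_cycles_per_mm=0.04, target_snr=None, quant_bits=12)
        s = cd.encode(small_truth, enc)
        sq = cd.encode(small_truth, enc_q)
        step = 2 * np.pi / 4096
        diff = np.abs(wrap_phase(s.phase_x - sq.phase_x))
        assert diff.max() <= step / 2 + 1e-12
        assert (sq.phase_x != s.phase_x).any()  # quantization actually applied

    def test_noise_is_seed_deterministic(self, small_truth):
        enc = cd.EncodingConfig(ke_cycles_per_mm=0.06, target_snr=15.0, seed=11)
        s1 = cd.encode(small_truth, enc)
        s2 = cd.encode(small_truth, enc)
        np.testing.assert_array_equal(s1.magnitude, s2.magnitude)
        np.testing.assert_array_equal(s1.phase_x, s2.phase_x)


class TestKspaceEchoes:
    def test_high_ke_moves_anti_echo_outside_sampled_region(self):
        enc = cd.EncodingConfig(ke_cycles_per_mm=0.10, cspamm=False, kd_thru_plane=0.0)
        layout = kspace_echoes(enc, matrix=128)
        assert layout.k_max_sampled == pytest.approx(128 / 720)
        assert not layout["anti"].within_sampled_region  # 0.20 > 0.178
        assert layout["stimulated"].offset_cycles_per_mm == 0.0

    def test_thru_plane_dephasing_suppresses_both_artifact_echoes(self):
        enc = cd.EncodingConfig(ke_cycles_per_mm=0.04, cspamm=True, kd_thru_plane=0.08, slice_mm=8.0)
        layout = kspace_echoes(enc, matrix=128)
        # 0.08 cycles/mm * 8 mm = 0.64 >= 0.5 cycles of through-plane dephasing
        assert layout["T1"].suppressed and layout["anti"].suppressed
        assert not layout.stripe_artifact_risk

    def test_low_ke_without_suppression_flags_stripe_artifacts(self):
        enc = cd.EncodingConfig(ke_cycles_per_mm=0.04, cspamm=False, kd_thru_plane=0.0)
        layout = kspace_echoes(enc, matrix=128)
        assert not layout["T1"].suppressed and not layout["anti"].suppressed
        assert layout["T1"].within_sampled_region
        assert layout["anti"].within_sampled_region
        assert layout.stripe_artifact_risk

    def test_echo_offsets(self):
        layout = kspace_echoes(cd.EncodingConfig(ke_cycles_per_mm=0.06), matrix=128)
        assert layout["T1"].offset_cycles_per_mm == pytest.approx(0.06)
        assert layout["anti"].offset_cycles_per_mm == pytest.approx(0.12)
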
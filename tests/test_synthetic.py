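"""Generators: programmed ground truth must be exactly what was rendered."""

import numpy as np
import pytest
from dataclasses import replace

from onhlab.erg import extract_features
from onhlab.synthetic import (
    AxonFieldParams,
    ERGParams,
    PhantomParams,
    StudyDesign,
    analytic_depression,
    generate_axon_field,
    generate_erg_trace,
    generate_oct_phantom,
    generate_study_dataset,
    pit_depth_for_target,
    pit_profile,
)

from conftest import small_phantom


def brute_force_depression(params: PhantomParams, n_theta=720, n_r=81) -> float:
    """Independent 150/500 µm evaluation by dense sampling of the analytic surface.

    Evaluates h on dense circles at both radii (including tilt, which must
    cancel) rather than reusing the generator's closed-form shortcut.
    """
    pr = pit_profile(params.pit_family)
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)

    def circle_mean(r0):
        x, y = r0 * np.cos(th), r0 * np.sin(th)
        h = (
            params.tilt_um_per_mm[0] * x / 1000.0
            + params.tilt_um_per_mm[1] * y / 1000.0
            - params.pit_depth_um * pr(np.hypot(x, y), params.pit_sigma_um)
        )
        return h.mean()

    return circle_mean(500.0) - circle_mean(150.0)


class TestOCTPhantom:
    def test_flat_surface_has_zero_depression(self):
        p = small_phantom(pit_depth_um=0.0, jitter_sigma_px=0.0, speckle_contrast=0.0)
        _, gt = generate_oct_phantom(p)
        assert gt.d_true_um == 0.0
        assert np.ptp(gt.surface_um) == 0.0

    @pytest.mark.parametrize("family", ["gaussian", "tanh-crater"])
    @pytest.mark.parametrize("tilt", [(0.0, 0.0), (40.0, -25.0)])
    def test_metric_depression_matches_independent_evaluation(self, family, tilt):
        p = small_phantom(
            pit_depth_um=100.0, pit_family=family, tilt_um_per_mm=tilt, jitter_sigma_px=0.0
        )
        assert analytic_depression(p) == pytest.approx(brute_force_depression(p), abs=0.1)

    def test_gaussian_depression_closed_form(self):
        p = small_phantom(pit_depth_um=100.0, pit_sigma_um=200.0, jitter_sigma_px=0.0)
        expected = 100.0 * (np.exp(-(150.0**2) / 80000.0) - np.exp(-(500.0**2) / 80000.0))
        assert analytic_depression(p) == pytest.approx(expected, abs=1e-9)

    def test_pit_depth_for_target_inverts_the_metric(self):
        d = pit_depth_for_target(89.3)
        p = small_phantom(pit_depth_um=d)
        assert analytic_depression(p) == pytest.approx(89.3, abs=1e-9)

    def test_jitter_shifts_recorded_equal_shifts_applied(self):
        """Read the rendered edge back per B-scan and compare with the record."""
        p = small_phantom(
            pit_depth_um=0.0, jitter_sigma_px=5.0, speckle_contrast=0.0, additive_noise=0.0
        )
        vol, gt = generate_oct_phantom(p)
        # flat surface: the ILM edge of B-scan b sits at reference + shift_b
        edge = np.argmax(np.diff(vol.data.mean(axis=1), axis=-1), axis=-1)
        readback = edge - np.median(edge)
        recorded = gt.shifts_px - np.median(gt.shifts_px)
        assert np.abs(readback - recorded).max() < 1.0  # integer-argmax readback
        assert len(gt.shifts_px) == p.n_bscans

    def test_seeded_generation_is_bit_reproducible(self):
        p = small_phantom(seed=42)
        v1, g1 = generate_oct_phantom(p)
        v2, g2 = generate_oct_phantom(p)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(g1.shifts_px, g2.shifts_px)

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError, match="pit diameter"):
            small_phantom(pit_sigma_um=500.0)
        with pytest.raises(ValueError, match="spacing"):
            small_phantom(lateral_spacing_um=0.0)
        with pytest.raises(ValueError, match="jitter"):
            small_phantom(jitter_shifts_px=np.zeros(3))


class TestERGGenerator:
    def test_null_waveform_is_flat_with_zero_features(self):
        p = ERGParams(
            a_amplitude_uv=0.0, b_amplitude_uv=0.0, op_amplitude_uv=0.0, noise_sigma_uv=0.0,
            baseline_uv=12.0,
        )
        tr, gt = generate_erg_trace(p)
        assert np.allclose(tr.voltage_uv, 12.0)
        assert gt.erg_features["a_amplitude_uv"] == 0.0
        assert gt.erg_features["b_amplitude_uv"] == 0.0
        assert gt.erg_features["op_rms_uv"] == 0.0

    def test_a_wave_amplitude_is_analytic_lobe_depth(self):
        p = ERGParams(
            a_amplitude_uv=200.0, b_amplitude_uv=0.0, op_amplitude_uv=0.0, noise_sigma_uv=0.0
        )
        tr, gt = generate_erg_trace(p)
        pre = tr.time_ms < 0
        depth = tr.voltage_uv[pre].mean() - tr.voltage_uv.min()
        assert depth == pytest.approx(200.0, rel=1e-6)
        assert gt.erg_features["a_amplitude_uv"] == pytest.approx(200.0, rel=1e-6)
        assert gt.erg_features["a_implicit_time_ms"] == pytest.approx(15.0, abs=0.5)

    def test_op_packet_filling_window_has_sinusoid_rms(self):
        # packet window wider than the 20-70 ms RMS window -> pure sinusoid there
        p = ERGParams(
            a_amplitude_uv=0.0,
            b_amplitude_uv=0.0,
            op_amplitude_uv=20.0,
            op_frequency_hz=150.0,
            op_window_ms=(10.0, 80.0),
            noise_sigma_uv=0.0,
        )
        _, gt = generate_erg_trace(p)
        assert gt.erg_features["op_rms_uv"] == pytest.approx(20.0 / np.sqrt(2), rel=0.02)

    def test_record_must_extend_past_stimulus(self):
        with pytest.raises(ValueError, match="100 ms"):
            ERGParams(record_ms=550.0)

    def test_out_of_band_packet_rejected(self):
        with pytest.raises(ValueError, match="75-300"):
            ERGParams(op_frequency_hz=50.0)


class TestAxonFieldGenerator:
    def test_zero_density_gives_empty_field(self):
        f = generate_axon_field(AxonFieldParams(density_per_mm2=0.0))
        assert len(f) == 0

    def test_poisson_count_matches_expectation_over_seeds(self):
        p = AxonFieldParams(density_per_mm2=360_000.0, semi_axes_mm=(0.28, 0.25))
        area = np.pi * 0.28 * 0.25
        lam = 360_000.0 * area
        counts = [len(generate_axon_field(replace(p, seed=s))) for s in range(200)]
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_degenerating_fraction_converges(self):
        p = AxonFieldParams(degenerating_fraction=0.094, seed=5)
        f = generate_axon_field(p)
        n = len(f)
        se = np.sqrt(0.094 * 0.906 / n)
        assert abs(f.degenerating.mean() - 0.094) < 3 * se

    def test_all_points_inside_boundary(self):
        f = generate_axon_field(AxonFieldParams(seed=2))
        assert bool(np.all(f.boundary.contains(f.xy_mm)))


class TestStudyDataset:
    def test_null_model_gives_identical_cells(self):
        d = StudyDesign(
            depression_means_um={
                e: {p: (50.0,) for p in ("pre", "loop", "post")} for e in ("treated", "untreated")
            },
            erg_loop_multiplier={"treated": (1.0,), "untreated": (1.0,)},
            noise_sd={k: (0.0, 0.0) for k in (
                "onh_depression_um", "erg_a_uv", "erg_b_uv", "erg_op_rms_uv", "iop_mmhg")},
        )
        ds = generate_study_dataset(d)
        dep = ds.endpoints[ds.endpoints.endpoint == "onh_depression_um"]
        assert np.allclose(dep.value, 50.0)

    def test_programmed_weekly_progression_is_recovered(self):
        """Loop-on depression means across seeds track 89.3 -> +131% -> +140%."""
        vals = {1: [], 5: [], 9: []}
        for s in range(25):
            ds = generate_study_dataset(StudyDesign(seed=s))
            t = ds.endpoints
            loop = t[
                (t.endpoint == "onh_depression_um") & (t.eye == "treated") & (t.procedure == "loop")
            ]
            for w, m in loop.groupby("week").value.mean().items():
                vals[w].append(m)
        m1, m5, m9 = (np.mean(vals[w]) for w in (1, 5, 9))
        assert m1 == pytest.approx(89.3, abs=6.0)
        assert m9 / m1 == pytest.approx(214.3 / 89.3, rel=0.1)
        assert m5 / m1 == pytest.approx(206.3 / 89.3, rel=0.1)

    def test_loop_erg_multiplier_flows_through_feature_extraction(self):
        """Realized loop-wear traces carry ~4x the pre-loop b-wave at week 1."""
        d = StudyDesign(noise_sd={k: (0.0, 0.0) for k in (
            "onh_depression_um", "erg_a_uv", "erg_b_uv", "erg_op_rms_uv", "iop_mmhg")})
        ds = generate_study_dataset(d)
        pre, _ = ds.realize_erg("S1", "treated", 1, "pre")
        loop, _ = ds.realize_erg("S1", "treated", 1, "loop")
        f_pre = extract_features(pre)
        f_loop = extract_features(loop)
        assert f_loop.b_amplitude_uv / f_pre.b_amplitude_uv == pytest.approx(4.0, rel=0.1)

    def test_refuses_single_subject(self):
        with pytest.raises(ValueError, match="2 subjects"):
            StudyDesign(n_subjects=1)

    def test_realized_phantom_matches_cell_depression(self):
        ds = generate_study_dataset(StudyDesign(seed=1))
        cell = ds.cell_value("S2", "treated", 5, "loop", "onh_depression_um")
        _, gt = ds.realize_oct(
            "S2", "treated", 5, "loop",
            n_bscans=96, n_ascans=96, n_depth=512, lateral_spacing_um=14.0,
        )
        assert gt.d_true_um == pytest.approx(max(cell, 0.0), abs=1e-6)
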
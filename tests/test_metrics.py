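"""Per-turn metric tests: resultants, radii, radial force, energy, summaries."""
import numpy as np
import pytest
from conftest import GENTLE_COURSE, GENTLE_SEGMENTATION, QUIET, circle_radius_kasa, make_synced
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from gsforce import (
    AthleteProfile,
    CohortSpec,
    CourseConfig,
    PipelineConfig,
    process_run,
    run_pipeline,
    segment_run,
    simulate_run,
)
from gsforce.metrics import (
    delta_emech_per_vin,
    limb_difference,
    process_metrics,
    radial_force,
    radial_series,
    ratio_of_forces,
    resultant_force,
    summarize_run,
    summarize_turn,
    turn_radius,
)
from gsforce.segmentation import TurnBoundary


class TestResultant:
    @pytest.mark.parametrize("fx,fy,fz,expected", [(0, 0, 0, 0.0), (3, 4, 0, 5.0)])
    def test_known_values(self, fx, fy, fz, expected):
        assert resultant_force(fx, fy, fz) == pytest.approx(expected)

    def test_matches_brute_force_norm(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(3, 200))
        oracle = np.array([np.sqrt(v[0, i] ** 2 + v[1, i] ** 2 + v[2, i] ** 2)
                           for i in range(200)])
        np.testing.assert_allclose(resultant_force(*v), oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_joint_rotation(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(3, 50))
        rot = Rotation.random(rng=rng).as_matrix() @ v
        np.testing.assert_allclose(resultant_force(*rot), resultant_force(*v), atol=1e-10)


class TestLimbDifference:
    def test_equal_limbs_zero(self):
        _, mean, _ = limb_difference(np.full(10, 0.8), np.full(10, 0.8))
        assert mean == pytest.approx(0.0)

    def test_single_limb_is_one(self):
        _, mean, _ = limb_difference(np.full(10, 0.8), np.zeros(10))
        assert mean == pytest.approx(1.0)

    def test_printed_course_means_consistent(self):
        """Constant 1.06/0.54 BW: diff = 0.52/1.60 = 0.325 (printed 0.32)."""
        _, mean, _ = limb_difference(1.06, 0.54)
        assert mean == pytest.approx(0.325)

    def test_zero_total_samples_excluded_and_counted(self):
        f_out = np.array([1.0, 0.0, 1.0])
        f_ins = np.array([0.5, 0.0, 0.5])
        diff, mean, n_excl = limb_difference(f_out, f_ins)
        assert n_excl == 1
        assert np.isnan(diff[1]) and mean == pytest.approx(0.5 / 1.5)


class TestTurnRadius:
    @staticmethod
    def _circle(r=30.0, n=400, z=0.0):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.vstack([r * np.cos(th), r * np.sin(th), np.full(n, z)])

    def test_unit_circle_exact(self):
        r, _, _ = turn_radius(self._circle(1.0), spacing=5)
        np.testing.assert_allclose(r, 1.0, rtol=1e-9)

    def test_collinear_points_capped_and_flagged(self):
        line = np.vstack([np.linspace(0, 100, 200), np.zeros(200), np.zeros(200)])
        r, _, bad = turn_radius(line, spacing=10)
        assert np.all(r == 1000.0) and bad.all()

    def test_thirty_metre_circle_clean_and_noisy(self):
        pts = self._circle(30.0)
        r, _, _ = turn_radius(pts, spacing=10)
        assert abs(r.mean() - 30.0) / 30.0 < 1e-3
        rng = np.random.default_rng(0)
        r_n, _, _ = turn_radius(pts + rng.normal(0, 0.05, pts.shape), spacing=10)
        assert abs(r_n.mean() - 30.0) / 30.0 < 0.03

    def test_kasa_oracle_agreement(self):
        pts = self._circle(30.0)
        rng = np.random.default_rng(3)
        noisy = pts + rng.normal(0, 0.02, pts.shape)
        r, _, _ = turn_radius(noisy, spacing=10)
        assert r.mean() == pytest.approx(circle_radius_kasa(noisy), rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            turn_radius(np.zeros((3, 50)), spacing=60)


class TestRadialForce:
    def test_zero_speed_flat_slope(self):
        assert radial_force(0.0, 20.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_hand_computed_flat_slope(self):
        """v=14, r=20, flat: (196/20)/9.81 = 0.999 BW."""
        assert radial_force(14.0, 20.0, 0.0, 0.3) == pytest.approx(0.9989, abs=1e-3)

    def test_straight_glide_gravity_term_only(self):
        """r -> inf on a 25 deg slope, heading across: sin(25deg) = 0.423 BW."""
        out = radial_force(15.0, 1e12, np.radians(25.0), 0.0)
        assert out == pytest.approx(np.sin(np.radians(25.0)), abs=1e-4)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            radial_force(10.0, 0.0, 0.0, 0.0)

    def test_ratio_of_forces(self):
        assert ratio_of_forces(1.0, 1.0) == pytest.approx(1.0)
        assert ratio_of_forces(1.06, 1.60) == pytest.approx(0.6625)
        with pytest.raises(ValueError):
            ratio_of_forces(1.0, 0.0)

    def test_geometric_projection_matches_closed_form_on_circle(self):
        """Dual route: radial_series' gravity projection vs the formula.

        Constant-speed 30 m circle on flat ground: F_r = v^2/(r g) and the
        projected gravity term vanishes.
        """
        v, r = 14.0, 30.0
        t = np.arange(0, 2 * np.pi * r / v, 0.005)
        th = v * t / r
        pos = np.vstack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
        synced = make_synced(t, np.ones_like(t), np.ones_like(t), pos)
        r_s, f_r, _, _ = radial_series(synced, spacing=60)
        mid = slice(200, -200)
        closed = radial_force(v, r, 0.0, 0.0)
        assert np.abs(f_r[mid] - closed).max() / closed < 0.005
        assert np.abs(r_s[mid] - r).max() / r < 0.005


class TestEnergy:
    def test_hand_computed_dissipation(self):
        """v 15->14 m/s over a 9 m drop: ((196-225)/2 - 9.81*9)/15 = -6.853."""
        assert delta_emech_per_vin(15.0, 14.0, 9.0, 0.0) == pytest.approx(-6.853, abs=1e-3)

    def test_conservative_turn_is_zero(self):
        # v_out^2/2 + g z_out == v_in^2/2 + g z_in
        v_in, z_in, z_out = 15.0, 9.0, 0.0
        v_out = np.sqrt(v_in**2 + 2 * 9.81 * (z_in - z_out))
        assert delta_emech_per_vin(v_in, v_out, z_in, z_out) == pytest.approx(0.0, abs=1e-12)

    def test_steady_speed_drop_matches_printed_scale(self):
        """Constant 15.6 m/s with a 9.33 m drop per turn: -5.87 J*s/kg/m,
        inside the printed course spread -5.59 +/- 0.52."""
        out = delta_emech_per_vin(15.6, 15.6, 9.33, 0.0)
        assert out == pytest.approx(-5.868, abs=1e-3)
        assert -5.59 - 2 * 0.52 < out < -5.59 + 2 * 0.52

    def test_invalid_entry_velocity(self):
        with pytest.raises(ValueError):
            delta_emech_per_vin(0.0, 10.0, 1.0, 0.0)


class TestSummaries:
    @staticmethod
    def _constant_run(f_left=1.0, f_right=0.5, v=12.0, duration=2.0):
        t = np.arange(0, duration + 3.0, 0.005)
        pos = np.vstack([0.001 * np.sin(t), v * t, np.zeros_like(t)])
        n = t.size
        return make_synced(t, np.full(n, f_left), np.full(n, f_right), pos)

    def test_constant_force_turn(self):
        synced = self._constant_run()
        rec = summarize_turn(synced, TurnBoundary(3, 0.5, 2.5, "speed"))
        assert rec.f_tot == pytest.approx(1.5, abs=1e-9)
        assert rec.f_max == pytest.approx(1.5, abs=1e-9)
        assert rec.f_tot == pytest.approx(rec.f_out + rec.f_ins, abs=1e-12)

    def test_straight_constant_speed_length(self):
        v, dur = 12.0, 2.0
        synced = self._constant_run(v=v)
        rec = summarize_turn(synced, TurnBoundary(3, 0.5, 0.5 + dur, "speed"))
        # the half-open sample window spans duration - dt
        assert rec.length == pytest.approx(v * (dur - 0.005), rel=1e-6)

    def test_printed_means_compose(self):
        """F_out 1.06 + F_ins 0.54 = F_tot 1.60 BW (course row identity)."""
        synced = self._constant_run(f_left=1.06, f_right=0.54)
        rec = summarize_turn(synced, TurnBoundary(3, 0.5, 2.5, "speed"))
        assert rec.f_tot == pytest.approx(1.60, abs=1e-12)

    def test_turn_means_additive_on_simulated_run(self, noisy_sim):
        synced = process_run(noisy_sim[0])
        summary = process_metrics(synced, segment_run(synced))
        np.testing.assert_allclose(
            summary.turns["f_tot"], summary.turns["f_out"] + summary.turns["f_ins"],
            atol=1e-12,
        )

    def test_course_mean_is_mean_of_turn_means(self, noisy_sim):
        synced = process_run(noisy_sim[0])
        summary = process_metrics(synced, segment_run(synced))
        assert summary.course_means["f_tot"] == pytest.approx(
            summary.turns["f_tot"].mean(), abs=1e-12
        )

    def test_identical_turns_give_equal_section_and_course_means(self):
        synced = self._constant_run(duration=12.0)
        recs = [
            summarize_turn(synced, TurnBoundary(i, 0.5 + k, 1.5 + k, s))
            for k, (i, s) in enumerate([(3, "speed"), (6, "overspeed"), (11, "flat")])
        ]
        summary = summarize_run(recs, course_time=10.0)
        for sec in ("speed", "overspeed", "flat"):
            assert summary.section_means.loc[sec, "f_tot"] == pytest.approx(
                summary.course_means["f_tot"]
            )


class TestPipelineProperties:
    def test_frictionless_interior_turns_conserve_energy(self):
        """Full conditioning then metrics on a gentle frictionless run:
        no spurious dissipation above 1e-4."""
        course = CourseConfig(**GENTLE_COURSE)
        ath = AthleteProfile(dissipation_coeff=0.0, v_start_ms=7.0, **QUIET)
        synced = process_run(simulate_run(course, ath)[0])
        summary = process_metrics(synced, segment_run(synced, GENTLE_SEGMENTATION))
        assert np.abs(summary.turns["de_mech_per_vin"]).max() < 1e-4

    def test_dissipation_ranking_recovered_noise_free(self, noise_free_pipeline_result):
        res = noise_free_pipeline_result
        measured = [s.course_means["de_mech_per_vin"] for s in res.summaries]
        injected = [-t.dissipation_coeff for t in res.truths]
        assert spearmanr(measured, injected).statistic == pytest.approx(1.0)

    def test_radial_force_quasi_identity(self, pipeline_result):
        r3 = pipeline_result.report.level3["course"]
        assert r3.model_r2 > 0.99
        assert set(r3.entered) == {"F_tot", "RF"}
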
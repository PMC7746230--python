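"""Generator self-consistency and emulated acquisition protocol."""
import numpy as np
import pytest

from afmbone import PullScenario, ValidationError
from afmbone.core import APPROACH, DWELL, RETRACT
from afmbone.synthetic import (APPROACH_VELOCITY, CONTACT_THRESHOLD,
                               DWELL_TIME, RETRACT_VELOCITY, CohortSpec,
                               analytic_pull_truth,
                               generate_approach_retract_cycle,
                               generate_paired_cohort,
                               generate_retraction_curve,
                               generate_stiff_surface_set,
                               generate_thermal_series, model_force)


class TestPullScenario:
    def test_rejects_non_increasing_lengths(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            PullScenario(rupture_events=[(2e-7, 1e-9), (1e-7, 1e-9)])

    def test_rejects_non_positive_peaks(self):
        with pytest.raises(ValidationError, match="positive"):
            PullScenario(rupture_events=[(2e-7, 0.0)])

    def test_triangle_exponent_is_one(self):
        sc = PullScenario(rupture_events=[(5e-7, 1e-9)], shape="triangle")
        assert sc.event_spans()[0][3] == 1.0

    def test_wlc_exponent_clipped(self):
        sc = PullScenario(rupture_events=[(10e-9, 1e-9), (2.5e-6, 1e-9)],
                          persistence_scale=200e-9)
        spans = sc.event_spans()
        assert spans[0][3] == 1.0          # short span clips up to 1
        assert spans[1][3] == 8.0          # long span clips down to 8


class TestAnalyticTruth:
    def test_triangle_area(self):
        sc = PullScenario(rupture_events=[(100e-9, 1.0e-9)], shape="triangle")
        truth = analytic_pull_truth(sc)
        assert truth.true_energy == pytest.approx(5.0e-17, rel=1e-12)
        assert truth.true_max_force == pytest.approx(1.0e-9)
        assert truth.true_pulling_length == pytest.approx(100e-9)

    def test_multi_event_sum(self):
        sc = PullScenario(baseline_noise_sd=0.0)
        truth = analytic_pull_truth(sc)
        expected = sum(pk * (s1 - s0) / (p + 1.0)
                       for s0, s1, pk, p in sc.event_spans())
        assert truth.true_energy == pytest.approx(expected, rel=1e-12)

    def test_truth_matches_quadrature_of_model(self):
        sc = PullScenario(baseline_noise_sd=0.0)
        truth = analytic_pull_truth(sc)
        s = np.linspace(0.0, truth.true_pulling_length, 400_001)
        riemann = float(np.trapezoid(-model_force(sc, s), s))
        assert riemann == pytest.approx(truth.true_energy, rel=5e-4)


class TestRetractionCurve:
    def test_deterministic(self, calib, scenario):
        a, _ = generate_retraction_curve(scenario, calib, seed=42)
        b, _ = generate_retraction_curve(scenario, calib, seed=42)
        np.testing.assert_array_equal(a.deflection_raw, b.deflection_raw)
        c, _ = generate_retraction_curve(scenario, calib, seed=43)
        assert not np.array_equal(a.deflection_raw, c.deflection_raw)

    def test_rupture_is_vertical_drop(self, calib, clean_scenario):
        cycle, _ = generate_retraction_curve(clean_scenario, calib, seed=0)
        # separation correction recovers true s; ruptures are duplicate
        # separations with the peak and baseline forces
        from afmbone.calibration import deflection_to_force
        r = deflection_to_force(cycle, calib)
        dup = np.flatnonzero(np.isclose(np.diff(r.separation), 0.0, atol=1e-15))
        assert dup.size == len(clean_scenario.rupture_events)

    def test_weak_event_warns(self, calib):
        sc = PullScenario(rupture_events=[(5e-7, 30e-12)],
                          baseline_noise_sd=20e-12)
        with pytest.warns(UserWarning, match="below noise floor"):
            _, truth = generate_retraction_curve(sc, calib, seed=1)
        assert "below noise floor" in truth.warning


class TestFullCycle:
    def test_protocol_segments_and_velocities(self, calib, clean_scenario):
        cycle = generate_approach_retract_cycle(clean_scenario, calib, seed=0)
        labels = cycle.segment_label
        assert set(labels) == {APPROACH, DWELL, RETRACT}
        app = labels == APPROACH
        ret = labels == RETRACT
        dwell = labels == DWELL
        # piezo speed over each moving segment matches the protocol
        t, z = cycle.time, cycle.z_position
        v_app = np.abs(np.diff(z[app]) / np.diff(t[app]))
        np.testing.assert_allclose(np.median(v_app), APPROACH_VELOCITY, rtol=1e-6)
        v_ret = np.abs(np.diff(z[ret]) / np.diff(t[ret]))
        assert np.median(v_ret) == pytest.approx(RETRACT_VELOCITY, rel=1e-6)
        dwell_t = t[dwell]
        assert dwell_t[-1] - t[app][-1] == pytest.approx(DWELL_TIME, rel=1e-6)

    def test_contact_threshold_reached(self, calib, clean_scenario):
        cycle = generate_approach_retract_cycle(clean_scenario, calib, seed=0)
        force = calib.spring_constant * calib.invols * cycle.deflection_raw
        peak = force[cycle.segment_label == APPROACH].max()
        # the approach stops within one sample of the 15 nN trigger
        step = clean_scenario.contact_stiffness * clean_scenario.sampling_interval
        assert CONTACT_THRESHOLD <= peak <= CONTACT_THRESHOLD + step

    def test_time_strictly_increasing_with_noise(self, calib, scenario):
        cycle = generate_approach_retract_cycle(scenario, calib, seed=3)
        assert np.all(np.diff(cycle.time) > 0)


class TestCalibrationInputs:
    def test_stiff_surface_slope(self):
        curves = generate_stiff_surface_set(50e-9, n_curves=3, noise_sd=0.0)
        assert len(curves) == 3
        c = curves[0]
        loaded = c.deflection_raw > 0
        slope = np.polyfit(c.z_position[loaded], c.deflection_raw[loaded], 1)[0]
        assert 1.0 / slope == pytest.approx(50e-9, rel=1e-9)

    def test_thermal_series_variance(self):
        from scipy.constants import k as kB
        series = generate_thermal_series(0.05, temperature=298.0,
                                         n_samples=200_000, seed=5)
        assert series.var(ddof=1) == pytest.approx(kB * 298.0 / 0.05, rel=0.02)


class TestPairedCohort:
    def test_schema_and_pairing(self):
        specs, assays = generate_paired_cohort(CohortSpec(seed=11))
        assert len(specs) == 2 * 2 * 7          # genotypes x limbs x pairs
        assert set(specs.treatment) == {"treated", "control"}
        per_animal = specs.groupby("animal_id").limb.nunique()
        assert (per_animal == 2).all()
        assert len(assays) == len(specs) * 3    # triplicates
        assert "kc_true" not in specs.columns   # truth is not leaked

    def test_kc_round_trips_through_engine(self):
        from afmbone.mechanics import default_geometry_factor, kc_unit_load
        spec = CohortSpec(kc_effect=0.18, seed=7)
        specs, _ = generate_paired_cohort(spec)
        gf = default_geometry_factor()
        kc = np.array([row.p_max_n * kc_unit_load(
            row.span_m, row.r_outer_m, row.r_inner_m,
            row.half_crack_angle_deg, gf) for row in specs.itertuples()])
        controls = kc[(specs.treatment == "control").to_numpy()]
        assert controls.mean() == pytest.approx(spec.kc_control_mean, rel=0.10)

    def test_effect_direction(self):
        specs, _ = generate_paired_cohort(CohortSpec(kc_effect=0.18, seed=3))
        from afmbone.mechanics import default_geometry_factor, kc_unit_load
        gf = default_geometry_factor()
        specs = specs.assign(kc=[row.p_max_n * kc_unit_load(
            row.span_m, row.r_outer_m, row.r_inner_m,
            row.half_crack_angle_deg, gf) for row in specs.itertuples()])
        means = specs.groupby("treatment").kc.mean()
        assert means["treated"] > means["control"]
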
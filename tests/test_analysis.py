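"""Curve splitting, contact alignment, and the three pull metrics."""
import numpy as np
import pytest

from afmbone import (PullScenario, RunConfig, ValidationError,
                     energy_dissipation, find_contact_point,
                     max_adhesion_force, process_batch, process_curve,
                     pulling_length, split_curve)
from afmbone.analysis import CurveRejected, estimate_noise_sd
from afmbone.calibration import deflection_to_force
from afmbone.core import ForceCurveCycle, RetractionSegment
from afmbone.synthetic import (analytic_pull_truth,
                               generate_approach_retract_cycle,
                               generate_retraction_curve)


def triangle_segment(depth=1.0e-9, base=100e-9, n=101):
    """Hand-built triangular adhesion pulse: exact area depth*base/2."""
    sep = np.linspace(0.0, base, n)
    force = -depth * sep / base
    sep = np.append(sep, [base, base + 50e-9])
    force = np.append(force, [0.0, 0.0])
    return RetractionSegment(separation=sep, force=force)


class TestSplitCurve:
    def test_labeled_split(self, calib, scenario):
        cycle = generate_approach_retract_cycle(scenario, calib, seed=0)
        approach, retract = split_curve(cycle)
        assert set(approach.segment_label) == {"approach"}
        assert set(retract.segment_label) == {"retract"}
        assert len(approach) + len(retract) < len(cycle)  # dwell dropped

    def test_unlabeled_split_at_closest_approach(self):
        z = np.concatenate([np.linspace(0, 1e-6, 50),
                            np.linspace(1e-6, 0, 50)[1:]])
        c = ForceCurveCycle(time=np.arange(99, dtype=float), z_position=z,
                            deflection_raw=np.zeros(99))
        approach, retract = split_curve(c)
        assert len(approach) == 50
        assert retract.z_position[0] == approach.z_position[-1]

    def test_monotone_z_cannot_split(self):
        c = ForceCurveCycle(time=np.arange(10, dtype=float),
                            z_position=np.linspace(0, 1e-6, 10),
                            deflection_raw=np.zeros(10))
        with pytest.raises(ValidationError, match="monotone"):
            split_curve(c)


class TestNoiseEstimate:
    def test_white_noise_recovered(self):
        rng = np.random.default_rng(8)
        f = rng.normal(0.0, 20e-12, 5000)
        assert estimate_noise_sd(f) == pytest.approx(20e-12, rel=0.05)

    def test_robust_to_trend_and_jumps(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 1, 5000)
        f = -2e-9 * x + rng.normal(0.0, 20e-12, 5000)
        f[2500:] += 1.5e-9                     # a rupture-sized jump
        assert estimate_noise_sd(f) == pytest.approx(20e-12, rel=0.10)

    def test_clean_signal_near_zero(self, calib, clean_scenario):
        cycle, _ = generate_retraction_curve(clean_scenario, calib, seed=0)
        r = deflection_to_force(cycle, calib)
        assert estimate_noise_sd(r.force) < 1e-13


class TestContactPoint:
    def test_clean_alignment_exact(self, calib, clean_scenario):
        cycle, truth = generate_retraction_curve(clean_scenario, calib, seed=0)
        seg = find_contact_point(deflection_to_force(cycle, calib))
        # last rupture sits exactly at the true pulling length
        i = int(np.argmin(np.abs(seg.separation - truth.true_pulling_length)))
        assert abs(seg.separation[i] - truth.true_pulling_length) < 1e-12

    def test_noisy_alignment_sub_sample(self, calib, scenario):
        worst = 0.0
        for seed in range(5):
            cycle, truth = generate_retraction_curve(scenario, calib, seed=seed)
            seg = find_contact_point(deflection_to_force(cycle, calib))
            i = int(np.argmin(seg.force))
            # deepest adhesion is at the second rupture (400 nm)
            worst = max(worst, abs(seg.separation[i] - 400e-9))
        assert worst < scenario.sampling_interval

    def test_all_repulsive_rejected(self, calib):
        c = ForceCurveCycle(time=np.arange(20, dtype=float),
                            z_position=np.linspace(1e-6, 0, 20),
                            deflection_raw=np.linspace(1.0, 0.1, 20))
        r = deflection_to_force(c, calib)
        with pytest.raises(CurveRejected, match="all_repulsive"):
            find_contact_point(r)

    def test_requires_calibration(self):
        c = ForceCurveCycle(time=np.arange(10, dtype=float),
                            z_position=np.linspace(1e-6, 0, 10),
                            deflection_raw=np.zeros(10))
        with pytest.raises(ValidationError, match="calibrated"):
            find_contact_point(c)


class TestMaxAdhesion:
    def test_triangle(self):
        seg = triangle_segment()
        mf = max_adhesion_force(seg)
        assert mf.force == pytest.approx(1.0e-9, rel=1e-12)
        assert mf.separation == pytest.approx(100e-9, rel=1e-12)

    def test_flat_curve_is_zero(self):
        seg = RetractionSegment(separation=np.linspace(0, 1e-6, 50),
                                force=np.zeros(50))
        assert max_adhesion_force(seg).force == 0.0

    def test_repulsive_samples_ignored(self):
        seg = RetractionSegment(separation=np.array([-1e-9, 0.0, 1e-9, 2e-9]),
                                force=np.array([5e-9, 0.0, -1e-9, 0.0]))
        assert max_adhesion_force(seg).force == pytest.approx(1e-9)


class TestPullingLength:
    def test_triangle_end(self):
        seg = triangle_segment()
        pl = pulling_length(seg, 1.0e-9, noise_floor_factor=0.0)
        assert pl == pytest.approx(100e-9, rel=1e-12)

    def test_threshold_monotone(self):
        # a stricter threshold can only shorten the pulling length
        seg = triangle_segment()
        lengths = [pulling_length(seg, 1.0e-9, threshold_fraction=f,
                                  noise_floor_factor=0.0)
                   for f in (0.01, 0.05, 0.2, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_zero_max_force(self):
        seg = triangle_segment()
        assert pulling_length(seg, 0.0) == 0.0

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            pulling_length(triangle_segment(), 1e-9, threshold_fraction=1.5)

    def test_noise_floor_suppresses_tail_blips(self):
        seg = triangle_segment()
        force = seg.force.copy()
        force[-1] = -0.02e-9      # isolated blip past the rupture, 2% of max
        noisy = RetractionSegment(separation=seg.separation, force=force)
        bare = pulling_length(noisy, 1.0e-9, noise_floor_factor=0.0)
        assert bare == pytest.approx(noisy.separation[-1])       # fooled
        # the floored rule keeps the true end (sigma-hat sees the blip as
        # an outlier in the differences, not as baseline noise)
        robust = pulling_length(noisy, 1.0e-9, noise_floor_factor=5.0)
        assert robust <= bare


class TestEnergyDissipation:
    def test_triangle_exact(self):
        seg = triangle_segment()
        e = energy_dissipation(seg, 100e-9)
        assert e == pytest.approx(5.0e-17, rel=1e-12)

    def test_positive_overshoot_excluded(self):
        sep = np.linspace(0, 100e-9, 101)
        force = -1e-9 * np.ones(101)
        force[40:60] = +2e-9                  # repulsive excursion
        seg = RetractionSegment(separation=sep, force=force)
        e = energy_dissipation(seg, 100e-9)
        assert e < 1e-9 * 100e-9              # overshoot did not add area

    def test_pl_beyond_span_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            energy_dissipation(triangle_segment(), 1.0)

    def test_zero_pl(self):
        assert energy_dissipation(triangle_segment(), 0.0) == 0.0


class TestProcessCurve:
    def test_full_cycle_matches_truth(self, calib, clean_scenario):
        cycle = generate_approach_retract_cycle(clean_scenario, calib, seed=0)
        truth = analytic_pull_truth(clean_scenario)
        m = process_curve(cycle, calib)
        assert not m.rejected
        assert m.energy == pytest.approx(truth.true_energy, rel=1e-3)
        assert m.max_force == pytest.approx(truth.true_max_force, rel=1e-6)
        assert m.pulling_length == pytest.approx(truth.true_pulling_length,
                                                 abs=clean_scenario.sampling_interval)

    def test_retraction_only_cycle(self, calib, scenario):
        cycle, truth = generate_retraction_curve(scenario, calib, seed=1)
        m = process_curve(cycle, calib)
        assert not m.rejected
        assert m.energy == pytest.approx(truth.true_energy, rel=0.05)

    def test_flat_curve_policies(self, calib):
        n = 400
        z = np.concatenate([np.linspace(0, 1e-6, n // 2),
                            np.linspace(1e-6, 0, n // 2)[1:]])
        # repulsive contact bump at closest approach, no adhesion
        defl = np.where(z > 0.9e-6, (z - 0.9e-6) / 50e-9 * 5, 0.0)
        c = ForceCurveCycle(time=np.arange(z.size, dtype=float),
                            z_position=z, deflection_raw=defl)
        m = process_curve(c, calib, RunConfig(flat_curve_policy="reject"))
        assert m.rejected and m.rejection_reason == "all_repulsive"
        m = process_curve(c, calib, RunConfig(flat_curve_policy="zero"))
        assert not m.rejected and m.energy == 0.0 and m.max_force == 0.0

    def test_batch_keeps_order_and_ids(self, calib, scenario):
        cycles = []
        for i in range(3):
            cy, _ = generate_retraction_curve(scenario, calib, seed=i)
            cy.metadata["source_id"] = f"pull_{i}"
            cycles.append(cy)
        out = process_batch(cycles, calib)
        assert [m.source_id for m in out] == ["pull_0", "pull_1", "pull_2"]

    def test_scale_covariance(self, calib):
        # doubling every peak doubles energy and max force, keeps length
        base = PullScenario(baseline_noise_sd=0.0)
        doubled = PullScenario(
            rupture_events=[(l, 2 * p) for l, p in base.rupture_events],
            baseline_noise_sd=0.0)
        ma = process_curve(generate_retraction_curve(base, calib, seed=0)[0], calib)
        mb = process_curve(generate_retraction_curve(doubled, calib, seed=0)[0], calib)
        assert mb.energy == pytest.approx(2 * ma.energy, rel=1e-6)
        assert mb.max_force == pytest.approx(2 * ma.max_force, rel=1e-9)
        assert mb.pulling_length == pytest.approx(ma.pulling_length, abs=1e-10)
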
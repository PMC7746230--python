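"""Synthetic force curves, calibration inputs, and paired bone cohorts.

Everything here carries an explicit ground truth so the analysis chain
can be tested end to end without instrument data.  The emulated
acquisition protocol: the tip starts 3 um from the surface, approaches
at 2.0 um/s until the repulsive contact force reaches 15 nN, dwells
10 s, and retracts at 5.0 um/s; adhesion appears as a train of rupture
events on the retraction trace.

Geometry convention
-------------------
Samples are generated on a uniform grid of *true* tip-sample
separation s.  The recorded piezo coordinate is back-computed as
``z = z_contact - (s - deflection)`` so that the downstream separation
correction (z + InvOLS * deflection, sign-fixed) recovers s exactly.
A real instrument ramps the piezo uniformly instead; the difference
(snap-in/snap-out multivaluedness for soft levers) is deliberately not
modelled — only the enclosed area matters to the pipeline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.constants import k as BOLTZMANN

from .core import (APPROACH, DWELL, RETRACT, CantileverCalibration,
                   ForceCurveCycle, ValidationError)

APPROACH_VELOCITY = 2.0e-6   # m/s
RETRACT_VELOCITY = 5.0e-6    # m/s
DWELL_TIME = 10.0            # s
CONTACT_THRESHOLD = 15e-9    # N, full-contact trigger
MAX_SEPARATION = 3e-6        # m, start/end distance from the surface


@dataclass
class PullScenario:
    """Ground-truth description of one multi-rupture retraction pull.

    rupture_events: (contour_length, peak_adhesion) pairs; contour
    lengths strictly increasing, peaks stored as positive magnitudes.
    Each event's rising limb spans from the previous rupture (or the
    contact point) to its own contour length; the limb shape is
    |F| = peak * x**p with p = clip(span / persistence_scale, 1, 8)
    ("triangle" forces p = 1), dropping to baseline instantaneously at
    rupture so every event has an analytic enclosed area
    peak * span / (p + 1).
    """

    rupture_events: List[Tuple[float, float]] = field(
        default_factory=lambda: [(150e-9, 0.8e-9), (400e-9, 1.2e-9), (800e-9, 0.6e-9)]
    )
    persistence_scale: float = 200e-9
    baseline_noise_sd: float = 20e-12
    max_separation: float = MAX_SEPARATION
    sampling_interval: float = 1e-9
    shape: str = "wlc"           # "wlc" (smooth concave) or "triangle"
    contact_stiffness: float = 0.5   # N/m, repulsive contact slope

    def __post_init__(self):
        lengths = [l for l, _ in self.rupture_events]
        peaks = [p for _, p in self.rupture_events]
        if any(np.diff(lengths) <= 0):
            raise ValidationError("contour lengths must be strictly increasing")
        if any(l >= self.max_separation for l in lengths):
            raise ValidationError("contour lengths must be < max_separation")
        if any(p <= 0 for p in peaks):
            raise ValidationError("peak adhesions must be positive magnitudes")
        if self.shape not in ("wlc", "triangle"):
            raise ValidationError("shape must be 'wlc' or 'triangle'")
        if self.sampling_interval <= 0 or self.max_separation <= 0:
            raise ValidationError("grid parameters must be positive")

    def event_spans(self) -> List[Tuple[float, float, float, float]]:
        """Per event: (onset, rupture, peak, exponent)."""
        spans = []
        s0 = 0.0
        for length, peak in self.rupture_events:
            span = length - s0
            p = 1.0 if self.shape == "triangle" else float(
                np.clip(span / self.persistence_scale, 1.0, 8.0))
            spans.append((s0, length, peak, p))
            s0 = length
        return spans


@dataclass
class GroundTruthPull:
    true_energy: float
    true_max_force: float
    true_pulling_length: float
    warning: str = ""

    def __post_init__(self):
        if self.true_energy < 0:
            raise ValidationError("true energy must be non-negative")


@dataclass
class CohortSpec:
    """Paired (contralateral-limb) cohort with a known treatment effect.

    Defaults mirror a typical design: 7 animal pairs per genotype, a
    fractional toughness effect (+0.18 for the phosphorylation preset,
    -0.25 for dephosphorylation), and triplicate phospho-assay reads.
    """

    n_pairs: int = 7
    kc_control_mean: float = 4.5        # MPa m^0.5, typical murine femur
    kc_control_sd: float = 0.4          # between-animal SD
    kc_pair_sd: float = 0.25            # limb-level residual SD
    kc_effect: float = 0.18             # fractional change under treatment
    phospho_control_mean: float = 5e-4  # AU/ng
    phospho_control_sd: float = 5e-5
    phospho_pair_sd: float = 4e-5
    phospho_effect: float = 0.3
    replicate_cv: float = 0.03
    n_replicates: int = 3
    protein_ng: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValidationError("need at least 2 animal pairs")
        for sd in (self.kc_control_sd, self.kc_pair_sd,
                   self.phospho_control_sd, self.phospho_pair_sd):
            if sd <= 0:
                raise ValidationError("SDs must be positive")


def model_force(scenario: PullScenario, s) -> np.ndarray:
    """Noise-free adhesion force (N, negative) at separations s >= 0.

    Repulsive contact for s < 0 with slope ``contact_stiffness``.
    """
    s = np.asarray(s, dtype=float)
    f = np.zeros_like(s)
    f[s < 0] = -scenario.contact_stiffness * s[s < 0]  # repulsive, positive
    for s0, s1, peak, p in scenario.event_spans():
        span = s1 - s0
        m = (s >= s0) & (s <= s1)
        f[m] = -peak * ((s[m] - s0) / span) ** p
    return f


def analytic_pull_truth(scenario: PullScenario) -> GroundTruthPull:
    """Exact enclosed area / max force / pulling length of the model."""
    if not scenario.rupture_events:
        return GroundTruthPull(0.0, 0.0, 0.0)
    energy = sum(peak * (s1 - s0) / (p + 1.0)
                 for s0, s1, peak, p in scenario.event_spans())
    max_force = max(peak for _, peak in scenario.rupture_events)
    pulling_length = scenario.rupture_events[-1][0]
    return GroundTruthPull(energy, max_force, pulling_length)


def _sample_pull(scenario: PullScenario, depth: float) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free sampled retraction: repulsive ramp, events, tail.

    Each rupture carries a duplicate separation sample (left limit at
    the peak, right limit at baseline) so the sampled polyline drops
    vertically, exactly like the instantaneous-rupture model.
    """
    h = scenario.sampling_interval
    ss, ff = [], []
    if depth > 0:
        s_c = np.arange(-depth, 0, h)
        ss.append(s_c)
        ff.append(-scenario.contact_stiffness * s_c)
    last = 0.0
    for s0, s1, peak, p in scenario.event_spans():
        s_e = np.arange(s0, s1, h)
        ss.append(s_e)
        ff.append(-peak * ((s_e - s0) / (s1 - s0)) ** p)
        ss.append(np.array([s1]))          # left limit: the event peak
        ff.append(np.array([-peak]))
        last = s1
    tail = np.arange(last, scenario.max_separation + h / 2, h)
    ss.append(tail)
    ff.append(np.zeros(tail.size))
    return np.concatenate(ss), np.concatenate(ff)


def _assemble_cycle(scenario, calibration, s, force, t, label,
                    z_contact, metadata):
    deflection_m = force / calibration.spring_constant
    deflection_raw = deflection_m / calibration.invols
    z = z_contact - (s - deflection_m)
    return ForceCurveCycle(time=t, z_position=z, deflection_raw=deflection_raw,
                           segment_label=np.array([label] * s.size, dtype=object),
                           metadata=metadata)


def generate_retraction_curve(scenario: PullScenario,
                              calibration: CantileverCalibration,
                              seed: int,
                              contact_threshold: float = CONTACT_THRESHOLD,
                              ) -> Tuple[ForceCurveCycle, GroundTruthPull]:
    """One retraction trace starting in repulsive contact.

    Returns the cycle (segment label 'retract' throughout) and the
    analytic ground truth of the noise-free model.  Identical seeds
    give identical output.
    """
    rng = np.random.default_rng(seed)
    depth = contact_threshold / scenario.contact_stiffness
    s, force = _sample_pull(scenario, depth)
    if scenario.baseline_noise_sd > 0:
        force = force + rng.normal(0.0, scenario.baseline_noise_sd, s.size)
    truth = analytic_pull_truth(scenario)
    if scenario.rupture_events:
        floor = 3.0 * scenario.baseline_noise_sd
        weak = [f"event at {l * 1e9:.0f} nm peak below noise floor"
                for l, p in scenario.rupture_events if p < floor]
        if weak:
            truth.warning = "; ".join(weak)
            warnings.warn(truth.warning)
    # index-based clock: duplicate rupture samples share a separation
    t = np.arange(s.size) * scenario.sampling_interval / RETRACT_VELOCITY
    meta = {"velocity_retract": RETRACT_VELOCITY, "seed": seed}
    cycle = _assemble_cycle(scenario, calibration, s, force, t, RETRACT,
                            z_contact=scenario.max_separation, metadata=meta)
    return cycle, truth


def generate_approach_retract_cycle(scenario: PullScenario,
                                    calibration: CantileverCalibration,
                                    contact_threshold: float = CONTACT_THRESHOLD,
                                    seed: int = 0,
                                    dwell_time: float = DWELL_TIME,
                                    dwell_samples: int = 50,
                                    ) -> ForceCurveCycle:
    """Full approach (2.0 um/s) / dwell (10 s) / retract (5.0 um/s) cycle.

    The approach ends when the repulsive contact force reaches
    ``contact_threshold`` (default 15 nN) to within one sample.
    """
    if contact_threshold <= 0:
        raise ValidationError("contact threshold must be positive")
    rng = np.random.default_rng(seed)
    h = scenario.sampling_interval
    depth = contact_threshold / scenario.contact_stiffness
    noise = scenario.baseline_noise_sd

    # approach: separation decreases from max_separation to -depth;
    # adhesion events belong to the retraction, so the approach is flat
    # until repulsive contact.
    s_app = np.arange(scenario.max_separation, -depth - h / 2, -h)
    f_app = np.where(s_app < 0, -scenario.contact_stiffness * s_app, 0.0)
    if noise > 0:
        f_app = f_app + rng.normal(0.0, noise, s_app.size)

    s_ret, f_ret_clean = _sample_pull(scenario, depth=-s_app[-1])
    f_ret = f_ret_clean.copy()
    if noise > 0:
        f_ret = f_ret + rng.normal(0.0, noise, s_ret.size)

    s_dwell = np.full(dwell_samples, s_app[-1])
    f_dwell = np.full(dwell_samples, f_app[-1])
    if noise > 0:
        f_dwell = f_dwell + rng.normal(0.0, noise, dwell_samples)

    k = calibration.spring_constant
    z_c = scenario.max_separation

    def z_of(s, f):
        return z_c - (s - f / k)

    z_app, z_dwell, z_ret = (z_of(s_app, f_app), z_of(s_dwell, f_dwell),
                             z_of(s_ret, f_ret))
    # the clock follows the commanded (noise-free) piezo path at the
    # segment velocities
    zc_app = z_of(s_app, np.where(s_app < 0, -scenario.contact_stiffness * s_app, 0.0))
    zc_ret = z_of(s_ret, f_ret_clean)
    t_app = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(zc_app)))]) / APPROACH_VELOCITY
    t_dwell = t_app[-1] + np.linspace(dwell_time / dwell_samples, dwell_time,
                                      dwell_samples)
    dz_ret = np.abs(np.diff(zc_ret))
    dz_ret = np.maximum(dz_ret, h * 1e-9)      # keep the clock strictly increasing
    t_ret = t_dwell[-1] + (np.concatenate([[h], h + np.cumsum(dz_ret)])
                           / RETRACT_VELOCITY)

    s_all = np.concatenate([s_app, s_dwell, s_ret])
    f_all = np.concatenate([f_app, f_dwell, f_ret])
    t_all = np.concatenate([t_app, t_dwell, t_ret])
    labels = np.array([APPROACH] * s_app.size + [DWELL] * dwell_samples
                      + [RETRACT] * s_ret.size, dtype=object)
    meta = {"velocity_approach": APPROACH_VELOCITY,
            "velocity_retract": RETRACT_VELOCITY,
            "dwell_time": dwell_time,
            "contact_threshold": contact_threshold,
            "seed": seed}
    deflection_m = f_all / k
    z_all = np.concatenate([z_app, z_dwell, z_ret])
    return ForceCurveCycle(time=t_all, z_position=z_all,
                           deflection_raw=deflection_m / calibration.invols,
                           segment_label=labels, metadata=meta)


def generate_stiff_surface_set(invols_true: float, n_curves: int = 10,
                               noise_sd: float = 0.0, seed: int = 0,
                               n_samples: int = 800,
                               contact_fraction: float = 0.5,
                               ) -> List[ForceCurveCycle]:
    """Calibration curves on a nominally infinitely stiff surface.

    On a rigid substrate the tip tracks the piezo one-to-one, so the
    loading part of deflection-vs-z is a line of slope 1/invols (V/m).
    Ten curves is the protocol default.
    """
    if invols_true <= 0:
        raise ValidationError("invols_true must be positive")
    if n_curves < 1:
        raise ValidationError("need at least one curve")
    rng = np.random.default_rng(seed)
    curves = []
    z_span = 200e-9
    for i in range(n_curves):
        z = np.linspace(0.0, z_span, n_samples)  # increasing toward surface
        z_contact = z_span * (1.0 - contact_fraction)
        defl = np.where(z > z_contact, (z - z_contact) / invols_true, 0.0)
        if noise_sd > 0:
            defl = defl + rng.normal(0.0, noise_sd, n_samples)
        t = z / APPROACH_VELOCITY + 1e-12
        curves.append(ForceCurveCycle(
            time=t, z_position=z, deflection_raw=defl,
            segment_label=np.array([APPROACH] * n_samples, dtype=object),
            metadata={"stiff_surface": 1.0, "curve_index": float(i)}))
    return curves


def generate_thermal_series(k_true: float, temperature: float = 298.0,
                            n_samples: int = 1_000_000,
                            sampling_rate: float = 100e3,
                            seed: int = 0) -> np.ndarray:
    """Thermal deflection fluctuations of the free cantilever (metres).

    White Gaussian noise at the equipartition variance k_B*T/k — the
    minimal model honoring the variance-based spring-constant estimator.
    """
    if k_true <= 0 or temperature <= 0:
        raise ValidationError("k_true and temperature must be positive")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(BOLTZMANN * temperature / k_true)
    return rng.normal(0.0, sd, int(n_samples))


def generate_paired_cohort(spec: CohortSpec,
                           genotypes: Sequence[str] = ("WT", "OpnKO"),
                           ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Paired treated/contralateral-control cohort with known effects.

    Per animal: a between-animal baseline draw, then
    control = baseline + residual and
    treated = baseline * (1 + effect) + residual,
    with the treated limb (left/right) randomized per animal.  Phospho
    assay readings are produced in triplicate per limb.

    Returns (specimens, assays) DataFrames in the CSV schemas the
    toughness/phospho commands consume.
    """
    rng = np.random.default_rng(spec.seed)
    spec_rows, assay_rows = [], []
    # nominal murine femur geometry; small per-animal variation
    for g in genotypes:
        for i in range(spec.n_pairs):
            animal = f"{g}_{i:02d}"
            base_kc = rng.normal(spec.kc_control_mean, spec.kc_control_sd)
            base_ph = rng.normal(spec.phospho_control_mean, spec.phospho_control_sd)
            treated_limb = "left" if rng.random() < 0.5 else "right"
            # redraw until the section lies inside the geometry-factor
            # table domain (Rm/t in [1.5, 20]), with a small margin
            while True:
                r_out = rng.normal(0.90e-3, 0.03e-3)
                r_in = rng.normal(0.55e-3, 0.02e-3)
                if 0 < r_in < r_out:
                    ratio = 0.5 * (r_out + r_in) / (r_out - r_in)
                    if 1.6 <= ratio <= 19.0:
                        break
            theta = rng.normal(85.0, 4.0)
            for treatment in ("treated", "control"):
                limb = treated_limb if treatment == "treated" else (
                    "right" if treated_limb == "left" else "left")
                kc = base_kc + rng.normal(0.0, spec.kc_pair_sd)
                ph = base_ph + rng.normal(0.0, spec.phospho_pair_sd)
                if treatment == "treated":
                    kc += base_kc * spec.kc_effect
                    ph += base_ph * spec.phospho_effect
                kc = max(kc, 0.05)
                ph = max(ph, 1e-6)
                sid = f"{animal}_{limb}"
                spec_rows.append(dict(
                    specimen_id=sid, animal_id=animal, limb=limb,
                    genotype=g, treatment=treatment,
                    kc_true=kc, span_m=8e-3, r_outer_m=r_out, r_inner_m=r_in,
                    half_crack_angle_deg=theta,
                    notch_cortex_fraction=float(rng.uniform(0.15, 0.30)),
                ))
                for rep in range(spec.n_replicates):
                    absorb = ph * spec.protein_ng * (
                        1.0 + rng.normal(0.0, spec.replicate_cv))
                    assay_rows.append(dict(
                        specimen_id=sid, animal_id=animal, genotype=g,
                        treatment=treatment, replicate=rep,
                        absorbance_au=absorb, protein_ng=spec.protein_ng))
    specimens = pd.DataFrame(spec_rows)
    assays = pd.DataFrame(assay_rows)
    # back out the maximum load that reproduces each kc_true through the
    # installed geometry-factor table, so the toughness engine round-trips
    from .mechanics import default_geometry_factor, kc_unit_load
    gf = default_geometry_factor()
    p_max = []
    for row in specimens.itertuples():
        kc_per_newton = kc_unit_load(
            span=row.span_m, r_outer=row.r_outer_m, r_inner=row.r_inner_m,
            half_crack_angle_deg=row.half_crack_angle_deg, geometry_factor=gf)
        p_max.append(row.kc_true / kc_per_newton)
    specimens["p_max_n"] = p_max
    specimens = specimens.drop(columns=["kc_true"])
    return specimens, assays
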
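"""Per-pull metrics from calibrated retraction curves.

Three quantities are extracted per pull:

* maximum adhesion force — magnitude of the Y-minimum of the retraction
  trace;
* pulling length — separation from contact to the end of the last
  adhesion excursion exceeding 1% of the maximum force;
* energy dissipation — area enclosed between the adhesive retraction
  trace and the zero-force axis from contact (0, 0) to the pulling
  length, trapezoid rule on the sampled grid, adhesive (negative-force)
  spans only, reported as a positive energy in joules.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .calibration import deflection_to_force
from .config import RunConfig
from .core import (APPROACH, DWELL, RETRACT, CantileverCalibration,
                   ForceCurveCycle, PullMetrics, RetractionSegment,
                   ValidationError)


class CurveRejected(Exception):
    """Internal signal: curve cannot yield metrics; carries the reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def split_curve(cycle: ForceCurveCycle) -> Tuple[ForceCurveCycle, ForceCurveCycle]:
    """Split a cycle into its approach and retraction parts.

    Labeled cycles split by label (dwell assigned to neither).  For
    unlabeled cycles the split is at the point of closest approach —
    the global extremum of the piezo coordinate, which with z
    increasing toward the surface is the global maximum.
    """
    if len(cycle) < 4:
        raise ValidationError("cycle too short to split (need >= 4 samples)")
    if cycle.segment_label is not None and \
            not all(l == "unknown" for l in cycle.segment_label):
        approach = cycle.slice(cycle.segment_label == APPROACH)
        retract = cycle.slice(cycle.segment_label == RETRACT)
        if len(approach.time) < 2 or len(retract.time) < 2:
            raise ValidationError("labeled split left an empty segment")
        return approach, retract
    z = cycle.z_position
    apex = int(np.argmax(z))
    if apex < 1 or apex > len(cycle) - 2:
        raise ValidationError("z is monotone: cycle cannot be split")
    return cycle.slice(slice(0, apex + 1)), cycle.slice(slice(apex, len(cycle)))


def estimate_noise_sd(force: np.ndarray) -> float:
    """Robust baseline-noise SD from first differences.

    Differencing removes slow model trends; the MAD makes the sparse
    rupture jumps irrelevant.  Returns SD in the units of ``force``.
    """
    d = np.diff(np.asarray(force, float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


NOISE_FLOOR_FACTOR = 5.0   # detection floors sit this many sigma above noise


def find_contact_point(retraction: ForceCurveCycle,
                       source_id: str = "") -> RetractionSegment:
    """Contact-align a calibrated retraction trace.

    The contact point is the last zero-crossing of force before
    adhesion onset — where the trace comes down from repulsive contact
    through zero.  It is located by anchoring on the last clearly
    repulsive sample (above a noise floor) before the deepest adhesion
    and interpolating the crossing on the steep unloading ramp, which
    keeps the alignment within a fraction of a sample even on noisy
    traces.  Both axes are shifted so the crossing sits at (0, 0);
    samples still in repulsive contact keep separation < 0.  Raises
    CurveRejected (reason all_repulsive / no_contact) for traces with
    no crossing.
    """
    if retraction.force is None or retraction.separation is None:
        raise ValidationError("retraction must be calibrated first")
    # keep acquisition order (a rupture is a vertical drop: two samples
    # at the same separation); clamp sub-sample backward jitter instead
    # of re-sorting, which would scramble drop edges
    sep = np.maximum.accumulate(retraction.separation)
    force = retraction.force
    imin = int(np.argmin(force))
    if force[imin] >= 0:
        raise CurveRejected("all_repulsive")
    floor = NOISE_FLOOR_FACTOR * estimate_noise_sd(force)
    anchors = np.flatnonzero(force[: imin + 1] > floor)
    if anchors.size == 0:
        # no clearly repulsive part; fall back to the plain last
        # non-negative sample before the deepest adhesion
        anchors = np.flatnonzero(force[: imin + 1] >= 0)
        if anchors.size == 0:
            raise CurveRejected("no_contact")
    i0 = int(anchors[-1])
    s_star = None
    if i0 >= 1 and force[i0 - 1] > force[i0] > 0 and sep[i0] > sep[i0 - 1]:
        # extrapolate the crossing from the last two samples of the
        # repulsive unloading ramp; its slope dwarfs the baseline noise,
        # whereas walking sample-by-sample to the first negative force
        # drifts through the flat adhesion onset on noisy traces
        slope = (force[i0] - force[i0 - 1]) / (sep[i0] - sep[i0 - 1])
        s_star = sep[i0] - force[i0] / slope
    if s_star is None:
        # degenerate ramp: fall back to walking to the first downward
        # zero crossing and interpolating it
        while i0 + 1 < force.size and force[i0 + 1] >= 0:
            i0 += 1
        if i0 + 1 >= force.size:
            raise CurveRejected("no_contact")
        f0, f1 = force[i0], force[i0 + 1]
        if f0 == f1 or f0 < 0:
            s_star = sep[i0]
        else:
            s_star = sep[i0] + (sep[i0 + 1] - sep[i0]) * f0 / (f0 - f1)
    return RetractionSegment(separation=sep - s_star, force=force,
                             source_id=source_id)


class MaxAdhesion(NamedTuple):
    force: float        # N, magnitude (>= 0)
    separation: float   # m, where the minimum occurs


def max_adhesion_force(segment: RetractionSegment) -> MaxAdhesion:
    """Magnitude of the deepest adhesion at separation >= 0 (0 if none)."""
    m = segment.separation >= 0
    if not m.any():
        return MaxAdhesion(0.0, 0.0)
    f = segment.force[m]
    s = segment.separation[m]
    i = int(np.argmin(f))
    if f[i] >= 0:
        return MaxAdhesion(0.0, 0.0)
    return MaxAdhesion(float(-f[i]), float(s[i]))


def pulling_length(segment: RetractionSegment, max_force: float,
                   threshold_fraction: float = 0.01,
                   noise_floor_factor: float = NOISE_FLOOR_FACTOR) -> float:
    """Separation of the end of the last adhesion excursion exceeding
    ``threshold_fraction`` of the maximum force (0 if max_force is 0).

    The cut is the larger of the relative threshold and a robust noise
    floor (``noise_floor_factor`` sigma of the baseline noise), so an
    isolated baseline fluctuation past the last rupture cannot
    masquerade as adhesion.  Pass noise_floor_factor=0 for the bare
    relative rule.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValidationError("threshold fraction must be in (0, 1)")
    if max_force == 0:
        return 0.0
    if max_force < 0:
        raise ValidationError("max_force must be a magnitude (>= 0)")
    thr = threshold_fraction * max_force
    if noise_floor_factor > 0:
        thr = max(thr, noise_floor_factor * estimate_noise_sd(segment.force))
    m = (segment.separation >= 0) & (-segment.force >= thr)
    if not m.any():
        return 0.0
    return float(segment.separation[np.flatnonzero(m)[-1]])


def energy_dissipation(segment: RetractionSegment,
                       pulling_length: float) -> float:
    """Trapezoidal integral of the adhesive force magnitude over
    separation in [0, pulling_length]; positive overshoots contribute 0."""
    if pulling_length < 0:
        raise ValidationError("pulling length must be non-negative")
    if pulling_length == 0:
        return 0.0
    if pulling_length > segment.separation[-1]:
        raise ValidationError("pulling length exceeds the segment span")
    m = (segment.separation >= 0) & (segment.separation <= pulling_length)
    sep = segment.separation[m]
    work = np.clip(-segment.force[m], 0.0, None)
    if sep.size < 2:
        return 0.0
    return float(np.trapezoid(work, sep))


def process_curve(cycle: ForceCurveCycle,
                  calibration: CantileverCalibration,
                  config: Optional[RunConfig] = None,
                  source_id: str = "") -> PullMetrics:
    """Full chain: split -> calibrate -> contact -> the three metrics.

    Rejected curves come back as PullMetrics records with rejected=True
    and a reason, never as exceptions.
    """
    cfg = config if config is not None else RunConfig()
    condition = str(cycle.metadata.get("condition", ""))
    try:
        if cycle.segment_label is not None and \
                set(cycle.segment_label) == {RETRACT}:
            retract = cycle          # retraction-only acquisition
        else:
            _, retract = split_curve(cycle)
        retract = deflection_to_force(retract, calibration)
        segment = find_contact_point(retract, source_id=source_id)
        mf = max_adhesion_force(segment)
        if mf.force == 0:
            if cfg.flat_curve_policy == "zero":
                return PullMetrics(0.0, 0.0, 0.0, n_points=len(segment.force),
                                   condition=condition, source_id=source_id)
            raise CurveRejected("no_adhesion")
        pl = pulling_length(segment, mf.force, cfg.threshold_fraction)
        energy = energy_dissipation(segment, pl)
        return PullMetrics(mf.force, pl, energy, n_points=len(segment.force),
                           condition=condition, source_id=source_id)
    except CurveRejected as rej:
        if rej.reason == "all_repulsive" and cfg.flat_curve_policy == "zero":
            # no adhesion anywhere on the trace: a legitimate zero pull
            return PullMetrics(0.0, 0.0, 0.0, n_points=len(cycle),
                               condition=condition, source_id=source_id)
        return PullMetrics(0.0, 0.0, 0.0, condition=condition,
                           source_id=source_id, rejected=True,
                           rejection_reason=rej.reason)
    except ValidationError as exc:
        return PullMetrics(0.0, 0.0, 0.0, condition=condition,
                           source_id=source_id, rejected=True,
                           rejection_reason=f"invalid_curve: {exc}")


def process_batch(cycles: Sequence[ForceCurveCycle],
                  calibration: CantileverCalibration,
                  config: Optional[RunConfig] = None) -> list:
    return [process_curve(c, calibration, config,
                          source_id=str(c.metadata.get("source_id", i)))
            for i, c in enumerate(cycles)]
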
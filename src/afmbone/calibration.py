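"""Cantilever calibration: optical-lever sensitivity and spring constant.

The conversion chain from raw photodiode volts to newtons is
force = k * InvOLS * deflection_raw, with InvOLS (m/V) fitted on stiff-
surface curves and k (N/m) from the thermal-noise (equipartition)
method on a free-cantilever deflection series.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.constants import k as BOLTZMANN

from .core import (APPROACH, CantileverCalibration, ForceCurveCycle,
                   ValidationError)

LOADING_FRACTION = 0.1      # loading region: terminal span above 10% of max
MIN_LOADING_SAMPLES = 5
MIN_THERMAL_SAMPLES = 10_000


@dataclass
class InvolsFit:
    invols: float                 # m/V, mean of per-curve estimates
    per_curve: np.ndarray         # m/V
    sd: float                     # m/V, SD across curves


def _loading_region(cycle: ForceCurveCycle) -> slice:
    """Terminal span of the approach where deflection exceeds 10% of max.

    On a stiff surface the deflection is proportional to the repulsive
    force, so the criterion can be applied to the raw signal.
    """
    if cycle.segment_label is not None:
        mask = cycle.segment_label == APPROACH
        if not mask.any():
            mask = np.ones(len(cycle), bool)
    else:
        mask = np.ones(len(cycle), bool)
    idx = np.flatnonzero(mask)
    d = cycle.deflection_raw[idx]
    dmax = d.max()
    if dmax <= 0:
        raise ValidationError("no repulsive loading found on the curve")
    above = d > LOADING_FRACTION * dmax
    # contiguous terminal run of super-threshold samples
    end = idx[-1] + 1
    start = end
    for j in range(d.size - 1, -1, -1):
        if above[j]:
            start = idx[j]
        else:
            break
    if end - start < MIN_LOADING_SAMPLES:
        raise ValidationError(
            f"loading region has {end - start} samples (< {MIN_LOADING_SAMPLES})")
    return slice(start, end)


def fit_invols(stiff_surface_curves: Sequence[ForceCurveCycle]) -> InvolsFit:
    """InvOLS from stiff-surface curves.

    Per curve, an ordinary least-squares line is fitted to the loading
    part of deflection-vs-z; the slope (V/m) is inverted to a per-curve
    InvOLS and the mean across curves is reported, with the per-curve
    values and their SD.
    """
    curves = list(stiff_surface_curves)
    if not curves:
        raise ValidationError("need at least one stiff-surface curve")
    per_curve = []
    for c in curves:
        sl = _loading_region(c)
        z = c.z_position[sl]
        d = c.deflection_raw[sl]
        slope = np.polyfit(z, d, 1)[0]       # V/m
        if slope <= 0:
            raise ValidationError(
                "negative loading slope: z/deflection geometry inverted")
        per_curve.append(1.0 / slope)
    per_curve = np.array(per_curve)
    sd = float(per_curve.std(ddof=1)) if per_curve.size > 1 else 0.0
    return InvolsFit(float(per_curve.mean()), per_curve, sd)


def thermal_spring_constant(deflection_series, temperature: float = 298.0,
                            beta: float = 1.0) -> float:
    """Spring constant from equipartition: k = beta * kB * T / Var(d).

    beta is a documented correction factor (default 1; the standard
    first-mode literature value 0.971 may be selected in RunConfig).
    The variance form is the minimal faithful thermal-noise estimator;
    no spectral fitting is attempted.
    """
    d = np.asarray(deflection_series, float)
    if d.size < MIN_THERMAL_SAMPLES:
        raise ValidationError(
            f"thermal series needs >= {MIN_THERMAL_SAMPLES} samples")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    var = float(d.var(ddof=1))
    if var <= 0:
        raise ValidationError("thermal series has zero variance")
    return beta * BOLTZMANN * temperature / var


def deflection_to_force(cycle: ForceCurveCycle,
                        calibration: CantileverCalibration) -> ForceCurveCycle:
    """Calibrated copy of the cycle with force (N) and tip-sample
    separation (m, arbitrary origin, increasing away from the surface).

    force = k * InvOLS * deflection_raw;
    separation = -(z - max z) + InvOLS * deflection_raw, i.e. the piezo
    coordinate flipped so distance grows away from the surface, plus
    the cantilever-bending correction.
    """
    if calibration is None:
        raise ValidationError("calibration required")
    deflection_m = calibration.invols * cycle.deflection_raw
    force = calibration.spring_constant * deflection_m
    separation = (cycle.z_position.max() - cycle.z_position) + deflection_m
    return cycle.with_calibration(force=force, separation=separation)


def write_calibration(calibration: CantileverCalibration, path) -> None:
    with open(path, "w") as fh:
        fh.write("# afmbone cantilever calibration\n")
        fh.write(f"invols={calibration.invols!r}\n")
        fh.write(f"spring_constant={calibration.spring_constant!r}\n")
        fh.write(f"temperature={calibration.temperature!r}\n")
        fh.write(f"provenance={calibration.provenance}\n")


def read_calibration(path) -> CantileverCalibration:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    try:
        return CantileverCalibration(
            invols=float(kv["invols"]),
            spring_constant=float(kv["spring_constant"]),
            temperature=float(kv.get("temperature", 298.0)),
            provenance=kv.get("provenance", "post_functionalization"))
    except KeyError as exc:
        raise ValidationError(f"calibration file missing key {exc}") from exc
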
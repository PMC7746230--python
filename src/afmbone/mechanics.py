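"""Bone-cohort arm: notched-femur fracture toughness and global
matrix phosphorylation under paired (contralateral-limb) designs.

Fracture toughness is the single value computed at maximum load for a
circumferentially notched femur in three-point bending:

    Kc = F(theta, Rm/t) * sigma_b * sqrt(pi * a)

with sigma_b = P_max * S / 4 * c / I the bending stress at the notch
(I the annular second moment, c the outer radius by default), a the
crack length along the mid-wall arc (a = theta_rad * Rm), and F the
tabulated geometry factor for a through-wall circumferential crack
under bending.  The factor coefficients ship as a versioned, editable
CSV (data/geometry_factor.csv) with a provenance note in its header.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .core import ValidationError
from . import stats

HALF_CRACK_ANGLE_RANGE = (0.0, 110.0)   # degrees, validity of the method
NOTCH_FRACTION_LIMIT = 1.0 / 3.0        # max notch depth into the cortex
ANGLE_OUTLIER_SD = 2.0                  # cohort-level outlier rule


@dataclass
class NotchedSpecimen:
    specimen_id: str
    animal_id: str
    limb: str                      # left / right
    genotype: str                  # WT / OpnKO
    treatment: str                 # treated / control
    p_max: float                   # N, maximum load
    span: float                    # m, loading span
    r_outer: float                 # m
    r_inner: float                 # m
    half_crack_angle: float        # degrees
    notch_cortex_fraction: float = 0.0
    off_center: bool = False

    def __post_init__(self):
        if not (0 < self.r_inner < self.r_outer):
            raise ValidationError("need 0 < r_inner < r_outer")
        if self.p_max < 0 or self.span <= 0:
            raise ValidationError("p_max >= 0 and span > 0 required")
        if self.half_crack_angle < 0:
            raise ValidationError("half crack angle must be >= 0")


@dataclass
class ToughnessResult:
    specimen_id: str
    kc: float                      # MPa m^0.5
    valid: bool = True
    rejection_reason: str = ""

    def __post_init__(self):
        if self.kc < 0:
            raise ValidationError("Kc must be non-negative")


@dataclass
class PhosphoSample:
    specimen_id: str
    group: str
    absorbance: float              # AU, mean over replicates
    protein: float                 # ng
    level: float                   # AU/ng
    replicate_cv: float = float("nan")
    flagged: str = ""


@dataclass
class PairedObservation:
    animal_id: str
    treated: float
    control: float

    @property
    def delta(self) -> float:
        return self.treated - self.control


class GeometryFactorTable:
    """Bilinear interpolation on the (half-crack-angle, Rm/t) grid."""

    def __init__(self, theta_deg: np.ndarray, rm_over_t: np.ndarray,
                 factor: np.ndarray, version: str = "unversioned"):
        self.theta_deg = np.asarray(theta_deg, float)
        self.rm_over_t = np.asarray(rm_over_t, float)
        self.factor = np.asarray(factor, float)
        self.version = version
        self._interp = RegularGridInterpolator(
            (self.theta_deg, self.rm_over_t), self.factor,
            method="linear", bounds_error=True)

    def __call__(self, theta_deg: float, rm_over_t: float) -> float:
        try:
            return float(self._interp([[theta_deg, rm_over_t]])[0])
        except ValueError as exc:
            raise ValidationError(
                f"(theta={theta_deg} deg, Rm/t={rm_over_t:.3g}) outside the "
                f"geometry-factor table domain") from exc

    @classmethod
    def from_csv(cls, path_or_buffer) -> "GeometryFactorTable":
        if hasattr(path_or_buffer, "read"):
            text = path_or_buffer.read()
        else:
            with open(path_or_buffer) as fh:
                text = fh.read()
        version = "unversioned"
        for line in text.splitlines():
            if line.startswith("#") and "version=" in line:
                version = line.split("version=")[1].split()[0]
        df = pd.read_csv(io.StringIO(text), comment="#", index_col=0)
        theta = df.index.to_numpy(float)
        ratio = np.array([float(c) for c in df.columns])
        return cls(theta, ratio, df.to_numpy(float), version=version)


_DEFAULT_TABLE: Optional[GeometryFactorTable] = None


def default_geometry_factor() -> GeometryFactorTable:
    """The geometry-factor table shipped with the package."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("afmbone").joinpath("data/geometry_factor.csv")
        with ref.open() as fh:
            _DEFAULT_TABLE = GeometryFactorTable.from_csv(fh)
    return _DEFAULT_TABLE


def validate_specimen(spec: NotchedSpecimen,
                      cohort_angles: Sequence[float]) -> ToughnessResult:
    """Apply the validity filters; always returns a decision.

    Rejection reasons: angle_range (theta outside 0-110 deg),
    angle_outlier (> 2 SD from the cohort mean), deep_notch (notch past
    1/3 of the cortex), off_center.
    """
    angles = np.asarray(cohort_angles, float)
    if angles.size == 0:
        raise ValidationError("cohort angles required for the outlier rule")
    lo, hi = HALF_CRACK_ANGLE_RANGE
    reason = ""
    if not (lo <= spec.half_crack_angle <= hi):
        reason = "angle_range"
    elif spec.notch_cortex_fraction > NOTCH_FRACTION_LIMIT:
        reason = "deep_notch"
    elif spec.off_center:
        reason = "off_center"
    else:
        sd = float(np.std(angles, ddof=1)) if angles.size > 1 else 0.0
        if sd > 0 and abs(spec.half_crack_angle - angles.mean()) > ANGLE_OUTLIER_SD * sd:
            reason = "angle_outlier"
    return ToughnessResult(spec.specimen_id, kc=0.0,
                           valid=(reason == ""), rejection_reason=reason)


def section_modulus_terms(r_outer: float, r_inner: float,
                          stress_radius: str = "outer") -> Tuple[float, float, float]:
    """(I, c, Rm): annular second moment, stress fiber radius, mid-wall radius."""
    i_ann = np.pi / 4.0 * (r_outer ** 4 - r_inner ** 4)
    if stress_radius == "outer":
        c = r_outer
    elif stress_radius == "mean":
        c = 0.5 * (r_outer + r_inner)
    else:
        raise ValidationError("stress_radius must be 'outer' or 'mean'")
    rm = 0.5 * (r_outer + r_inner)
    return i_ann, c, rm


def kc_unit_load(span: float, r_outer: float, r_inner: float,
                 half_crack_angle_deg: float,
                 geometry_factor: GeometryFactorTable,
                 stress_radius: str = "outer") -> float:
    """Kc (MPa m^0.5) produced per newton of maximum load."""
    i_ann, c, rm = section_modulus_terms(r_outer, r_inner, stress_radius)
    t = r_outer - r_inner
    theta_rad = np.deg2rad(half_crack_angle_deg)
    a = theta_rad * rm
    f = geometry_factor(half_crack_angle_deg, rm / t)
    sigma_per_newton = span / 4.0 * c / i_ann          # Pa per N
    return f * sigma_per_newton * np.sqrt(np.pi * a) / 1e6


def kc_max_load(spec: NotchedSpecimen,
                geometry_factor: Optional[GeometryFactorTable] = None,
                stress_radius: str = "outer") -> ToughnessResult:
    """Single-valued fracture toughness at maximum load."""
    gf = geometry_factor if geometry_factor is not None else default_geometry_factor()
    kc = spec.p_max * kc_unit_load(spec.span, spec.r_outer, spec.r_inner,
                                   spec.half_crack_angle, gf, stress_radius)
    return ToughnessResult(spec.specimen_id, kc=float(kc))


def phospho_level(absorbance_replicates: Sequence[float],
                  protein_ng: float,
                  specimen_id: str = "", group: str = "") -> PhosphoSample:
    """Global phosphorylation level: mean absorbance / ng of protein."""
    reps = np.asarray(absorbance_replicates, float)
    if reps.size < 1:
        raise ValidationError("need at least one absorbance replicate")
    if protein_ng <= 0:
        raise ValidationError("protein mass must be positive")
    mean_abs = float(reps.mean())
    level = mean_abs / protein_ng
    if reps.size >= 2 and mean_abs != 0:
        cv = float(reps.std(ddof=1) / abs(mean_abs))
        flag = ""
    else:
        cv = float("nan")
        flag = "single_replicate" if reps.size < 2 else "zero_mean"
    return PhosphoSample(specimen_id, group, mean_abs, protein_ng,
                         level, replicate_cv=cv, flagged=flag)


@dataclass
class PairedAnalysis:
    observations: dict              # genotype -> list of PairedObservation
    paired_tests: dict              # genotype -> TestReport
    delta_test: stats.TestReport    # independent t on deltas between genotypes


def paired_deltas(values: pd.DataFrame, measure: str = "toughness",
                  value_col: str = "value") -> PairedAnalysis:
    """Treated-minus-control deltas and the two-level paired testing.

    ``values`` needs columns animal_id, genotype, treatment and the
    value column.  Per genotype a paired t-test compares treated vs
    control limbs; the deltas of the two genotypes are then compared by
    an independent-samples t-test (two-tailed, alpha 0.05).
    """
    required = {"animal_id", "genotype", "treatment", value_col}
    missing = required - set(values.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    observations, paired_tests, deltas = {}, {}, {}
    for genotype, grp in values.groupby("genotype", sort=True):
        obs = []
        for animal, sub in grp.groupby("animal_id", sort=True):
            tr = sub.loc[sub.treatment == "treated", value_col]
            co = sub.loc[sub.treatment == "control", value_col]
            if len(tr) != 1 or len(co) != 1:
                raise ValidationError(
                    f"animal {animal} must contribute exactly one treated "
                    f"and one control value")
            obs.append(PairedObservation(animal, float(tr.iloc[0]),
                                         float(co.iloc[0])))
        observations[genotype] = obs
        treated = np.array([o.treated for o in obs])
        control = np.array([o.control for o in obs])
        paired_tests[genotype] = stats.paired_t(
            treated, control, name=f"paired_t[{measure}:{genotype}]")
        deltas[genotype] = treated - control
    genotypes = sorted(deltas)
    if len(genotypes) == 2:
        delta_test = stats.unpaired_t(
            deltas[genotypes[0]], deltas[genotypes[1]],
            name=f"delta_t[{measure}:{genotypes[0]} vs {genotypes[1]}]")
    else:
        delta_test = stats.degenerate_report(
            f"delta_t[{measure}]", note="need exactly two genotypes")
    return PairedAnalysis(observations, paired_tests, delta_test)
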
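"""Core in-memory containers shared across the pipeline.

All quantities are carried in SI units internally: metres, seconds,
newtons, volts, kelvin.  Unit conversion happens once, in the ASCII
reader, declared by the file dialect.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

APPROACH = "approach"
DWELL = "dwell"
RETRACT = "retract"
UNKNOWN = "unknown"

SEGMENT_LABELS = (APPROACH, DWELL, RETRACT, UNKNOWN)


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ForceCurveCycle:
    """One approach/dwell/retract force-curve acquisition.

    Parameters
    ----------
    time : array, seconds, strictly increasing.
    z_position : array, metres. Piezo extension: increases toward the
        surface during approach, so the point of closest approach is the
        global maximum.
    deflection_raw : array, volts (photodiode signal).
    segment_label : optional array of {"approach", "dwell", "retract",
        "unknown"}, same length.
    metadata : free-form key/value pairs from the file header
        (velocities, condition, substrate, ...).
    force : newtons, populated by the calibration step.
    separation : metres, tip-sample separation with an arbitrary origin
        (increasing away from the surface), populated by calibration;
        the contact-alignment step fixes the origin.
    """

    time: np.ndarray
    z_position: np.ndarray
    deflection_raw: np.ndarray
    segment_label: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)
    force: Optional[np.ndarray] = None
    separation: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.z_position = np.asarray(self.z_position, dtype=float)
        self.deflection_raw = np.asarray(self.deflection_raw, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValidationError("a force-curve cycle needs at least 2 samples")
        if self.z_position.size != n or self.deflection_raw.size != n:
            raise ValidationError(
                "time, z_position and deflection_raw must have equal length"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(
                f"time must be strictly increasing (violated at sample {bad})"
            )
        if self.segment_label is not None:
            self.segment_label = np.asarray(self.segment_label, dtype=object)
            if self.segment_label.size != n:
                raise ValidationError("segment_label length mismatch")
            bad_labels = set(self.segment_label) - set(SEGMENT_LABELS)
            if bad_labels:
                raise ValidationError(f"unknown segment labels: {sorted(bad_labels)}")

    def __len__(self) -> int:
        return int(self.time.size)

    def slice(self, mask_or_index) -> "ForceCurveCycle":
        """Return a sub-cycle (used by segment splitting)."""
        kw = dict(
            time=self.time[mask_or_index],
            z_position=self.z_position[mask_or_index],
            deflection_raw=self.deflection_raw[mask_or_index],
            metadata=dict(self.metadata),
        )
        if self.segment_label is not None:
            kw["segment_label"] = self.segment_label[mask_or_index]
        if self.force is not None:
            kw["force"] = self.force[mask_or_index]
        if self.separation is not None:
            kw["separation"] = self.separation[mask_or_index]
        return ForceCurveCycle(**kw)

    def with_calibration(self, force: np.ndarray, separation: np.ndarray) -> "ForceCurveCycle":
        return replace(self, force=np.asarray(force, float),
                       separation=np.asarray(separation, float))


# plausible spring-constant window used only to flag suspicious values
K_PLAUSIBLE = (0.001, 10.0)


@dataclass
class CantileverCalibration:
    """Conversion factors from raw photodiode volts to newtons.

    invols : metres/volt (inverse optical lever sensitivity).
    spring_constant : N/m, from the thermal-noise (equipartition) method.
    provenance : 'pre_functionalization' or 'post_functionalization';
        the post-functionalization value is the one used downstream.
    """

    invols: float
    spring_constant: float
    temperature: float = 298.0
    provenance: str = "post_functionalization"

    def __post_init__(self):
        if not (self.invols > 0):
            raise ValidationError("invols must be positive")
        if not (self.spring_constant > 0):
            raise ValidationError("spring constant must be positive")
        if not (self.temperature > 0):
            raise ValidationError("temperature must be positive")
        lo, hi = K_PLAUSIBLE
        self.flagged = not (lo <= self.spring_constant <= hi)


@dataclass
class RetractionSegment:
    """Contact-aligned retraction trace.

    separation is non-decreasing with origin at the contact point
    (0, 0); samples still in repulsive contact carry separation < 0 and
    are excluded from energy integration.  force is in newtons with
    adhesion negative.
    """

    separation: np.ndarray
    force: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.size != self.force.size:
            raise ValidationError("separation/force length mismatch")
        if np.any(np.diff(self.separation) < 0):
            raise ValidationError("separation must be non-decreasing")


@dataclass
class PullMetrics:
    """Per-retraction summary: the three quantities extracted per pull."""

    max_force: float          # N, magnitude of the deepest adhesion
    pulling_length: float     # m
    energy: float             # J, dissipated (enclosed) energy
    n_points: int = 0
    condition: str = ""
    source_id: str = ""
    rejected: bool = False
    rejection_reason: str = ""

    def __post_init__(self):
        if not self.rejected:
            if self.energy < 0 or self.pulling_length < 0 or self.max_force < 0:
                raise ValidationError("metrics must be non-negative")
            if self.max_force == 0 and (self.energy != 0 or self.pulling_length != 0):
                raise ValidationError(
                    "zero max force implies zero energy and pulling length"
                )
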
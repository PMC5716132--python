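"""Detector models: volume averaging plus field-size-dependent response.

A detector turns a :class:`~srscone.synthetic_field.DoseField` into a
*reading*: the dose averaged over the active footprint, multiplied by a
phenomenological material response factor

    RF(A) = 1 + c * exp(-A / lambda)

where A is the nominal field diameter (mm).  For an unshielded silicon diode
c > 0: the diode over-responds in small fields relative to the 20 mm cone —
the perturbation the daisy-chain k-factor correction must undo.  RF is ground
truth of the synthetic world, not a cavity-theory computation: the pipeline's
job is to recover a knowable perturbation, so the generator must know it.

The packaged diode footprint matches an unshielded SRS diode chip: a disc of
area 0.6 mm^2 (diameter 0.874 mm), 0.06 mm thick, bare (no encapsulation).
The Markus-type plane-parallel chamber is modelled as a 5 mm disc with
RF ≡ 1; it is only used at the 20 mm cone and the reference field, where
lateral equilibrium holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .synthetic_field import (
    DEFAULT_SEED,
    BeamModel,
    ConeSpec,
    DoseField,
    _get_field,
    terma_depth_factor,
)

__all__ = [
    "DetectorSpec",
    "Reading",
    "srs_diode",
    "markus_chamber",
    "read",
    "paired_dose_samples",
]

#: Reference conditions for output-factor readings and k-factor pairs.
REFERENCE_DEPTH_MM = 15.0
REFERENCE_SSD_MM = 1000.0


@dataclass(frozen=True)
class DetectorSpec:
    """Active-volume footprint and material response of a detector.

    ``response_c`` (dimensionless) and ``response_lambda`` (mm) parametrize
    RF(A) = 1 + c*exp(-A/lambda); RF -> 1 for broad fields by construction.
    """

    name: str
    footprint_diameter: float
    thickness: float
    response_c: float = 0.0
    response_lambda: float = 1.0
    averaging_samples: int = 128

    def __post_init__(self):
        if self.footprint_diameter <= 0:
            raise ValidationError("footprint_diameter must be positive")
        if self.thickness <= 0:
            raise ValidationError("thickness must be positive")
        if self.response_lambda <= 0:
            raise ValidationError("response_lambda must be positive")
        if self.averaging_samples < 100:
            raise ValidationError("footprint averaging requires >= 100 samples")

    def rf(self, field_diameter_mm: float) -> float:
        """Field-size-dependent material response factor RF(A)."""
        if field_diameter_mm <= 0:
            raise DomainError("field diameter must be positive")
        return 1.0 + self.response_c * math.exp(
            -field_diameter_mm / self.response_lambda
        )


@dataclass(frozen=True)
class Reading:
    """One detector reading (arbitrary dose units) with its conditions."""

    value: float
    detector: str
    cone_mm: float
    ssd_mm: float
    depth_mm: float
    sigma: float = 0.0

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError("reading value must be non-negative")
        if self.sigma < 0:
            raise ValidationError("reading sigma must be non-negative")


def srs_diode() -> DetectorSpec:
    """Unshielded SRS silicon diode: 0.6 mm^2 chip, small-field over-response.

    The response parameters (c = 0.10, lambda = 6.0 mm) give
    RF(5)/RF(20) ≈ 1.040, i.e. a ~4% over-response of the 5 mm cone relative
    to the 20 mm cone — the magnitude reported for this diode/beam class.
    """
    return DetectorSpec(
        name="srs_diode",
        footprint_diameter=2.0 * math.sqrt(0.6 / math.pi),  # area 0.6 mm^2
        thickness=0.06,
        response_c=0.10,
        response_lambda=6.0,
    )


def markus_chamber() -> DetectorSpec:
    """Markus-type plane-parallel chamber: 5 mm footprint, water-like (RF=1)."""
    return DetectorSpec(
        name="markus",
        footprint_diameter=5.0,
        thickness=2.0,
        response_c=0.0,
        response_lambda=1.0,
    )


def _footprint_offsets(radius: float, n: int, seed: int):
    """Stratified quasi-uniform sample offsets on the footprint disc."""
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    r = radius * np.sqrt((i + rng.random(n)) / n)
    theta = i * math.pi * (3.0 - math.sqrt(5.0)) + 2.0 * math.pi * rng.random()
    return r * np.cos(theta), r * np.sin(theta)


def read(
    detector: DetectorSpec,
    field: DoseField,
    position,
    field_diameter_mm: float,
    seed: int = DEFAULT_SEED,
) -> Reading:
    """Detector reading at ``position`` (3-D mm, beam frame) in ``field``.

    The dose is averaged over stratified sample points on the footprint disc
    (oriented perpendicular to the beam axis) and multiplied by the material
    response RF(A).  Deterministic for a fixed seed.
    """
    if field_diameter_mm <= 0:
        raise DomainError("field diameter A must be positive")
    position = np.asarray(position, dtype=float)
    if position.shape != (3,):
        raise ValidationError("position must be a 3-vector (mm, beam frame)")
    depth = position[2] - field.ssd_mm
    if depth < 0:
        raise DomainError("footprint must be inside the phantom")
    ox, oy = _footprint_offsets(
        detector.footprint_diameter / 2.0, detector.averaging_samples, seed
    )
    radii = np.hypot(position[0] + ox, position[1] + oy)
    lat = np.atleast_1d(field.lateral_factor(radii, position[2]))
    tdf = terma_depth_factor(field.beam, depth, position[2])
    mean_dose = field.beam.output_normalization * tdf * float(lat.mean())
    return Reading(
        value=mean_dose * detector.rf(field_diameter_mm),
        detector=detector.name,
        cone_mm=field_diameter_mm,
        ssd_mm=field.ssd_mm,
        depth_mm=float(depth),
        sigma=0.0,
    )


def paired_dose_samples(
    beam: BeamModel,
    cone: ConeSpec,
    detector: DetectorSpec,
    with_cavity: bool,
    ssd_mm: float = REFERENCE_SSD_MM,
    depth_mm: float = REFERENCE_DEPTH_MM,
    seed: int = DEFAULT_SEED,
) -> float:
    """One member of the water/cavity dose pair at the reference point.

    ``with_cavity=True`` emulates the dose scored in the detector cavity:
    footprint-averaged dose times RF(A).  ``with_cavity=False`` is the dose
    to water at the same point with no detector present.  The water-to-cavity
    conversion factor is the ratio of the two calls,
    k_w^det(A) = D_w / D_det, computed per cone by the pipeline.
    """
    fld = _get_field(beam, cone, ssd_mm, seed=seed)
    point = np.array([0.0, 0.0, ssd_mm + depth_mm])
    if with_cavity:
        return read(detector, fld, point, cone.nominal_diameter, seed=seed).value
    return float(fld(point))
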
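"""Synthetic small-field photon dose engine for circular SRS cones.

This module generates physically plausible dose distributions for circular
cone-collimated 6 MV-like beams, standing in for a full Monte Carlo head
model.  The model is deliberately simple but captures the features that make
small-field cone dosimetry hard:

* a finite focal spot (uniform disc) whose partial visibility through the
  two cone apertures defines the primary fluence (geometric penumbra and,
  for sufficiently focused collimation, source occlusion);
* a depth factor with exponential buildup, quasi-exponential attenuation and
  inverse-square divergence;
* a radial lateral-spread kernel (weighted Gaussians: a narrow component for
  secondary-electron transport, a broad one for phantom scatter) whose
  convolution with the aperture fluence produces the loss of lateral
  electronic equilibrium below ~18 mm field diameter;
* beam-axis/scan-axis tilt for misalignment studies, pivoting at the point
  where the untilted central axis meets the phantom surface.

Coordinate convention: right-handed beam frame, origin at the source, z along
the central axis pointing into the phantom, all lengths in mm.  Depth is
measured from the phantom surface along the ray to the point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

from .errors import ConfigurationError, DomainError, ValidationError
from .scan_analysis import ScanCurve

__all__ = [
    "BeamModel",
    "ConeSpec",
    "ScanRequest",
    "DoseField",
    "NON_CONVERGING",
    "PACKAGED_CONE_DIAMETERS_MM",
    "default_beam",
    "default_cone_set",
    "reference_field_cone",
    "make_cone",
    "fluence_at",
    "terma_depth_factor",
    "dose_at",
    "simulate_scan",
    "convergence_distance",
    "occlusion_fraction",
]

#: Nominal diameters (mm at isocenter) of the packaged circular cone set.
PACKAGED_CONE_DIAMETERS_MM = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0)

#: Default seed for the quasi-uniform focal-spot disc sampling.
DEFAULT_SEED = 20120105

#: Sentinel returned by :func:`convergence_distance` for a cylindrical opening.
NON_CONVERGING = math.inf

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class BeamModel:
    """Source, geometry and bulk-physics parameters of the synthetic beam.

    Parameters
    ----------
    focal_spot_diameter : float
        Diameter (mm) of the uniform-disc focal spot on the target.
    source_to_iso : float
        Source-to-isocenter distance (mm).
    mu : float
        Effective linear attenuation coefficient (1/mm) governing the
        quasi-exponential depth falloff of the primary beam.
    buildup_beta : float
        Buildup rise constant (1/mm); the depth of maximum on the central
        axis of a broad field is ln(1 + beta/mu)/beta.
    kernel_components : tuple of (weight, sigma_mm)
        Radial lateral-spread kernel as a weighted sum of 2-D Gaussians;
        weights must sum to 1.  The narrow component models lateral
        secondary-electron transport, the broad one phantom scatter.
    output_normalization : float
        Overall dimensionless scale applied to every dose value.
    """

    focal_spot_diameter: float = 1.5
    source_to_iso: float = 1000.0
    mu: float = 0.005
    buildup_beta: float = 0.3
    kernel_components: tuple = ((0.88, 2.2), (0.12, 28.0))
    output_normalization: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self,
            "kernel_components",
            tuple((float(w), float(s)) for w, s in self.kernel_components),
        )
        if self.focal_spot_diameter <= 0:
            raise ValidationError("focal_spot_diameter must be positive")
        if self.mu <= 0:
            raise ValidationError("mu must be positive")
        if self.buildup_beta <= 0:
            raise ValidationError("buildup_beta must be positive")
        if len(self.kernel_components) < 1:
            raise ValidationError("kernel needs at least one component")
        wsum = sum(w for w, _ in self.kernel_components)
        if abs(wsum - 1.0) > 1e-9:
            raise ValidationError(f"kernel weights must sum to 1, got {wsum!r}")
        if any(s <= 0 for _, s in self.kernel_components):
            raise ValidationError("kernel sigmas must be positive")

    @property
    def narrowest_sigma(self) -> float:
        return min(s for _, s in self.kernel_components)


@dataclass(frozen=True)
class ConeSpec:
    """Physical aperture geometry of one circular SRS cone.

    The nominal diameter is quoted at the isocenter plane; the upstream (top)
    and downstream (bottom) circular openings are given by radius and
    distance from the source along the central axis.
    """

    nominal_diameter: float
    top_radius: float
    bottom_radius: float
    top_distance: float
    bottom_distance: float

    def __post_init__(self):
        if self.nominal_diameter <= 0:
            raise ValidationError("nominal_diameter must be positive")
        if not (0 < self.top_distance < self.bottom_distance):
            raise ValidationError(
                "need 0 < top_distance < bottom_distance "
                f"(got {self.top_distance}, {self.bottom_distance})"
            )
        if self.top_radius <= 0 or self.bottom_radius <= 0:
            raise ValidationError("aperture radii must be positive")

    @property
    def apertures(self):
        """((radius, distance) top, (radius, distance) bottom)."""
        return (
            (self.top_radius, self.top_distance),
            (self.bottom_radius, self.bottom_distance),
        )


@dataclass(frozen=True)
class ScanRequest:
    """A request for a simulated 1-D scan.

    ``scan_type`` is "PDD" (positions are depths along the detector motion
    line) or "OAR" (positions are lateral offsets at fixed ``depth_mm``).
    ``tilt_deg`` is the angle between the beam central axis and the detector
    motion line and applies to PDD scans only.
    """

    scan_type: str
    ssd_mm: float
    positions: tuple
    depth_mm: float | None = None
    tilt_deg: float = 0.0

    def __post_init__(self):
        st = self.scan_type.upper()
        if st not in ("PDD", "OAR"):
            raise ValidationError(f"scan_type must be PDD or OAR, got {self.scan_type!r}")
        object.__setattr__(self, "scan_type", st)
        if self.ssd_mm <= 0:
            raise ValidationError("ssd_mm must be positive")
        pos = tuple(float(p) for p in self.positions)
        if len(pos) == 0:
            raise ValidationError("positions must be non-empty")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        if not (0.0 <= self.tilt_deg <= 5.0):
            raise ValidationError("tilt_deg must lie in [0, 5] degrees")
        if st == "OAR":
            if self.depth_mm is None:
                raise ValidationError("OAR request requires depth_mm")
            if self.tilt_deg != 0.0:
                raise ValidationError("tilt applies to PDD scans only")
        if st == "PDD" and min(pos) < 0:
            raise ValidationError("PDD depths must be non-negative")


def default_beam() -> BeamModel:
    """The packaged 6 MV-SRS-like synthetic beam (all defaults)."""
    return BeamModel()


def make_cone(
    nominal_diameter: float,
    beam: BeamModel | None = None,
    top_distance: float = 630.0,
    bottom_distance: float = 700.0,
    convergence_mm: float = -4000.0,
) -> ConeSpec:
    """Build a cone of the given nominal field diameter at isocenter.

    The downstream (bottom) aperture is the field-defining one: it projects
    the nominal radius from the source to the isocenter plane.  The upstream
    (top) aperture lies on the edge line through the bottom edge converging
    at ``convergence_mm`` on the z axis; the default, 4 m above the source,
    reproduces the near-cylindrical inner bore of BrainLAB-type cones, whose
    back-projected opening far exceeds the focal spot so source occlusion is
    absent.  The aperture distances are synthetic defaults: no cone drawings
    are published, so the geometry here is invented (and configurable).
    """
    beam = beam or default_beam()
    bottom_radius = (nominal_diameter / 2.0) * bottom_distance / beam.source_to_iso
    top_radius = bottom_radius * (top_distance - convergence_mm) / (
        bottom_distance - convergence_mm
    )
    return ConeSpec(
        nominal_diameter=float(nominal_diameter),
        top_radius=top_radius,
        bottom_radius=bottom_radius,
        top_distance=float(top_distance),
        bottom_distance=float(bottom_distance),
    )


def default_cone_set(beam: BeamModel | None = None) -> dict:
    """The packaged nine-cone set, keyed by nominal diameter (mm)."""
    return {a: make_cone(a, beam) for a in PACKAGED_CONE_DIAMETERS_MM}


def reference_field_cone(beam: BeamModel | None = None) -> ConeSpec:
    """Circular stand-in for the 100 x 100 mm^2 reference field.

    Modelled as the equal-area circle (diameter 112.838 mm) collimated by the
    same aperture planes; at this size the engine is laterally saturated, so
    the circular/square distinction is immaterial for central-axis dose.
    """
    return make_cone(2.0 * math.sqrt(1e4 / math.pi), beam)


def _spot_samples(radius: float, n: int, seed: int):
    """Quasi-uniform (stratified-radius, golden-angle) points on the spot disc."""
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    r = radius * np.sqrt((i + rng.random(n)) / n)
    theta = i * _GOLDEN_ANGLE + 2.0 * math.pi * rng.random()
    return r * np.cos(theta), r * np.sin(theta)


def _visible_fraction(cone: ConeSpec, sx, sy, px, py, pz):
    """Fraction of focal-spot sample points visible from (px, py, pz).

    ``px/py/pz`` may be arrays broadcastable against each other; the sample
    axis is appended internally.
    """
    px = np.asarray(px, dtype=float)[..., None]
    py = np.asarray(py, dtype=float)[..., None]
    pz = np.asarray(pz, dtype=float)[..., None]
    visible = np.ones(np.broadcast_shapes(px.shape, (sx.size,)), dtype=bool)
    for radius, za in cone.apertures:
        t = za / pz
        qx = sx + (px - sx) * t
        qy = sy + (py - sy) * t
        visible &= qx * qx + qy * qy <= radius * radius
    return visible.mean(axis=-1)


def fluence_at(
    beam: BeamModel,
    cone: ConeSpec,
    point,
    n_samples: int = 600,
    seed: int = DEFAULT_SEED,
) -> float:
    """Source-visibility fraction at a point downstream of both apertures.

    The focal-spot disc is sampled with >= 500 quasi-uniform points; each is
    ray-traced through both circular openings.  Returns the visible fraction
    in [0, 1] — this is the primary (un-scattered) relative fluence, and the
    quantity through which source occlusion manifests.
    """
    if n_samples < 500:
        raise ConfigurationError("fluence sampling requires >= 500 spot points")
    point = np.asarray(point, dtype=float)
    if point.shape != (3,):
        raise ValidationError("point must be a 3-vector (mm, beam frame)")
    if point[2] <= cone.bottom_distance:
        raise DomainError(
            f"point at z={point[2]} mm is not downstream of the bottom "
            f"aperture (z={cone.bottom_distance} mm)"
        )
    sx, sy = _spot_samples(beam.focal_spot_diameter / 2.0, n_samples, seed)
    return float(_visible_fraction(cone, sx, sy, point[0], point[1], point[2]))


def terma_depth_factor(beam: BeamModel, depth_mm: float, source_to_point_mm: float) -> float:
    """Depth component of the dose engine.

    ``(1 - exp(-beta d)) * exp(-mu d) * (SAD / source_to_point)^2``:
    exponential buildup, primary attenuation, inverse square.
    """
    if np.any(np.asarray(depth_mm) < 0):
        raise DomainError(f"depth must be non-negative, got {depth_mm}")
    d = np.asarray(depth_mm, dtype=float)
    out = (
        (1.0 - np.exp(-beam.buildup_beta * d))
        * np.exp(-beam.mu * d)
        * (beam.source_to_iso / np.asarray(source_to_point_mm, dtype=float)) ** 2
    )
    return out if out.ndim else float(out)


def convergence_distance(cone: ConeSpec) -> float:
    """z (mm from the source plane) where the aperture edge lines meet the axis.

    Negative values lie above/behind the source.  A cylindrical opening
    (equal radii) never converges and returns :data:`NON_CONVERGING`.
    """
    if cone.top_radius == cone.bottom_radius:
        return NON_CONVERGING
    return cone.top_distance - cone.top_radius * (
        cone.bottom_distance - cone.top_distance
    ) / (cone.bottom_radius - cone.top_radius)


def occlusion_fraction(cone: ConeSpec, beam: BeamModel) -> float:
    """Fraction of focal-spot area hidden from the isocenter by the apertures.

    Both aperture edges are back-projected from the isocenter to the source
    plane; the smaller projected diameter d0 is the effective opening.  When
    d0 is below the focal-spot diameter, the occluded fraction is the area
    deficit 1 - (d0/spot)^2; otherwise the whole spot is visible and the
    occlusion is zero (the BrainLAB near-cylindrical case).
    """
    z_view = beam.source_to_iso
    d0 = min(
        2.0 * radius * z_view / (z_view - za) for radius, za in cone.apertures
    )
    spot = beam.focal_spot_diameter
    if d0 >= spot:
        return 0.0
    return min(1.0, 1.0 - (d0 / spot) ** 2)


class DoseField:
    """Callable relative-dose distribution for one (beam, cone) pair.

    ``field(point)`` maps a 3-D point (mm, beam frame, z from the source) to
    relative dose; the phantom surface sits at ``z = ssd_mm``.  Internally
    the lateral dose factor in each transverse plane is the radial
    convolution of the aperture fluence with the multi-Gaussian kernel,
    evaluated by polar-grid quadrature (radial midpoint rule at ``grid_step``
    resolution with the angular integral done analytically via the modified
    Bessel function I0).  Radial fluence profiles are cached per plane, so
    scans and footprint averages are cheap.
    """

    def __init__(
        self,
        beam: BeamModel,
        cone: ConeSpec,
        ssd_mm: float = 1000.0,
        grid_step: float = 0.1,
        n_spot_samples: int = 600,
        seed: int = DEFAULT_SEED,
    ):
        if grid_step > beam.narrowest_sigma:
            raise ConfigurationError(
                f"grid step {grid_step} mm exceeds the narrowest kernel sigma "
                f"{beam.narrowest_sigma} mm"
            )
        if ssd_mm <= cone.bottom_distance:
            raise ValidationError("phantom surface must lie below the cone")
        self.beam = beam
        self.cone = cone
        self.ssd_mm = float(ssd_mm)
        self.grid_step = float(grid_step)
        self.n_spot_samples = int(n_spot_samples)
        self.seed = int(seed)
        self._sx, self._sy = _spot_samples(
            beam.focal_spot_diameter / 2.0, self.n_spot_samples, self.seed
        )
        self._profiles: dict = {}

    # -- lateral machinery -------------------------------------------------

    def _penumbra_annulus(self, z: float):
        """(r_full, r_blocked): radii bracketing the geometric penumbra in
        plane z — full source visibility inside, none outside."""
        spot_r = self.beam.focal_spot_diameter / 2.0
        r_full = min(
            (radius - spot_r * (1.0 - za / z)) / (za / z)
            for radius, za in self.cone.apertures
        )
        r_blocked = min(
            (radius + spot_r * (1.0 - za / z)) / (za / z)
            for radius, za in self.cone.apertures
        )
        return max(0.0, r_full), r_blocked

    def fluence_profile(self, z: float):
        """(radii, fluence, cell widths): radial fluence profile in plane z.

        Midpoint cells at ``grid_step`` resolution, refined 5x across the
        geometric penumbra annulus where the fluence varies fastest.
        """
        key = round(float(z), 9)
        cached = self._profiles.get(key)
        if cached is not None:
            return cached
        r_full, r_blocked = self._penumbra_annulus(z)
        pad = self.grid_step
        edges = [np.array([0.0])]
        if r_full > pad:
            edges.append(np.linspace(0.0, r_full - pad, max(2, int(r_full / self.grid_step)) + 1)[1:])
        lo = edges[-1][-1]
        fine = self.grid_step / 5.0
        edges.append(lo + np.arange(1, int((r_blocked + pad - lo) / fine) + 2) * fine)
        edge = np.concatenate(edges)
        centers = 0.5 * (edge[1:] + edge[:-1])
        half = 0.5 * np.diff(edge)
        # two-point Gauss-Legendre nodes per cell: O(h^4) radial quadrature
        offset = half / math.sqrt(3.0)
        radii = np.concatenate([centers - offset, centers + offset])
        widths = np.concatenate([half, half])
        order = np.argsort(radii)
        radii, widths = radii[order], widths[order]
        flu = _visible_fraction(self.cone, self._sx, self._sy, radii, 0.0, z)
        self._profiles[key] = (radii, flu, widths)
        return radii, flu, widths

    def lateral_factor(self, r, z: float):
        """Kernel-convolved fluence at radius r (mm) in plane z.

        Normalized so that a fully open, laterally saturated field gives 1.
        """
        radii, flu, widths = self.fluence_profile(z)
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out = np.zeros_like(r)
        src = flu * radii * widths
        for w, sig in self.beam.kernel_components:
            s2 = sig * sig
            ker = (
                np.exp(-((radii[None, :] - r[:, None]) ** 2) / (2.0 * s2))
                * i0e(radii[None, :] * r[:, None] / s2)
                / s2
            )
            out += w * ker @ src
        return out if out.size > 1 else float(out[0])

    # -- dose --------------------------------------------------------------

    def dose(self, r, z: float, depth_mm: float) -> float:
        """Relative dose at radius r in plane z, at water depth ``depth_mm``."""
        tdf = terma_depth_factor(self.beam, depth_mm, z)
        return self.beam.output_normalization * tdf * self.lateral_factor(r, z)

    def cax_dose(self, depth_mm: float) -> float:
        """Central-axis dose at a depth below the (untilted) surface."""
        return self.dose(0.0, self.ssd_mm + depth_mm, depth_mm)

    def __call__(self, point) -> float:
        point = np.asarray(point, dtype=float)
        if point.shape != (3,):
            raise ValidationError("point must be a 3-vector (mm, beam frame)")
        depth = point[2] - self.ssd_mm
        if depth < 0:
            raise DomainError("point lies above the phantom surface")
        r = math.hypot(point[0], point[1])
        return float(self.dose(r, point[2], depth))


_FIELD_CACHE: dict = {}


def _get_field(beam, cone, ssd_mm, grid_step=0.1, n_spot_samples=600, seed=DEFAULT_SEED):
    key = (beam, cone, float(ssd_mm), float(grid_step), int(n_spot_samples), int(seed))
    fld = _FIELD_CACHE.get(key)
    if fld is None:
        fld = DoseField(beam, cone, ssd_mm, grid_step, n_spot_samples, seed)
        if len(_FIELD_CACHE) > 64:
            _FIELD_CACHE.clear()
        _FIELD_CACHE[key] = fld
    return fld


def dose_at(
    beam: BeamModel,
    cone: ConeSpec,
    point,
    ssd_mm: float = 1000.0,
    grid_step: float = 0.1,
) -> float:
    """Relative dose at a 3-D point (mm, beam frame; surface at z = ssd_mm)."""
    return _get_field(beam, cone, ssd_mm, grid_step)(point)


def _tilted_sample(ssd_mm: float, depth_on_line: float, tilt_deg: float):
    """Beam-frame (r, z, ray depth) of a detector at ``depth_on_line`` on the
    fixed vertical motion line, for a beam tilted by ``tilt_deg`` about the
    point where the untilted axis meets the surface.

    The phantom surface stays horizontal; in the tilted beam frame it is the
    plane through (0, 0, ssd) with normal (-sin t, 0, cos t).  Depth is
    measured from that plane along the source-to-detector ray.
    """
    t = math.radians(tilt_deg)
    x = depth_on_line * math.sin(t)
    z = ssd_mm + depth_on_line * math.cos(t)
    dist = math.hypot(x, z)
    if depth_on_line == 0.0:
        return 0.0, z, 0.0
    n_dot_u = (-math.sin(t) * x + math.cos(t) * z) / dist
    t_surf = ssd_mm * math.cos(t) / n_dot_u
    return x, z, dist - t_surf


def simulate_scan(
    beam: BeamModel,
    cone: ConeSpec,
    request: ScanRequest,
    grid_step: float = 0.1,
    n_spot_samples: int = 600,
    seed: int = DEFAULT_SEED,
) -> ScanCurve:
    """Simulate a water-tank scan of the synthetic field.

    PDD scans return unnormalized dose versus position along the detector
    motion line (normalization is scan analysis' job); OAR scans return the
    lateral profile at the requested depth.  Metadata records the geometry.
    """
    fld = _get_field(beam, cone, request.ssd_mm, grid_step, n_spot_samples, seed)
    if request.scan_type == "PDD":
        values = []
        for pos in request.positions:
            if pos == 0.0:
                values.append(0.0)
                continue
            x, z, depth = _tilted_sample(request.ssd_mm, pos, request.tilt_deg)
            values.append(fld.dose(abs(x), z, depth))
        depth_meta = ""
    else:
        z = request.ssd_mm + request.depth_mm
        r = np.abs(np.asarray(request.positions, dtype=float))
        vals = fld.lateral_factor(r, z)
        tdf = terma_depth_factor(beam, request.depth_mm, z)
        values = list(beam.output_normalization * tdf * np.atleast_1d(vals))
        depth_meta = request.depth_mm
    return ScanCurve(
        positions=request.positions,
        values=tuple(float(v) for v in values),
        metadata={
            "scan_type": request.scan_type,
            "cone_mm": cone.nominal_diameter,
            "ssd_mm": request.ssd_mm,
            "depth_mm": depth_meta,
            "detector": "point",
            "tilt_deg": request.tilt_deg,
        },
    )
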
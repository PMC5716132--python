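"""Beam-axis / detector-motion-line misalignment (tilt) studies.

A PDD scanned with the beam central axis tilted relative to the vertical
detector motion line samples progressively off-axis dose with depth; for
small cones this distorts the curve at depth while leaving the shallow
region (where output factors are measured) nearly untouched.  The study
simulates PDDs over a set of tilt angles, normalizes each, and reports the
signed percent deviation from the untilted baseline versus depth, plus the
depth beyond which the deviation magnitude exceeds a threshold for good.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .scan_analysis import ScanCurve, normalize_pdd
from .synthetic_field import BeamModel, ConeSpec, ScanRequest, simulate_scan

__all__ = [
    "DEFAULT_TILT_ANGLES_DEG",
    "TiltStudy",
    "run_tilt_study",
    "depth_exceeding",
]

#: Tilt angles of the misalignment protocol (degrees).
DEFAULT_TILT_ANGLES_DEG = (0.0, 0.2, 0.5, 0.7, 0.9, 1.0)

#: Default deviation threshold (percent) for crossing-depth reports.
DEFAULT_THRESHOLD_PCT = 2.0


def default_depth_grid() -> np.ndarray:
    """0-150 mm in 1 mm steps (surface included)."""
    return np.arange(0.0, 151.0, 1.0)


@dataclass(frozen=True)
class TiltStudy:
    """Normalized PDDs and deviation-vs-depth series per tilt angle.

    ``deviations[theta]`` is 100*(PDD_theta - PDD_0)/PDD_0 on the depth
    grid (signed; the sign convention is tilted minus baseline).  Depths
    where the baseline is zero (the surface point) carry deviation 0.
    """

    cone_mm: float
    angles_deg: tuple
    depths_mm: tuple
    curves: dict
    deviations: dict

    def deviation(self, angle_deg: float) -> np.ndarray:
        return np.asarray(self.deviations[angle_deg], dtype=float)


def run_tilt_study(
    beam: BeamModel,
    cone: ConeSpec,
    angles_deg=DEFAULT_TILT_ANGLES_DEG,
    depths_mm=None,
    ssd_mm: float = 1000.0,
) -> TiltStudy:
    """Simulate and normalize PDDs for each tilt angle; tabulate deviations."""
    angles = tuple(float(a) for a in angles_deg)
    if 0.0 not in angles:
        raise ValidationError("the 0 degree baseline angle must be included")
    depths = default_depth_grid() if depths_mm is None else np.asarray(
        depths_mm, dtype=float
    )
    if depths.size == 0:
        raise ValidationError("depth grid must be non-empty")
    curves = {}
    for a in angles:
        raw = simulate_scan(
            beam,
            cone,
            ScanRequest(
                scan_type="PDD", ssd_mm=ssd_mm, positions=tuple(depths), tilt_deg=a
            ),
        )
        curves[a] = normalize_pdd(raw)
    base = curves[0.0].dose
    deviations = {}
    for a in angles:
        v = curves[a].dose
        dev = np.where(base > 0, 100.0 * (v - base) / np.where(base > 0, base, 1.0), 0.0)
        deviations[a] = tuple(dev)
    return TiltStudy(
        cone_mm=cone.nominal_diameter,
        angles_deg=angles,
        depths_mm=tuple(float(d) for d in depths),
        curves=curves,
        deviations=deviations,
    )


def depth_exceeding(
    study: TiltStudy, angle_deg: float, threshold_pct: float = DEFAULT_THRESHOLD_PCT
):
    """Smallest grid depth beyond which |deviation| stays above the threshold.

    Returns the depth in mm, or ``None`` if the deviation never exceeds the
    threshold permanently.
    """
    if angle_deg not in study.deviations:
        raise ValidationError(f"angle {angle_deg} not part of the study")
    dev = np.abs(study.deviation(angle_deg))
    above = dev > threshold_pct
    # last index that is NOT above; everything beyond it qualifies
    not_above = np.nonzero(~above)[0]
    start = 0 if not_above.size == 0 else not_above[-1] + 1
    if start >= dev.size:
        return None
    return float(study.depths_mm[start])
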
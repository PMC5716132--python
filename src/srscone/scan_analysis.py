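"""Scan normalization and summary metrics for water-tank curves.

Percentage depth dose (PDD) curves are normalized to 100 at their maximum;
off-axis ratio (OAR) profiles are summarized by FWHM, 80-20% penumbra widths
and a mirrored-symmetry index.  The module also carries the lateral electronic
equilibrium (LEE) machinery: the published rule-of-thumb mapping from the
%dd(20)/%dd(10) ratio to the minimum field diameter D_LEE restoring LEE, the
packaged per-cone D_LEE reference constants, and the rule selecting the
intermediate cone through which two detectors are daisy-chained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DomainError,
    MetricError,
    RangeError,
    SelectionError,
    ValidationError,
)

__all__ = [
    "ScanCurve",
    "ProfileMetrics",
    "LEE_DIAMETERS_MM",
    "DLEE_SLOPE",
    "DLEE_INTERCEPT",
    "normalize_pdd",
    "percent_dd",
    "dlee",
    "select_intermediate",
    "profile_metrics",
]

#: Published lateral-electron-equilibrium diameter (mm) per SRS cone diameter
#: (mm), for a 6 MV SRS beam.  Used as packaged reference constants when
#: selecting the intermediate daisy-chain cone.
LEE_DIAMETERS_MM = {
    5.0: 16.5,
    7.5: 16.9,
    10.0: 17.6,
    12.5: 18.4,
    15.0: 18.5,
    17.5: 18.6,
    20.0: 18.7,
    25.0: 19.2,
    30.0: 19.7,
}

# Coefficients of the published rule of thumb D_LEE = slope * ratio + intercept.
DLEE_SLOPE = 15.124
DLEE_INTERCEPT = -10.086


@dataclass(frozen=True)
class ScanCurve:
    """An ordered 1-D dose scan (PDD or OAR) with acquisition metadata.

    ``positions`` are mm (depth for PDD, lateral offset for OAR), strictly
    increasing; ``values`` are relative dose, non-negative.  ``metadata`` uses
    the keys of the scan-CSV dialect: ``scan_type``, ``cone_mm``, ``ssd_mm``,
    ``depth_mm``, ``detector``, ``tilt_deg`` (extra keys are preserved).
    """

    positions: tuple
    values: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = tuple(float(p) for p in self.positions)
        val = tuple(float(v) for v in self.values)
        if len(pos) != len(val):
            raise ValidationError(
                f"positions ({len(pos)}) and values ({len(val)}) differ in length"
            )
        if len(pos) == 0:
            raise ValidationError("empty scan curve")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if min(val) < 0:
            raise ValidationError("dose values must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def positions_mm(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)

    @property
    def dose(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ProfileMetrics:
    """FWHM, per-side 80-20% penumbra widths and symmetry of an OAR profile."""

    fwhm_mm: float
    penumbra_left_mm: float
    penumbra_right_mm: float
    symmetry: float


def normalize_pdd(curve: ScanCurve) -> ScanCurve:
    """Scale a PDD so its maximum is exactly 100.0 (ratios preserved)."""
    v = curve.dose
    vmax = v.max()
    if vmax <= 0:
        raise ValidationError("cannot normalize an all-zero curve")
    # divide before scaling so the maximum is exactly 100.0
    return replace(curve, values=tuple(100.0 * (v / vmax)))


def percent_dd(curve: ScanCurve, depth_mm: float) -> float:
    """%dd at ``depth_mm``: linear interpolation on the normalized curve."""
    d = curve.positions_mm
    if not (d[0] <= depth_mm <= d[-1]):
        raise RangeError(
            f"depth {depth_mm} mm outside scanned range [{d[0]}, {d[-1]}] mm"
        )
    norm = normalize_pdd(curve)
    return float(np.interp(depth_mm, d, norm.dose))


def dlee(dd_ratio: float) -> float:
    """Lateral-equilibrium diameter from the published %dd rule of thumb.

    Evaluates ``15.124 * dd_ratio - 10.086`` exactly as printed.  The formula
    is stated for the ratio %dd(20)/%dd(10); for physical 6 MV beams that
    ratio is < 1 and the printed formula then returns a negative, non-physical
    diameter, whereas the published per-cone D_LEE table is consistent with
    the inverse ratio (≈1.9).  The formula is applied verbatim to whatever
    ratio the caller supplies — never silently inverted — and a warning is
    raised when the result is non-positive.
    """
    if dd_ratio <= 0:
        raise DomainError(f"dd_ratio must be positive, got {dd_ratio}")
    value = DLEE_SLOPE * dd_ratio + DLEE_INTERCEPT
    if value <= 0:
        warnings.warn(
            f"D_LEE = {value:.2f} mm is non-physical under this ratio "
            "orientation (ratio < ~0.667); the published rule is only "
            "consistent with the inverted %dd(10)/%dd(20) ratio",
            UserWarning,
            stacklevel=2,
        )
    return value


def select_intermediate(cone_diameters_mm, dlee_values_mm) -> float:
    """Smallest cone whose diameter meets or exceeds its own D_LEE.

    This is the daisy-chain intermediate field: the first cone large enough
    to restore lateral electronic equilibrium, so that the small-field diode
    and the reference ion chamber respond comparably there.
    """
    cones = [float(c) for c in cone_diameters_mm]
    dlees = [float(v) for v in dlee_values_mm]
    if len(cones) != len(dlees):
        raise ValidationError("cone and D_LEE lists must be aligned")
    if sorted(cones) != cones:
        raise ValidationError("cone diameters must be sorted ascending")
    for c, v in zip(cones, dlees):
        if c >= v:
            return c
    raise SelectionError(
        "no cone diameter meets or exceeds its lateral-equilibrium diameter"
    )


def _crossing(x, y, level, rising):
    """Linearly interpolated x where y crosses ``level``.

    ``rising``: scan from the left for an upward crossing; otherwise scan from
    the right for the mirrored downward crossing.
    """
    idx = np.nonzero(y >= level)[0]
    if idx.size == 0:
        raise MetricError(f"profile never reaches {level} of maximum")
    if rising:
        i = idx[0]
        if i == 0:
            return x[0]
        x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    else:
        i = idx[-1]
        if i == len(y) - 1:
            return x[-1]
        x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    if y1 == y0:
        return x1 if rising else x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def profile_metrics(curve: ScanCurve) -> ProfileMetrics:
    """FWHM, 80-20% penumbra widths, and symmetry of a unimodal OAR profile.

    All level crossings are linearly interpolated.  Symmetry is the maximum
    mirrored difference ``|D(x) - D(-x)| / D(0)`` over the overlapping
    mirrored range.  A profile whose supra-threshold region is not contiguous
    (at 20%, 50% or 80% of maximum) is rejected as non-unimodal.
    """
    x = curve.positions_mm
    y = curve.dose
    ymax = y.max()
    if ymax <= 0:
        raise ValidationError("cannot analyze an all-zero profile")
    yn = y / ymax
    for level in (0.2, 0.5, 0.8):
        above = np.nonzero(yn >= level)[0]
        if above.size and not np.array_equal(
            above, np.arange(above[0], above[-1] + 1)
        ):
            raise MetricError(
                f"profile is non-unimodal (region above {level:.0%} of the "
                "maximum is not contiguous)"
            )
    left50 = _crossing(x, yn, 0.5, rising=True)
    right50 = _crossing(x, yn, 0.5, rising=False)
    fwhm = right50 - left50
    pen_left = abs(
        _crossing(x, yn, 0.8, rising=True) - _crossing(x, yn, 0.2, rising=True)
    )
    pen_right = abs(
        _crossing(x, yn, 0.2, rising=False) - _crossing(x, yn, 0.8, rising=False)
    )
    # symmetry on the mirrored overlap
    lim = min(abs(x[0]), abs(x[-1]))
    if lim > 0:
        xs = np.linspace(0.0, lim, 201)
        d0 = np.interp(0.0, x, y)
        if d0 <= 0:
            raise MetricError("zero dose at profile center")
        sym = float(
            np.max(np.abs(np.interp(xs, x, y) - np.interp(-xs[::-1], x, y)[::-1]))
            / d0
        )
    else:
        sym = 0.0
    return ProfileMetrics(float(fwhm), float(pen_left), float(pen_right), sym)
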
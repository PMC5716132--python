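"""Daisy-chained relative output factors with uncertainty propagation.

The relative output factor of a cone of nominal diameter A is

    ROF(A) = D_w(A, d_ref = 15 mm) / D_w(100 x 100 mm^2, d_ref = 15 mm).

Because no single detector behaves in both a 5 mm cone and the reference
field, the ratio is measured through an intermediate 20 mm cone where both a
small-field diode and a plane-parallel chamber respond reliably:

    ROF(A) = [D_Si(A) / D_Si(20)] * [D_w^IC(20) / D_w^IC(ref)]

and the residual silicon/water response difference is removed by the
field-size-dependent factor k^A_20 = k_w^Si(A) / k_w^Si(20):

    ROF_corr(A) = k^A_20 * ROF_meas(A).

Uncertainties are 1-sigma absolute and propagate through products/ratios by
uncorrelated relative quadrature.  Rounding for reported tables is half-up
(3 decimals for ROFs, 2 for percent deviations), applied at the presentation
layer only; full precision is retained internally.

The module ships the published worked-example dataset for BrainLAB cones on
a Varian Trilogy (6 MV SRS mode): k factors, measured/corrected/Monte-Carlo
ROFs and diode-vs-MC deviations per cone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .detectors import Reading
from .errors import AssemblyError, NormalizationError, ValidationError

__all__ = [
    "UncertainValue",
    "CorrectionTable",
    "RofRow",
    "RofTable",
    "round_half_up",
    "rof_direct",
    "k_from_paired_doses",
    "chain_rof",
    "apply_correction",
    "deviation_pct",
    "build_rof_table",
    "published_rof_table",
    "PUBLISHED_CONES_MM",
    "PUBLISHED_K_NORM",
    "PUBLISHED_ROF_MEASURED",
    "PUBLISHED_ROF_CORRECTED",
    "PUBLISHED_ROF_MC",
    "PUBLISHED_DEVIATION_PCT",
    "ROUNDING_CONSISTENT_ROWS",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.0005 -> 0.001 at 3 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class UncertainValue:
    """A dimensionless value with 1-sigma absolute uncertainty.

    Products and ratios treat operands as uncorrelated and combine relative
    uncertainties in quadrature.
    """

    value: float
    sigma: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")

    @property
    def relative(self) -> float:
        if self.value == 0:
            raise ZeroDivisionError("relative sigma undefined for zero value")
        return self.sigma / abs(self.value)

    def _coerce(self, other):
        if isinstance(other, UncertainValue):
            return other
        return UncertainValue(float(other), 0.0)

    def __mul__(self, other) -> "UncertainValue":
        other = self._coerce(other)
        v = self.value * other.value
        s = math.hypot(self.sigma * other.value, other.sigma * self.value)
        return UncertainValue(v, s)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "UncertainValue":
        other = self._coerce(other)
        if other.value == 0:
            raise ZeroDivisionError("division by an UncertainValue of zero")
        v = self.value / other.value
        s = abs(v) * math.hypot(
            self.sigma / abs(self.value) if self.value else 0.0, other.relative
        )
        return UncertainValue(v, s)

    def rounded(self, decimals: int = 3) -> "UncertainValue":
        return UncertainValue(
            round_half_up(self.value, decimals), round_half_up(self.sigma, decimals)
        )


# ---------------------------------------------------------------------------
# published worked-example dataset (BrainLAB cones, Varian Trilogy SRS mode)
# ---------------------------------------------------------------------------

#: Cones of the published cross-calibration table (mm).
PUBLISHED_CONES_MM = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)

#: Monte-Carlo silicon/water correction factors k^A_20 (value, 1 sigma).
PUBLISHED_K_NORM = {
    5.0: (0.961, 0.011),
    7.5: (0.978, 0.011),
    10.0: (0.983, 0.011),
    12.5: (0.985, 0.011),
    15.0: (0.991, 0.011),
    17.5: (0.994, 0.011),
    20.0: (1.000, 0.0),
}

#: Diode/chamber daisy-chained ROFs before the k correction.
PUBLISHED_ROF_MEASURED = {
    5.0: (0.711, 0.007),
    7.5: (0.797, 0.008),
    10.0: (0.850, 0.008),
    12.5: (0.889, 0.008),
    15.0: (0.905, 0.009),
    17.5: (0.916, 0.009),
    20.0: (0.926, 0.009),
}

#: Corrected ROFs as printed, k^A_20 x measured, rounded half-up to 3 decimals.
PUBLISHED_ROF_CORRECTED = {
    5.0: (0.683, 0.011),
    7.5: (0.779, 0.012),
    10.0: (0.836, 0.012),
    12.5: (0.876, 0.012),
    15.0: (0.897, 0.013),
    17.5: (0.911, 0.013),
    20.0: (0.926, 0.009),
}

#: Independent Monte-Carlo reference ROFs.
PUBLISHED_ROF_MC = {
    5.0: (0.692, 0.011),
    7.5: (0.793, 0.011),
    10.0: (0.850, 0.011),
    12.5: (0.889, 0.011),
    15.0: (0.906, 0.011),
    17.5: (0.923, 0.011),
    20.0: (0.933, 0.011),
}

#: Printed diode-vs-MC deviations (percent).
PUBLISHED_DEVIATION_PCT = {
    5.0: 1.32,
    7.5: 1.79,
    10.0: 1.67,
    12.5: 1.48,
    15.0: 1.00,
    17.5: 1.32,
    20.0: 0.75,
}

#: Rows whose printed deviation cell is exactly reproduced by half-up
#: rounding on the rounded table entries.  The 7.5 and 20.0 mm cells are off
#: by one unit in the last digit under any single rounding convention and are
#: excluded from exact checks.
ROUNDING_CONSISTENT_ROWS = (5.0, 10.0, 12.5, 15.0, 17.5)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rof_direct(dose_cone: UncertainValue, dose_ref: UncertainValue) -> UncertainValue:
    """Single-detector ROF: cone dose over reference-field dose."""
    if dose_ref.value <= 0:
        raise ZeroDivisionError("reference dose must be positive")
    return dose_cone / dose_ref


@dataclass(frozen=True)
class CorrectionTable:
    """Per-cone silicon/water conversion factors, raw and 20 mm-normalized.

    ``k_raw[A] = k_w^Si(A) = D_w / D_Si`` and ``k_norm[A] = k_raw(A) /
    k_raw(20)``; the 20 mm entry of ``k_norm`` is exactly 1 with zero sigma.
    """

    k_raw: dict
    k_norm: dict

    def __post_init__(self):
        if 20.0 not in self.k_norm:
            raise NormalizationError("CorrectionTable requires a 20 mm entry")
        anchor = self.k_norm[20.0]
        if anchor.value != 1.0 or anchor.sigma != 0.0:
            raise ValidationError("k_norm at 20 mm must be exactly 1 +/- 0")


def k_from_paired_doses(d_water: dict, d_cavity: dict) -> CorrectionTable:
    """Correction factors from paired in-water / in-cavity dose samples.

    ``d_water`` and ``d_cavity`` map cone diameter (mm) to
    :class:`UncertainValue` doses at the reference point, computed with and
    without the detector cavity present.  Raw factors are elementwise
    ratios; normalized factors divide by the 20 mm entry (which therefore
    becomes exactly 1 +/- 0, the sigmas of the other entries combining in
    quadrature).
    """
    if set(d_water) != set(d_cavity):
        raise ValidationError("water and cavity dose tables list different cones")
    if any(v.value <= 0 for v in list(d_water.values()) + list(d_cavity.values())):
        raise ValidationError("doses must be positive")
    k_raw = {a: d_water[a] / d_cavity[a] for a in d_water}
    if 20.0 not in k_raw:
        raise NormalizationError("missing 20 mm entry; cannot normalize k factors")
    anchor = k_raw[20.0]
    k_norm = {a: k / anchor for a, k in k_raw.items()}
    k_norm[20.0] = UncertainValue(1.0, 0.0)
    return CorrectionTable(k_raw=k_raw, k_norm=k_norm)


def _require_same_conditions(readings):
    ssds = {r.ssd_mm for r in readings}
    depths = {r.depth_mm for r in readings}
    if len(ssds) > 1 or len(depths) > 1:
        raise ValidationError(
            f"daisy-chain readings must share SSD/depth conditions "
            f"(got SSDs {sorted(ssds)}, depths {sorted(depths)})"
        )


def _to_uv(reading: Reading) -> UncertainValue:
    if reading.value <= 0:
        raise ValidationError("chain readings must be positive")
    return UncertainValue(reading.value, reading.sigma)


def chain_rof(
    diode_cone: Reading,
    diode_20: Reading,
    chamber_20: Reading,
    chamber_ref: Reading,
    k_norm: UncertainValue,
):
    """Two-detector daisy-chained ROF, uncorrected and k-corrected.

    measured = (diode_A / diode_20) * (chamber_20 / chamber_ref);
    corrected = k^A_20 * measured.  Returns ``(measured, corrected)``.
    """
    _require_same_conditions([diode_cone, diode_20, chamber_20, chamber_ref])
    measured = (_to_uv(diode_cone) / _to_uv(diode_20)) * (
        _to_uv(chamber_20) / _to_uv(chamber_ref)
    )
    corrected = apply_correction(measured, k_norm)
    return measured, corrected


def apply_correction(
    measured: UncertainValue, k_norm: UncertainValue
) -> UncertainValue:
    """k^A_20 x measured ROF, sigmas in quadrature (full precision retained)."""
    if measured.value <= 0 or k_norm.value <= 0:
        raise ValidationError("measured ROF and k factor must be positive")
    return k_norm * measured


def deviation_pct(reference: UncertainValue, corrected: UncertainValue) -> float:
    """Percent deviation of a reference ROF from the corrected ROF.

    Computed as 100*(reference - corrected)/corrected on the 3-decimal
    (half-up) table entries, reported half-up to 2 decimals — the convention
    that reproduces the published deviation column.
    """
    ref = round_half_up(reference.value, 3)
    corr = round_half_up(corrected.value, 3)
    if corr <= 0:
        raise ZeroDivisionError("corrected ROF must be positive")
    return round_half_up(100.0 * (ref - corr) / corr, 2)


@dataclass(frozen=True)
class RofRow:
    """One cone's row of the output-factor table."""

    cone_mm: float
    k_norm: UncertainValue
    rof_measured: UncertainValue
    rof_corrected: UncertainValue
    rof_reference: UncertainValue
    deviation_pct: float


@dataclass(frozen=True)
class RofTable:
    """Per-cone measured/corrected/reference ROFs with k factors.

    ``rof_corrected`` stores full precision; the serialized table rounds
    half-up to 3 decimals (ROFs) and 2 decimals (deviations).
    """

    rows: tuple

    def __post_init__(self):
        for row in self.rows:
            for uv in (row.rof_measured, row.rof_corrected, row.rof_reference):
                if not (0.0 < uv.value <= 1.0 + 1e-9):
                    raise ValidationError(
                        f"ROF {uv.value} for cone {row.cone_mm} outside (0, 1]"
                    )

    def cones(self):
        return tuple(r.cone_mm for r in self.rows)

    def row(self, cone_mm: float) -> RofRow:
        for r in self.rows:
            if r.cone_mm == cone_mm:
                return r
        raise KeyError(cone_mm)

    def to_frame(self) -> pd.DataFrame:
        """Presentation-layer table (half-up rounded), published column order."""
        rec = []
        for r in self.rows:
            rec.append(
                {
                    "cone_mm": r.cone_mm,
                    "k_norm": round_half_up(r.k_norm.value, 3),
                    "k_norm_sigma": round_half_up(r.k_norm.sigma, 3),
                    "rof_measured": round_half_up(r.rof_measured.value, 3),
                    "rof_measured_sigma": round_half_up(r.rof_measured.sigma, 3),
                    "rof_corrected": round_half_up(r.rof_corrected.value, 3),
                    "rof_corrected_sigma": round_half_up(r.rof_corrected.sigma, 3),
                    "rof_reference": round_half_up(r.rof_reference.value, 3),
                    "rof_reference_sigma": round_half_up(r.rof_reference.sigma, 3),
                    "deviation_pct": r.deviation_pct,
                }
            )
        return pd.DataFrame.from_records(rec)


def build_rof_table(
    cones_mm,
    k_norm: dict,
    measured: dict,
    reference: dict,
) -> RofTable:
    """Assemble the per-cone output-factor table.

    ``k_norm``, ``measured`` and ``reference`` map cone diameter (mm) to
    :class:`UncertainValue`.  Every requested cone must be present in all
    three maps; gaps are reported together.
    """
    missing = [
        (a, name)
        for a in cones_mm
        for name, table in (
            ("k_norm", k_norm),
            ("measured", measured),
            ("reference", reference),
        )
        if a not in table
    ]
    if missing:
        raise AssemblyError(
            "incomplete inputs: " + ", ".join(f"{n}[{a}]" for a, n in missing),
            missing=missing,
        )
    rows = []
    for a in cones_mm:
        corrected = apply_correction(measured[a], k_norm[a])
        rows.append(
            RofRow(
                cone_mm=float(a),
                k_norm=k_norm[a],
                rof_measured=measured[a],
                rof_corrected=corrected,
                rof_reference=reference[a],
                deviation_pct=deviation_pct(reference[a], corrected),
            )
        )
    return RofTable(rows=tuple(rows))


def published_rof_table() -> RofTable:
    """The published worked example assembled from its printed inputs."""
    uv = UncertainValue
    return build_rof_table(
        PUBLISHED_CONES_MM,
        {a: uv(*PUBLISHED_K_NORM[a]) for a in PUBLISHED_CONES_MM},
        {a: uv(*PUBLISHED_ROF_MEASURED[a]) for a in PUBLISHED_CONES_MM},
        {a: uv(*PUBLISHED_ROF_MC[a]) for a in PUBLISHED_CONES_MM},
    )
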
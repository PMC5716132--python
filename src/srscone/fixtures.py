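"""Synthetic measurement-set generator (fixture emitter).

``make_fixtures`` emits, deterministically per (config, seed), a complete
synthetic commissioning data set:

* a PDD scan (0-150 mm, 1 mm) and an OAR scan (SSD 92.5 cm, depth 7.5 cm)
  per cone;
* a detector reading table at the reference point (diode for every cone,
  chamber for the 20 mm cone and the reference field) with repeat-averaged
  multiplicative noise;
* the water/cavity paired-dose k-factor table (noise-free, the synthetic
  stand-in for a Monte-Carlo detector simulation);
* ground-truth tables: true point-dose ROF per cone and the diode response
  factor RF(A), for parameter-recovery tests.

Each reported reading is the mean of ``noise_repeats`` acquisitions with
``noise_relative_sigma`` Gaussian multiplicative noise; the tabulated sigma
is the standard error of that mean.  All files carry ``#seed`` and
``#config_sha256`` provenance comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .detectors import read
from .errors import ValidationError
from .io import write_scan_csv, write_table_csv
from .rof_pipeline import UncertainValue, k_from_paired_doses
from .synthetic_field import DoseField, ScanRequest, simulate_scan

__all__ = ["make_fixtures", "reference_readings", "paired_dose_tables"]

#: Reference-field label used in reading tables.
REFERENCE_FIELD_LABEL = 112.838  # equal-area circle of 100 x 100 mm^2, mm


def _noisy_reading(value: float, rng, rel_sigma: float, repeats: int):
    """Mean and standard error of ``repeats`` noisy acquisitions."""
    draws = value * (1.0 + rel_sigma * rng.standard_normal(repeats))
    if repeats == 1:
        return float(draws[0]), value * rel_sigma
    return float(draws.mean()), float(draws.std(ddof=1) / np.sqrt(repeats))


def _field(cfg: RunConfig, cone, ssd_mm):
    return DoseField(
        cfg.beam,
        cone,
        ssd_mm,
        grid_step=cfg.grid_step_mm,
        n_spot_samples=cfg.spot_samples,
        seed=cfg.seed_for("spot-sampling"),
    )


def reference_readings(cfg: RunConfig, rng=None) -> pd.DataFrame:
    """Reading table at the reference point (SSD 100 cm, depth 15 mm).

    Diode rows for every configured cone; chamber rows for the intermediate
    cone and the reference field.  With ``rng`` given, repeat-averaged noise
    is applied; otherwise readings are exact.
    """
    diode = cfg.detector("srs_diode")
    chamber = cfg.detector("markus")
    point = np.array([0.0, 0.0, cfg.ssd_mm + cfg.reference_depth_mm])
    seed = cfg.seed_for("footprint-sampling")
    rows = []

    def emit(detector, cone, label):
        fld = _field(cfg, cone, cfg.ssd_mm)
        exact = read(detector, fld, point, cone.nominal_diameter, seed=seed).value
        if rng is None:
            value, sigma = exact, 0.0
        else:
            value, sigma = _noisy_reading(
                exact, rng, cfg.noise_relative_sigma, cfg.noise_repeats
            )
        rows.append(
            {
                "detector": detector.name,
                "cone_mm": label,
                "ssd_mm": cfg.ssd_mm,
                "depth_mm": cfg.reference_depth_mm,
                "value": value,
                "sigma": sigma,
            }
        )

    for a in sorted(cfg.cones):
        emit(diode, cfg.cone(a), a)
    emit(chamber, cfg.cone(cfg.intermediate_cone_mm), cfg.intermediate_cone_mm)
    emit(chamber, cfg.reference_cone(), REFERENCE_FIELD_LABEL)
    return pd.DataFrame.from_records(rows)


def paired_dose_tables(cfg: RunConfig):
    """(d_water, d_cavity) UncertainValue maps for the diode k factors."""
    from .detectors import paired_dose_samples

    diode = cfg.detector("srs_diode")
    d_water, d_cavity = {}, {}
    seed = cfg.seed_for("spot-sampling")
    for a in sorted(cfg.cones):
        cone = cfg.cone(a)
        d_water[a] = UncertainValue(
            paired_dose_samples(
                cfg.beam, cone, diode, with_cavity=False,
                ssd_mm=cfg.ssd_mm, depth_mm=cfg.reference_depth_mm, seed=seed,
            )
        )
        d_cavity[a] = UncertainValue(
            paired_dose_samples(
                cfg.beam, cone, diode, with_cavity=True,
                ssd_mm=cfg.ssd_mm, depth_mm=cfg.reference_depth_mm, seed=seed,
            )
        )
    return d_water, d_cavity


def true_rof_table(cfg: RunConfig) -> pd.DataFrame:
    """Ground-truth point-dose ROF per cone (no detector, no noise)."""
    ref_field = _field(cfg, cfg.reference_cone(), cfg.ssd_mm)
    d_ref = ref_field.cax_dose(cfg.reference_depth_mm)
    rows = []
    for a in sorted(cfg.cones):
        fld = _field(cfg, cfg.cone(a), cfg.ssd_mm)
        rows.append({"cone_mm": a, "rof_true": fld.cax_dose(cfg.reference_depth_mm) / d_ref})
    return pd.DataFrame.from_records(rows)


def make_fixtures(cfg: RunConfig, out_dir, seed: int | None = None, force: bool = False):
    """Emit the complete synthetic measurement set as CSV files.

    Deterministic per (config, seed): the same seed yields byte-identical
    outputs.  Refuses to write into an existing non-empty directory unless
    ``force`` is set.  Returns the list of written paths.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(
            f"output directory {out} is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        from dataclasses import replace

        cfg = replace(cfg, seed=int(seed))
    provenance = {"seed": cfg.seed, "config_sha256": cfg.config_hash()}
    written = []

    # scans
    for a in sorted(cfg.cones):
        cone = cfg.cone(a)
        pdd = simulate_scan(
            cfg.beam,
            cone,
            ScanRequest(
                scan_type="PDD",
                ssd_mm=cfg.ssd_mm,
                positions=tuple(np.arange(0.0, 151.0, 1.0)),
            ),
            grid_step=cfg.grid_step_mm,
            n_spot_samples=cfg.spot_samples,
            seed=cfg.seed_for("spot-sampling"),
        )
        pdd.metadata.update({f"fixture_{k}": v for k, v in provenance.items()})
        path = out / f"pdd_{a:g}mm.csv"
        write_scan_csv(pdd, path)
        written.append(path)

        oar = simulate_scan(
            cfg.beam,
            cone,
            ScanRequest(
                scan_type="OAR",
                ssd_mm=925.0,
                depth_mm=75.0,
                positions=tuple(np.round(np.arange(-25.0, 25.0 + 1e-9, 0.25), 6)),
            ),
            grid_step=cfg.grid_step_mm,
            n_spot_samples=cfg.spot_samples,
            seed=cfg.seed_for("spot-sampling"),
        )
        oar.metadata.update({f"fixture_{k}": v for k, v in provenance.items()})
        path = out / f"oar_{a:g}mm.csv"
        write_scan_csv(oar, path)
        written.append(path)

    # noisy reading table
    rng = np.random.default_rng(cfg.seed_for("reading-noise"))
    readings = reference_readings(cfg, rng=rng)
    path = out / "readings.csv"
    write_table_csv(readings, path, provenance)
    written.append(path)

    # k factors from paired doses (noise-free)
    d_water, d_cavity = paired_dose_tables(cfg)
    ktab = k_from_paired_doses(d_water, d_cavity)
    kframe = pd.DataFrame.from_records(
        [
            {
                "cone_mm": a,
                "k_raw": ktab.k_raw[a].value,
                "k_raw_sigma": ktab.k_raw[a].sigma,
                "k_norm": ktab.k_norm[a].value,
                "k_norm_sigma": ktab.k_norm[a].sigma,
            }
            for a in sorted(d_water)
        ]
    )
    path = out / "k_factors.csv"
    write_table_csv(kframe, path, provenance)
    written.append(path)

    # ground truth
    path = out / "rof_truth.csv"
    write_table_csv(true_rof_table(cfg), path, provenance)
    written.append(path)

    diode = cfg.detector("srs_diode")
    rf_frame = pd.DataFrame.from_records(
        [{"cone_mm": a, "rf": diode.rf(a)} for a in sorted(cfg.cones)]
    )
    path = out / "rf_truth.csv"
    write_table_csv(rf_frame, path, provenance)
    written.append(path)
    return written
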
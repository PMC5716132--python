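"""Run configuration: beam, cone set, detectors, pipeline constants, seeds.

The configuration is a human-readable YAML tree.  All randomness in a run
flows from the single top-level ``seed``; per-purpose streams are derived
deterministically with :class:`numpy.random.SeedSequence` so that any output
is reproducible bit-for-bit from (config, seed).

The packaged cone aperture geometry is *invented*: no aperture drawings are
published for these cones, so the defaults place the openings at 630/700 mm
from the source with edge lines through the nominal radius at isocenter,
converging 4 m above the source (near-cylindrical, occlusion-free).  The
config file labels them accordingly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .detectors import DetectorSpec, markus_chamber, srs_diode
from .errors import ConfigurationError
from .synthetic_field import (
    BeamModel,
    ConeSpec,
    default_cone_set,
    reference_field_cone,
)

__all__ = ["RunConfig", "default_config", "load_config", "dump_config"]

#: schema version of the YAML layout
CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Validated in-memory run configuration."""

    beam: BeamModel
    cones: dict              # nominal diameter (mm) -> ConeSpec
    detectors: dict          # name -> DetectorSpec
    reference_depth_mm: float = 15.0
    reference_field_mm: tuple = (100.0, 100.0)
    intermediate_cone_mm: float = 20.0
    ssd_mm: float = 1000.0
    seed: int = 20120105
    noise_relative_sigma: float = 0.003
    noise_repeats: int = 10
    grid_step_mm: float = 0.1
    spot_samples: int = 600
    raw: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.intermediate_cone_mm not in self.cones:
            raise ConfigurationError(
                f"intermediate cone {self.intermediate_cone_mm} mm is not in the set"
            )
        if self.noise_repeats < 1:
            raise ConfigurationError("noise_repeats must be >= 1")

    def cone(self, nominal_mm: float) -> ConeSpec:
        try:
            return self.cones[float(nominal_mm)]
        except KeyError:
            raise ConfigurationError(
                f"cone {nominal_mm} mm not in configured set "
                f"{sorted(self.cones)}"
            ) from None

    def detector(self, name: str) -> DetectorSpec:
        try:
            return self.detectors[name]
        except KeyError:
            raise ConfigurationError(f"unknown detector {name!r}") from None

    def reference_cone(self) -> ConeSpec:
        """Equal-area circular stand-in for the rectangular reference field."""
        return reference_field_cone(self.beam)

    def config_hash(self) -> str:
        """Stable short hash of the canonical YAML dump (for logs/outputs)."""
        text = yaml.safe_dump(_to_tree(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def seed_for(self, purpose: str) -> int:
        """Deterministic sub-seed (< 2^31) for a named purpose."""
        digest = hashlib.sha256(purpose.encode()).digest()
        child = int.from_bytes(digest[:4], "big")
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(child,))
        return int(ss.generate_state(1)[0] % (2**31))


def _to_tree(cfg: RunConfig) -> dict:
    return {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": cfg.seed,
        "beam": {
            "focal_spot_diameter_mm": cfg.beam.focal_spot_diameter,
            "source_to_iso_mm": cfg.beam.source_to_iso,
            "mu_per_mm": cfg.beam.mu,
            "buildup_beta_per_mm": cfg.beam.buildup_beta,
            "kernel": [
                {"weight": w, "sigma_mm": s} for w, s in cfg.beam.kernel_components
            ],
            "output_normalization": cfg.beam.output_normalization,
        },
        "cones": {
            "note": "synthetic aperture geometry (no published drawings)",
            "set": {
                str(a): {
                    "top_radius_mm": c.top_radius,
                    "bottom_radius_mm": c.bottom_radius,
                    "top_distance_mm": c.top_distance,
                    "bottom_distance_mm": c.bottom_distance,
                }
                for a, c in sorted(cfg.cones.items())
            },
        },
        "detectors": {
            name: {
                "footprint_diameter_mm": d.footprint_diameter,
                "thickness_mm": d.thickness,
                "response_c": d.response_c,
                "response_lambda_mm": d.response_lambda,
                "averaging_samples": d.averaging_samples,
            }
            for name, d in sorted(cfg.detectors.items())
        },
        "pipeline": {
            "reference_depth_mm": cfg.reference_depth_mm,
            "reference_field_mm": list(cfg.reference_field_mm),
            "intermediate_cone_mm": cfg.intermediate_cone_mm,
            "ssd_mm": cfg.ssd_mm,
        },
        "noise": {
            "relative_sigma": cfg.noise_relative_sigma,
            "repeats": cfg.noise_repeats,
        },
        "numerics": {
            "grid_step_mm": cfg.grid_step_mm,
            "spot_samples": cfg.spot_samples,
        },
    }


def default_config(seed: int | None = None) -> RunConfig:
    """The packaged defaults (synthetic beam, nine cones, diode + chamber)."""
    beam = BeamModel()
    return RunConfig(
        beam=beam,
        cones=default_cone_set(beam),
        detectors={"srs_diode": srs_diode(), "markus": markus_chamber()},
        seed=20120105 if seed is None else int(seed),
    )


def dump_config(cfg: RunConfig, path) -> None:
    """Write the configuration as YAML."""
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(_to_tree(cfg), sort_keys=True))


def load_config(path=None, seed: int | None = None) -> RunConfig:
    """Load a YAML configuration (or the packaged defaults when path=None).

    Missing sections fall back to defaults; an explicit ``seed`` argument
    overrides the file.
    """
    if path is None:
        return default_config(seed)
    with open(path) as fh:
        tree = yaml.safe_load(fh) or {}
    if not isinstance(tree, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(tree)}")
    base = default_config()
    beam_tree = tree.get("beam", {})
    beam = BeamModel(
        focal_spot_diameter=beam_tree.get(
            "focal_spot_diameter_mm", base.beam.focal_spot_diameter
        ),
        source_to_iso=beam_tree.get("source_to_iso_mm", base.beam.source_to_iso),
        mu=beam_tree.get("mu_per_mm", base.beam.mu),
        buildup_beta=beam_tree.get("buildup_beta_per_mm", base.beam.buildup_beta),
        kernel_components=tuple(
            (k["weight"], k["sigma_mm"]) for k in beam_tree["kernel"]
        )
        if "kernel" in beam_tree
        else base.beam.kernel_components,
        output_normalization=beam_tree.get(
            "output_normalization", base.beam.output_normalization
        ),
    )
    cone_tree = tree.get("cones", {}).get("set")
    if cone_tree:
        cones = {
            float(a): ConeSpec(
                nominal_diameter=float(a),
                top_radius=c["top_radius_mm"],
                bottom_radius=c["bottom_radius_mm"],
                top_distance=c["top_distance_mm"],
                bottom_distance=c["bottom_distance_mm"],
            )
            for a, c in cone_tree.items()
        }
    else:
        cones = default_cone_set(beam)
    det_tree = tree.get("detectors")
    if det_tree:
        detectors = {
            name: DetectorSpec(
                name=name,
                footprint_diameter=d["footprint_diameter_mm"],
                thickness=d["thickness_mm"],
                response_c=d.get("response_c", 0.0),
                response_lambda=d.get("response_lambda_mm", 1.0),
                averaging_samples=d.get("averaging_samples", 128),
            )
            for name, d in det_tree.items()
        }
    else:
        detectors = dict(base.detectors)
    pipe = tree.get("pipeline", {})
    noise = tree.get("noise", {})
    numerics = tree.get("numerics", {})
    return RunConfig(
        beam=beam,
        cones=cones,
        detectors=detectors,
        reference_depth_mm=pipe.get("reference_depth_mm", base.reference_depth_mm),
        reference_field_mm=tuple(
            pipe.get("reference_field_mm", base.reference_field_mm)
        ),
        intermediate_cone_mm=pipe.get(
            "intermediate_cone_mm", base.intermediate_cone_mm
        ),
        ssd_mm=pipe.get("ssd_mm", base.ssd_mm),
        seed=int(seed if seed is not None else tree.get("seed", base.seed)),
        noise_relative_sigma=noise.get("relative_sigma", base.noise_relative_sigma),
        noise_repeats=noise.get("repeats", base.noise_repeats),
        grid_step_mm=numerics.get("grid_step_mm", base.grid_step_mm),
        spot_samples=numerics.get("spot_samples", base.spot_samples),
        raw=tree,
    )
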
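"""End-to-end run configuration and orchestration.

``RunConfig`` is one serializable YAML/JSON document describing a complete
run: phantom, instrument geometry, noise, reconstruction policies, rendering
and statistics choices, plus the seed. Unknown keys are rejected (fail-fast)
rather than ignored, and every default matches the corresponding module
default. ``run_pipeline`` executes simulate -> stokes -> derive -> rgb ->
extract -> t-test, writes every intermediate with provenance metadata
(config hash + seed), and is numerically reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .instrument import InstrumentGeometry, NoiseModel, simulate_acquisition
from .phantom import PhantomSpec, generate_phantom
from .rgb import build_default_response, hsi_to_rgb, shift_signed_plane
from .spectra import ROIMask, extract_mean_spectrum, per_band_ttest
from .stokes import compute_derived, compute_stokes

log = logging.getLogger("stokescope")

__all__ = ["RunConfig", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1

#: Canonical plane order in multi-plane outputs and manifests.
PLANE_ORDER = ("S0", "S1", "S2", "S3", "DOP", "DOLP", "DOCP")
SIGNED_PLANES = ("S1", "S2", "S3")


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    geometry: dict = field(default_factory=dict)  # InstrumentGeometry overrides
    noise_kind: str = "gaussian"
    noise_level: float = 0.01
    s0_floor: float | str = "auto"
    clip_policy: str = "clip"
    rgb_norm: str = "p99"
    parameters: list[str] = field(default_factory=lambda: ["S0", "DOP", "DOLP", "DOCP"])
    ttest_groups: tuple[str, str] = ("granulocyte", "lymphocyte")
    ttest_parameters: list[str] = field(default_factory=lambda: ["S0", "DOP", "DOLP"])
    equal_var: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {self.schema_version} "
                f"(this build reads version {CONFIG_SCHEMA_VERSION})"
            )
        self.ttest_groups = tuple(self.ttest_groups)
        bad = set(self.parameters) - set(PLANE_ORDER)
        if bad:
            raise ValueError(f"unknown parameter plane(s): {sorted(bad)}")
        # fail fast on unknown nested keys too
        _from_mapping(InstrumentGeometry, self.geometry, "geometry")
        _from_mapping(PhantomSpec, {**self.phantom, "seed": 0}, "phantom")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ttest_groups"] = list(self.ttest_groups)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_mapping(cls, dict(data), "run config")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- realized component objects ---------------------------------------
    def phantom_spec(self) -> PhantomSpec:
        merged = dict(self.phantom)
        merged.setdefault("seed", self.seed)
        if "image_size" in merged:
            merged["image_size"] = tuple(merged["image_size"])
        return _from_mapping(PhantomSpec, merged, "phantom")

    def instrument_geometry(self) -> InstrumentGeometry:
        return _from_mapping(InstrumentGeometry, self.geometry, "geometry")

    def noise_model(self) -> NoiseModel:
        if self.noise_kind == "none":
            return NoiseModel.none()
        return NoiseModel(kind=self.noise_kind, level=self.noise_level)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic pipeline and write all artifacts to ``out_dir``.

    Stages: phantom generation, four-analyzer acquisition, Stokes
    reconstruction, DOP derivation, synthetic-RGB rendering of all configured
    planes, ground-truth ROI spectra extraction and per-band group t-tests.
    Returns the output manifest (also written as ``manifest.json``). Any
    stage failure raises with the stage name prepended.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}
    manifest: dict = {"provenance": provenance, "files": {}}
    stage = "configure"
    try:
        stage = "simulate"
        scene = generate_phantom(config.phantom_spec())
        geom = config.instrument_geometry()
        stack = simulate_acquisition(
            scene, geom, config.noise_model(), seed=config.seed + 1
        )
        for label, plane in stack.planes().items():
            p = sio.write_cube(
                out_dir / f"analyzer_{label}.tif",
                plane,
                wavelengths=stack.wavelengths,
                metadata=provenance,
            )
            manifest["files"][f"analyzer/{label}"] = p.name
        labels_path = sio.write_mask(out_dir / "labels_foreground.png", scene.labels > 0)
        manifest["files"]["labels"] = labels_path.name

        stage = "stokes"
        stokes = compute_stokes(stack)
        for name, plane in stokes.planes().items():
            p = sio.write_cube(
                out_dir / f"stokes_{name}.tif",
                plane,
                wavelengths=stokes.wavelengths,
                metadata=provenance,
            )
            manifest["files"][f"stokes/{name}"] = p.name

        stage = "derive"
        floor = None if config.s0_floor == "auto" else float(config.s0_floor)
        derived = compute_derived(stokes, s0_floor=floor, clip_policy=config.clip_policy)
        for name, plane in derived.planes().items():
            p = sio.write_cube(
                out_dir / f"derived_{name}.tif",
                plane,
                wavelengths=derived.wavelengths,
                metadata={**provenance, "n_clipped": derived.n_clipped},
            )
            manifest["files"][f"derived/{name}"] = p.name
        manifest["n_clipped"] = derived.n_clipped

        stage = "rgb"
        planes = {**stokes.planes(), **derived.planes()}
        response = build_default_response(stokes.wavelengths)
        import imageio.v3 as iio

        for name in PLANE_ORDER:
            plane = planes[name]
            prov_extra = {}
            if name in SIGNED_PLANES:
                plane, (lo, hi) = shift_signed_plane(plane)
                prov_extra = {"signed_shift": [lo, hi]}
            img = hsi_to_rgb(plane, response, norm=config.rgb_norm, plane_name=name)
            path = out_dir / f"rgb_{name}.png"
            iio.imwrite(path, (img.rgb * 255).round().astype(np.uint8))
            manifest["files"][f"rgb/{name}"] = path.name

        stage = "extract"
        param_planes = {k: planes[k] for k in config.parameters}
        spectra = []
        for rec in scene.cell_records:
            roi = ROIMask(
                mask=scene.cell_mask(rec.cell_id),
                cell_id=rec.cell_id,
                class_label=rec.class_label,
            )
            for pname, plane in param_planes.items():
                spectra.append(
                    extract_mean_spectrum(
                        plane, roi, wavelengths=stokes.wavelengths, parameter_name=pname
                    )
                )
        spectra_path = sio.write_spectra_csv(out_dir / "spectra.csv", spectra)
        manifest["files"]["spectra"] = spectra_path.name
        manifest["n_cells"] = len(scene.cell_records)

        stage = "ttest"
        ga, gb = config.ttest_groups
        series = []
        for pname in config.ttest_parameters:
            group_a = [s for s in spectra if s.class_label == ga and s.parameter_name == pname]
            group_b = [s for s in spectra if s.class_label == gb and s.parameter_name == pname]
            if len(group_a) >= 2 and len(group_b) >= 2:
                series.append(
                    per_band_ttest(group_a, group_b, equal_var=config.equal_var, adjust="bh")
                )
        if series:
            pv_path = sio.write_pvalues_csv(out_dir / "pvalues.csv", series)
            manifest["files"]["pvalues"] = pv_path.name

        stage = "manifest"
        config.to_yaml(out_dir / "config.yaml")
        manifest["files"]["config"] = "config.yaml"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        manifest["files"]["manifest"] = "manifest.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest
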
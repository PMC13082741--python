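"""Forward model of the polarization state generator (PSG) and analyzer (PSA).

The instrument is a transmission microscope with, in light-path order:

1. Polarizer 1 (PSG), transmissive axis 45 deg — conditions the illumination;
2. the sample;
3. LCVR 1 (fast axis 0 deg), LCVR 2 (fast axis 45 deg), Polarizer 2
   (axis 0 deg) — together the PSA;
4. the camera, which records only total intensity.

Four retardance settings of the two LCVRs turn the fixed horizontal analyzer
into four effective analyzers — horizontal, vertical, 45-degree linear and
right-circular — whose intensities (Ih, Iv, I45, Irc) determine the full
Stokes vector of the light leaving the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cubes import ANALYZER_LABELS, AnalyzerStack
from .mueller import linear_polarizer, variable_retarder

__all__ = [
    "InstrumentGeometry",
    "PSAConfig",
    "CANONICAL_CONFIGS",
    "NoiseModel",
    "psa_matrix",
    "psa_intensity",
    "illumination_after_psg",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class InstrumentGeometry:
    """Orientation (degrees) of the four polarization elements."""

    polarizer1_axis: float = 45.0
    polarizer2_axis: float = 0.0
    lcvr1_fast_axis: float = 0.0
    lcvr2_fast_axis: float = 45.0


@dataclass(frozen=True)
class PSAConfig:
    """One retardance setting of the two LCVRs, labelled by the effective analyzer."""

    retardance_lcvr1: float
    retardance_lcvr2: float
    label: str

    def __post_init__(self):
        if self.label not in ANALYZER_LABELS:
            raise ValueError(f"label must be one of {ANALYZER_LABELS}, got {self.label!r}")


#: The four canonical LCVR settings: (0,0) horizontal, (0,pi) vertical,
#: (pi/2,pi/2) 45-degree linear, (0,pi/2) right-circular analyzer.
CANONICAL_CONFIGS: dict[str, PSAConfig] = {
    "Ih": PSAConfig(0.0, 0.0, "Ih"),
    "Iv": PSAConfig(0.0, math.pi, "Iv"),
    "I45": PSAConfig(math.pi / 2, math.pi / 2, "I45"),
    "Irc": PSAConfig(0.0, math.pi / 2, "Irc"),
}


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise applied to simulated analyzer images.

    kind:
        ``"none"``, ``"gaussian"`` (sigma = ``level`` x full scale, where full
        scale is the maximum intensity across the four noiseless cubes), or
        ``"poisson"`` (counts drawn at ``level`` expected photons per unit
        intensity, then rescaled).
    """

    kind: str = "gaussian"
    level: float = 0.01

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none" and self.level <= 0:
            raise ValueError("noise level must be positive")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(kind="none", level=1.0)


def psa_matrix(cfg: PSAConfig, geom: InstrumentGeometry = InstrumentGeometry()) -> np.ndarray:
    """Mueller matrix of the full analyzer arm: Polarizer2 . LCVR2 . LCVR1."""
    return (
        linear_polarizer(geom.polarizer2_axis)
        @ variable_retarder(geom.lcvr2_fast_axis, cfg.retardance_lcvr2)
        @ variable_retarder(geom.lcvr1_fast_axis, cfg.retardance_lcvr1)
    )


def psa_intensity(
    s: np.ndarray, cfg: PSAConfig, geom: InstrumentGeometry = InstrumentGeometry()
) -> float:
    """Intensity recorded by the camera for light ``s`` entering the PSA.

    For the canonical configs this equals (S0+S1)/2, (S0-S1)/2, (S0+S2)/2 and
    (S0+S3)/2 respectively.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (4,):
        raise ValueError(f"expected a length-4 Stokes vector, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("Stokes vector contains non-finite values")
    return float(psa_matrix(cfg, geom)[0] @ s)


def illumination_after_psg(
    geom: InstrumentGeometry = InstrumentGeometry(), intensity0: float = 1.0
) -> np.ndarray:
    """Stokes vector of the illumination reaching the sample.

    An unpolarized source of intensity ``intensity0`` passes through
    Polarizer 1; for the default 45-degree axis the result is
    ``(intensity0/2) * (1, 0, 1, 0)``.
    """
    intensity0 = float(intensity0)
    if not np.isfinite(intensity0) or intensity0 < 0:
        raise ValueError(f"intensity0 must be finite and >= 0, got {intensity0}")
    return linear_polarizer(geom.polarizer1_axis) @ np.array([intensity0, 0.0, 0.0, 0.0])


def _apply_noise(
    planes: dict[str, np.ndarray], noise: NoiseModel, seed: int | None
) -> dict[str, np.ndarray]:
    if noise.kind == "none":
        return planes
    if seed is None:
        raise ValueError("a seed is required when the noise model is stochastic")
    rng = np.random.default_rng(seed)
    if noise.kind == "gaussian":
        full_scale = max(float(p.max()) for p in planes.values())
        sigma = noise.level * full_scale
        return {k: p + rng.normal(0.0, sigma, size=p.shape) for k, p in planes.items()}
    # poisson: `level` is the expected photon count per unit intensity
    return {
        k: rng.poisson(np.clip(p, 0.0, None) * noise.level).astype(float) / noise.level
        for k, p in planes.items()
    }


def simulate_acquisition(
    scene,
    geom: InstrumentGeometry = InstrumentGeometry(),
    noise: NoiseModel = NoiseModel(kind="none", level=1.0),
    seed: int | None = None,
    intensity0: float = 1.0,
) -> AnalyzerStack:
    """Simulate the four-analyzer acquisition sequence on a sample scene.

    For every pixel and band the illumination (unpolarized source through
    Polarizer 1) passes through the sample Mueller matrix; the exiting Stokes
    vector is projected onto each of the four canonical analyzer settings and
    detector noise is applied per analyzer image. With ``noise.kind == "none"``
    the output is bit-reproducible.

    Parameters
    ----------
    scene : SampleScene
        Synthetic sample field (see :mod:`stokescope.phantom`).
    geom, noise, seed, intensity0
        Instrument geometry, detector noise model, RNG seed (required for
        stochastic noise) and source intensity.
    """
    s_in = illumination_after_psg(geom, intensity0)
    exit_stokes = scene.exit_stokes(s_in)  # (bands, rows, cols, 4)
    planes = {}
    for label, cfg in CANONICAL_CONFIGS.items():
        row = psa_matrix(cfg, geom)[0]
        planes[label] = np.einsum("bijs,s->bij", exit_stokes, row)
    planes = _apply_noise(planes, noise, seed)
    return AnalyzerStack(
        i_h=planes["Ih"],
        i_v=planes["Iv"],
        i_45=planes["I45"],
        i_rc=planes["Irc"],
        wavelengths=scene.wavelengths,
        metadata={
            "geometry": geom,
            "noise": noise,
            "seed": seed,
            "intensity0": intensity0,
        },
    )
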
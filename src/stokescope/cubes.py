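"""Array containers shared across the pipeline.

All cubes are stored band-first, shape ``(bands, rows, cols)``, matching the
page order of the multi-page TIFF serialization. ``wavelengths`` holds the
band centers in nm for hyperspectral data; in broadband polarized-light (PLI)
mode it is ``None`` and ``band_labels`` names the three color channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["AnalyzerStack", "StokesCube", "DerivedCube", "ANALYZER_LABELS"]

ANALYZER_LABELS = ("Ih", "Iv", "I45", "Irc")


def _as_band_cube(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        a = a[np.newaxis]
    if a.ndim != 3:
        raise ValueError(f"{name} must be a (bands, rows, cols) cube, got shape {a.shape}")
    return a


def _check_bands(n_bands: int, wavelengths, band_labels):
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.shape != (n_bands,):
            raise ValueError(
                f"wavelength count {wavelengths.size} does not match band count {n_bands}"
            )
        if n_bands > 1 and not np.all(np.diff(wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
    if band_labels is not None and len(band_labels) != n_bands:
        raise ValueError(
            f"band label count {len(band_labels)} does not match band count {n_bands}"
        )
    return wavelengths


@dataclass
class AnalyzerStack:
    """The four co-registered analyzer intensity cubes (Ih, Iv, I45, Irc)."""

    i_h: np.ndarray
    i_v: np.ndarray
    i_45: np.ndarray
    i_rc: np.ndarray
    wavelengths: np.ndarray | None = None
    band_labels: Sequence[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.i_h = _as_band_cube(self.i_h, "i_h")
        for name in ("i_v", "i_45", "i_rc"):
            cube = _as_band_cube(getattr(self, name), name)
            if cube.shape != self.i_h.shape:
                raise ValueError(
                    f"analyzer plane {name} has shape {cube.shape}, "
                    f"expected {self.i_h.shape} (same as i_h)"
                )
            setattr(self, name, cube)
        self.wavelengths = _check_bands(self.n_bands, self.wavelengths, self.band_labels)
        for name in ANALYZER_LABELS:
            attr = {"Ih": "i_h", "Iv": "i_v", "I45": "i_45", "Irc": "i_rc"}[name]
            if not np.all(np.isfinite(getattr(self, attr))):
                raise ValueError(f"analyzer plane {name} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.i_h.shape

    @property
    def n_bands(self) -> int:
        return self.i_h.shape[0]

    def planes(self) -> dict[str, np.ndarray]:
        return {"Ih": self.i_h, "Iv": self.i_v, "I45": self.i_45, "Irc": self.i_rc}


@dataclass
class StokesCube:
    """Per-pixel, per-band Stokes parameters S0..S3."""

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    s3: np.ndarray
    wavelengths: np.ndarray | None = None
    band_labels: Sequence[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s0 = _as_band_cube(self.s0, "s0")
        for name in ("s1", "s2", "s3"):
            cube = _as_band_cube(getattr(self, name), name)
            if cube.shape != self.s0.shape:
                raise ValueError(f"{name} shape {cube.shape} != s0 shape {self.s0.shape}")
            setattr(self, name, cube)
        self.wavelengths = _check_bands(self.s0.shape[0], self.wavelengths, self.band_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s0.shape

    @property
    def n_bands(self) -> int:
        return self.s0.shape[0]

    def planes(self) -> dict[str, np.ndarray]:
        return {"S0": self.s0, "S1": self.s1, "S2": self.s2, "S3": self.s3}


@dataclass
class DerivedCube:
    """Degree-of-polarization maps derived from a StokesCube.

    ``mask_valid`` marks pixels whose S0 exceeded the floor; invalid pixels
    carry 0 in all three maps. ``n_clipped`` counts pixels whose raw ratio
    exceeded 1 and was clipped (noise artifacts).
    """

    dop: np.ndarray
    dolp: np.ndarray
    docp: np.ndarray
    mask_valid: np.ndarray
    wavelengths: np.ndarray | None = None
    band_labels: Sequence[str] | None = None
    n_clipped: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dop = _as_band_cube(self.dop, "dop")
        for name in ("dolp", "docp"):
            cube = _as_band_cube(getattr(self, name), name)
            if cube.shape != self.dop.shape:
                raise ValueError(f"{name} shape {cube.shape} != dop shape {self.dop.shape}")
            setattr(self, name, cube)
        self.mask_valid = np.asarray(self.mask_valid, dtype=bool)
        if self.mask_valid.shape != self.dop.shape:
            raise ValueError("mask_valid shape must match the derived cubes")
        self.wavelengths = _check_bands(self.dop.shape[0], self.wavelengths, self.band_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dop.shape

    def planes(self) -> dict[str, np.ndarray]:
        return {"DOP": self.dop, "DOLP": self.dolp, "DOCP": self.docp}
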
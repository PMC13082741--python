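"""Synthetic blood-smear phantoms for exercising the polarimetric pipeline.

A :class:`SampleScene` describes, per pixel and wavelength band, how the
sample transforms the illumination Stokes vector. The sample model is

    M(x, y, lambda) = t(x, y, lambda) * diag(1, d, d, d) * LR(axis, delta)

i.e. wavelength-dependent transmittance times an isotropic partial
depolarizer (polarized fraction ``d``) times an optional weak linear
retarder. This is the minimal model able to produce contrast in all of DOP,
DOLP and DOCP while staying passive (no gain).

:func:`generate_phantom` lays out non-overlapping elliptical white blood
cells of three morphological classes on a clear background:

* granulocyte-like — granular cytoplasm: small high-depolarization granules
  scattered at high spatial frequency;
* lymphocyte-like — a dense nucleus filling most of the cell with a
  low-amplitude surface texture in depolarization and retardance;
* monocyte-like — a large cell with a lobed, strongly absorbing nucleus.

All absorbing structures share a stain-like transmission spectrum with a
transmission minimum in the 520-550 nm region, scaled by a per-pixel
chromatin/stain density. The generator is a pure function of its spec,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_LABELS",
    "CellRecord",
    "SampleScene",
    "PhantomSpec",
    "default_stain_transmission",
    "generate_phantom",
]

#: Integer codes used in the scene label map.
CLASS_LABELS = {
    "background": 0,
    "granulocyte": 1,
    "lymphocyte": 2,
    "monocyte": 3,
    "nucleus": 4,
    "granule": 5,
}

_CELL_CLASSES = ("granulocyte", "lymphocyte", "monocyte")


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    class_label: str
    centroid: tuple[float, float]  # (row, col)
    n_pixels: int


@dataclass
class SampleScene:
    """Per-pixel, per-band parametric sample description plus ground truth.

    ``transmittance`` and ``depolarization`` have shape (bands, rows, cols)
    and live in [0, 1]. ``retardance`` (radians) and ``retardance_axis``
    (degrees) are per-pixel and wavelength-independent; both may be None.
    ``labels`` is the semantic class map (see :data:`CLASS_LABELS`) and
    ``cell_id_map`` assigns each pixel to a cell instance (0 = none).
    A full ``mueller_field`` of shape (bands, rows, cols, 4, 4) may be given
    instead of the parametric encoding and then takes precedence.
    """

    wavelengths: np.ndarray
    transmittance: np.ndarray
    depolarization: np.ndarray
    retardance: np.ndarray | None = None
    retardance_axis: np.ndarray | None = None
    labels: np.ndarray | None = None
    cell_id_map: np.ndarray | None = None
    cell_records: list[CellRecord] = field(default_factory=list)
    mueller_field: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or (
            self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0)
        ):
            raise ValueError("wavelengths must be a strictly increasing 1-D grid")
        if np.any(self.wavelengths < 400) or np.any(self.wavelengths > 800):
            raise ValueError("wavelengths must lie within [400, 800] nm")
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        self.depolarization = np.asarray(self.depolarization, dtype=float)
        expected = (self.wavelengths.size,) + self.spatial_shape
        for name in ("transmittance", "depolarization"):
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ValueError(f"{name} shape {arr.shape} != expected {expected}")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.labels is None:
            self.labels = np.zeros(self.spatial_shape, dtype=np.uint8)
        if self.cell_id_map is None:
            self.cell_id_map = np.zeros(self.spatial_shape, dtype=np.int32)
        for rec in self.cell_records:
            if not np.any(self.cell_id_map == rec.cell_id):
                raise ValueError(f"cell {rec.cell_id} ({rec.class_label}) has an empty mask")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.transmittance.shape[1:]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def cell_mask(self, cell_id: int) -> np.ndarray:
        """Boolean ground-truth mask of one cell instance."""
        mask = self.cell_id_map == cell_id
        if not mask.any():
            raise KeyError(f"no pixels carry cell id {cell_id}")
        return mask

    def exit_stokes(self, s_in: np.ndarray) -> np.ndarray:
        """Stokes field of the light leaving the sample, shape (bands, rows, cols, 4).

        ``s_in`` is the (constant) illumination Stokes vector hitting the
        sample; the per-pixel sample Mueller matrix is applied to it.
        """
        s_in = np.asarray(s_in, dtype=float)
        if s_in.shape != (4,):
            raise ValueError("s_in must be a length-4 Stokes vector")
        if self.mueller_field is not None:
            return np.einsum("bijkl,l->bijk", self.mueller_field, s_in)
        s0, s1, s2, s3 = s_in
        rows, cols = self.spatial_shape
        if self.retardance is not None:
            axis = (
                np.zeros(self.spatial_shape)
                if self.retardance_axis is None
                else np.asarray(self.retardance_axis, dtype=float)
            )
            two_a = 2.0 * np.deg2rad(axis)
            ca, sa = np.cos(two_a), np.sin(two_a)
            cd, sd = np.cos(self.retardance), np.sin(self.retardance)
            # rotate into the fast-axis frame, retard, rotate back
            v1 = ca * s1 + sa * s2
            v2 = -sa * s1 + ca * s2
            w2 = cd * v2 - sd * s3
            w3 = sd * v2 + cd * s3
            u1 = ca * v1 - sa * w2
            u2 = sa * v1 + ca * w2
        else:
            u1 = np.full(self.spatial_shape, s1)
            u2 = np.full(self.spatial_shape, s2)
            w3 = np.full(self.spatial_shape, s3)
        t, d = self.transmittance, self.depolarization
        out = np.empty(t.shape + (4,))
        out[..., 0] = t * s0
        out[..., 1] = t * d * u1[np.newaxis]
        out[..., 2] = t * d * u2[np.newaxis]
        out[..., 3] = t * d * w3[np.newaxis]
        return out

    def build_mueller_field(self) -> np.ndarray:
        """Materialize the per-pixel, per-band 4x4 Mueller field.

        Intended for small scenes and cross-checks; memory grows as
        bands x rows x cols x 16 doubles.
        """
        from .mueller import partial_depolarizer, variable_retarder

        nb, (rows, cols) = self.n_bands, self.spatial_shape
        out = np.zeros((nb, rows, cols, 4, 4))
        for i in range(rows):
            for j in range(cols):
                if self.retardance is not None:
                    axis = 0.0 if self.retardance_axis is None else self.retardance_axis[i, j]
                    ret = variable_retarder(axis, float(self.retardance[i, j]))
                else:
                    ret = np.eye(4)
                for b in range(nb):
                    depol = partial_depolarizer(float(self.depolarization[b, i, j]))
                    out[b, i, j] = self.transmittance[b, i, j] * (depol @ ret)
        return out


def default_stain_transmission(
    wavelengths: np.ndarray,
    min_wavelength: float = 535.0,
    min_transmission: float = 0.45,
    bandwidth: float = 40.0,
) -> np.ndarray:
    """Stain-like transmission spectrum with a minimum near ``min_wavelength``.

    Emulates the absorption band of Romanowsky-type (e.g. Wright's) stains,
    which produces the characteristic transmission "low peak" in the
    520-550 nm region. Returns values in [min_transmission, 1].
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    return 1.0 - (1.0 - min_transmission) * np.exp(
        -(((wavelengths - min_wavelength) / bandwidth) ** 2)
    )


@dataclass
class PhantomSpec:
    """Parameters of the synthetic blood-smear field.

    All contrasts and amplitudes are dimensionless fractions in [0, 1];
    radii are pixels; ``seed`` fully determines the output.
    """

    image_size: tuple[int, int] = (160, 160)
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {"granulocyte": 3, "lymphocyte": 3, "monocyte": 2}
    )
    cell_radius_range: tuple[float, float] = (6.0, 10.0)
    granule_density: float = 0.08
    granule_depolarization_contrast: float = 0.5
    surface_texture_amplitude: float = 0.1
    nucleus_lobedness: float = 0.6
    class_depolarization: dict[str, float] = field(
        default_factory=lambda: {"granulocyte": 0.5, "lymphocyte": 0.3, "monocyte": 0.4}
    )
    depolarization_cell_sd: float = 0.05
    background_depolarization: float = 0.0
    wavelengths: Sequence[float] | np.ndarray = field(
        default_factory=lambda: np.arange(470.0, 751.0, 10.0)
    )
    stain_transmission_curve: Callable[[np.ndarray], np.ndarray] = default_stain_transmission
    seed: int = 0
    max_placement_attempts: int = 5000

    def __post_init__(self):
        for name in (
            "granule_density",
            "granule_depolarization_contrast",
            "surface_texture_amplitude",
            "nucleus_lobedness",
            "depolarization_cell_sd",
            "background_depolarization",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cls, v in self.class_depolarization.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"class_depolarization[{cls!r}] must be in [0, 1]")
        unknown = set(self.n_cells_per_class) - set(_CELL_CLASSES)
        if unknown:
            raise ValueError(f"unknown cell classes: {sorted(unknown)}")
        lo, hi = self.cell_radius_range
        if not 0 < lo <= hi:
            raise ValueError("cell_radius_range must satisfy 0 < lo <= hi")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle_rad: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-std spatially correlated noise field."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    std = raw.std()
    return raw / std if std > 0 else raw


def _place_cells(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses; returns per-cell geometry."""
    shape = spec.image_size
    occupied = np.zeros(shape, dtype=bool)
    placements = []
    lo, hi = spec.cell_radius_range
    order = [
        (cls, i)
        for cls in _CELL_CLASSES
        for i in range(spec.n_cells_per_class.get(cls, 0))
    ]
    for cls, _ in order:
        placed = False
        for _attempt in range(spec.max_placement_attempts):
            a = rng.uniform(lo, hi)
            b = rng.uniform(0.7, 1.0) * a
            if cls == "monocyte":  # monocytes are the largest WBC class
                a, b = 1.25 * a, 1.25 * b
            angle = rng.uniform(0, np.pi)
            margin = max(a, b) + 1.5
            if shape[0] - 2 * margin <= 0 or shape[1] - 2 * margin <= 0:
                break
            center = (
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            )
            mask = _ellipse_mask(shape, center, (a, b), angle)
            halo = ndimage.binary_dilation(mask, iterations=2)
            if not (halo & occupied).any():
                occupied |= halo
                placements.append((cls, center, (a, b), angle, mask))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a {cls} cell without overlap after "
                f"{spec.max_placement_attempts} attempts; reduce cell count or "
                f"radius, or enlarge the image"
            )
    return placements


def generate_phantom(spec: PhantomSpec) -> SampleScene:
    """Render a synthetic stained blood-smear scene from its spec.

    Deterministic given ``spec.seed``. Raises ``RuntimeError`` when the
    requested cells cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size
    wavelengths = np.asarray(spec.wavelengths, dtype=float)
    nb = wavelengths.size

    labels = np.zeros(shape, dtype=np.uint8)
    cell_id_map = np.zeros(shape, dtype=np.int32)
    density = np.zeros(shape)  # stain/chromatin density, scales absorption
    d_map = np.full(shape, spec.background_depolarization)
    retardance = np.zeros(shape)
    ret_axis = np.zeros(shape)
    records: list[CellRecord] = []

    for cell_id, (cls, center, semi_axes, angle, mask) in enumerate(
        _place_cells(spec, rng), start=1
    ):
        labels[mask] = CLASS_LABELS[cls]
        cell_id_map[mask] = cell_id
        d_cell = np.clip(
            rng.normal(spec.class_depolarization[cls], spec.depolarization_cell_sd),
            0.0,
            1.0,
        )
        d_map[mask] = d_cell

        if cls == "granulocyte":
            density[mask] = 0.45
            # scatter small granules: high-frequency depolarization texture
            n_px = int(mask.sum())
            n_gran = max(1, int(round(spec.granule_density * n_px / 4.0)))
            idx = np.flatnonzero(mask)
            centers = idx[rng.integers(0, idx.size, size=n_gran)]
            gran = np.zeros(shape, dtype=bool)
            gran.flat[centers] = True
            gran = ndimage.binary_dilation(gran, iterations=1) & mask
            if spec.granule_depolarization_contrast > 0 and gran.any():
                bump = spec.granule_depolarization_contrast * rng.uniform(
                    0.5, 1.0, size=int(gran.sum())
                )
                d_map[gran] = np.clip(d_map[gran] + bump, 0.0, 1.0)
                labels[gran] = CLASS_LABELS["granule"]
                density[gran] = 0.65
        elif cls == "lymphocyte":
            # dense nucleus fills most of the cell; weak surface texture in
            # both depolarization and retardance
            density[mask] = 0.65
            tex = _smooth_noise(rng, shape, sigma=1.2)
            d_map[mask] = np.clip(
                d_map[mask] + spec.surface_texture_amplitude * tex[mask], 0.0, 1.0
            )
            retardance[mask] = np.abs(
                0.3 * spec.surface_texture_amplitude * np.pi * _smooth_noise(rng, shape, 1.5)[mask]
            )
            ret_axis[mask] = (90.0 * (_smooth_noise(rng, shape, 2.0)[mask] + 1.0)) % 180.0
        else:  # monocyte: large lobed nucleus, stronger absorption
            density[mask] = 0.35
            a, b = semi_axes
            n_lobes = 2 + int(rng.integers(0, 2))
            nucleus = np.zeros(shape, dtype=bool)
            for _ in range(n_lobes):
                off = spec.nucleus_lobedness * 0.45 * min(a, b)
                lc = (
                    center[0] + rng.uniform(-off, off),
                    center[1] + rng.uniform(-off, off),
                )
                nucleus |= _ellipse_mask(
                    shape, lc, (0.55 * a, 0.55 * b), angle + rng.uniform(-0.5, 0.5)
                )
            nucleus &= mask
            labels[nucleus] = CLASS_LABELS["nucleus"]
            density[nucleus] = 0.8

        inside = mask
        records.append(
            CellRecord(
                cell_id=cell_id,
                class_label=cls,
                centroid=tuple(np.mean(np.nonzero(inside), axis=1)),
                n_pixels=int(inside.sum()),
            )
        )

    stain = np.clip(spec.stain_transmission_curve(wavelengths), 0.0, 1.0)
    # Beer-Lambert-like scaling: denser chromatin absorbs more of the stain band
    transmittance = 1.0 - (1.0 - stain)[:, None, None] * density[None]
    depolarization = np.broadcast_to(d_map, (nb,) + shape).copy()

    return SampleScene(
        wavelengths=wavelengths,
        transmittance=np.clip(transmittance, 0.0, 1.0),
        depolarization=np.clip(depolarization, 0.0, 1.0),
        retardance=retardance if retardance.any() else None,
        retardance_axis=ret_axis if retardance.any() else None,
        labels=labels,
        cell_id_map=cell_id_map,
        cell_records=records,
    )
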
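"""ROI spectral signatures and per-band group comparison.

A cell's spectral signature is the per-band arithmetic mean of a parameter
(S0, DOP, DOLP, DOCP, ...) over its binary ROI mask; background pixels are
excluded entirely. Groups of cells are compared band-by-band with a
two-sided two-sample t-test on the per-cell means (one value per cell per
band — pixels are never pooled across cells). Welch's unequal-variance
variant is the default; the pooled-variance Student's t is available via
``equal_var=True``. Raw p-values are always reported; Benjamini-Hochberg
adjusted values can be attached alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ROIMask",
    "Spectrum",
    "PValueSeries",
    "extract_mean_spectrum",
    "normalize_spectrum",
    "per_band_ttest",
    "find_spectral_extrema",
]


@dataclass
class ROIMask:
    """Binary region-of-interest mask for one cell.

    ``source_plane`` records which rendering the outline was drawn on
    (conventionally the S0 synthetic RGB).
    """

    mask: np.ndarray
    cell_id: int | str = 0
    class_label: str = ""
    source_plane: str = "S0"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not self.mask.any():
            raise ValueError(f"ROI mask for cell {self.cell_id!r} has no foreground pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Spectrum:
    """Per-band ROI mean of one parameter for one cell."""

    wavelengths: np.ndarray
    values: np.ndarray
    n_pixels: int
    parameter_name: str = ""
    cell_id: int | str = 0
    class_label: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values and wavelengths must have matching length")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass
class PValueSeries:
    """Per-band two-sided p-values for a two-group comparison."""

    wavelengths: np.ndarray
    p_values: np.ndarray
    group_sizes: tuple[int, int]
    parameter_name: str = ""
    t_statistics: np.ndarray | None = None
    adjusted: np.ndarray | None = None
    adjust_method: str | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.p_values.shape != self.wavelengths.shape:
            raise ValueError("p_values and wavelengths must have matching length")
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def extract_mean_spectrum(
    cube_plane: np.ndarray,
    mask: ROIMask | np.ndarray,
    wavelengths: np.ndarray | None = None,
    parameter_name: str = "",
) -> Spectrum:
    """Per-band mean of ``cube_plane`` over the ROI's foreground pixels.

    ``cube_plane`` has shape (bands, rows, cols). Background pixels do not
    enter the mean at all, so the result is invariant to anything outside
    the mask.
    """
    if not isinstance(mask, ROIMask):
        mask = ROIMask(mask)
    cube_plane = np.asarray(cube_plane, dtype=float)
    if cube_plane.ndim != 3:
        raise ValueError("cube_plane must have shape (bands, rows, cols)")
    if cube_plane.shape[1:] != mask.mask.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match cube spatial grid "
            f"{cube_plane.shape[1:]}"
        )
    values = cube_plane[:, mask.mask].mean(axis=1)
    if wavelengths is None:
        wavelengths = np.arange(cube_plane.shape[0], dtype=float)
    return Spectrum(
        wavelengths=wavelengths,
        values=values,
        n_pixels=mask.n_pixels,
        parameter_name=parameter_name,
        cell_id=mask.cell_id,
        class_label=mask.class_label,
    )


def normalize_spectrum(s: Spectrum, method: str = "max") -> Spectrum:
    """Normalize a spectrum by its maximum (``max``), its sum (``area``), or
    return it unchanged (``none``)."""
    if method == "none":
        return s
    if method not in ("max", "area"):
        raise ValueError(f"unknown normalization method {method!r}")
    denom = s.values.max() if method == "max" else s.values.sum()
    if denom == 0:
        raise ValueError(f"cannot {method}-normalize an all-zero spectrum")
    return Spectrum(
        wavelengths=s.wavelengths,
        values=s.values / denom,
        n_pixels=s.n_pixels,
        parameter_name=s.parameter_name,
        cell_id=s.cell_id,
        class_label=s.class_label,
    )


def _group_matrix(group: Sequence[Spectrum], wavelengths: np.ndarray) -> np.ndarray:
    rows = []
    for s in group:
        if s.wavelengths.shape != wavelengths.shape or not np.allclose(
            s.wavelengths, wavelengths
        ):
            raise ValueError(
                f"spectrum for cell {s.cell_id!r} is on a different band grid"
            )
        rows.append(s.values)
    return np.asarray(rows)


def per_band_ttest(
    group_a: Sequence[Spectrum],
    group_b: Sequence[Spectrum],
    equal_var: bool = False,
    adjust: str | None = None,
) -> PValueSeries:
    """Two-sided two-sample t-test at every band between two groups of cells.

    Each cell contributes its ROI-mean value per band. ``equal_var=False``
    (default) gives Welch's test. ``adjust="bh"`` attaches Benjamini-Hochberg
    adjusted p-values next to — never instead of — the raw ones.
    Symmetric: swapping the groups leaves every p-value unchanged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 spectra for a t-test")
    wavelengths = np.asarray(group_a[0].wavelengths, dtype=float)
    a = _group_matrix(group_a, wavelengths)
    b = _group_matrix(group_b, wavelengths)
    res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    # identical groups give 0/0 t-statistics -> no evidence against the null
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    t = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    adjusted = None
    if adjust is not None:
        if adjust.lower() != "bh":
            raise ValueError(f"unknown adjustment {adjust!r} (only 'bh' is supported)")
        adjusted = stats.false_discovery_control(p, method="bh")
    name = group_a[0].parameter_name or (group_b[0].parameter_name if group_b else "")
    return PValueSeries(
        wavelengths=wavelengths,
        p_values=p,
        group_sizes=(len(group_a), len(group_b)),
        parameter_name=name,
        t_statistics=t,
        adjusted=adjusted,
        adjust_method="bh" if adjusted is not None else None,
    )


def find_spectral_extrema(s: Spectrum) -> list[tuple[float, float, str]]:
    """Interior local extrema of a spectrum by three-point comparison.

    Endpoints are never reported. On a flat run of equal values the extremum
    is attributed to the shortest wavelength of the run. Returns
    ``(wavelength, value, kind)`` tuples in wavelength order, with ``kind``
    in {"peak", "trough"}.
    """
    v = s.values
    if v.size < 3:
        raise ValueError("need at least 3 bands to locate interior extrema")
    out = []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            out.append((float(s.wavelengths[i]), float(v[i]), "peak"))
        elif v[i] < v[i - 1] and v[i] <= v[i + 1]:
            out.append((float(s.wavelengths[i]), float(v[i]), "trough"))
    return out
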
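"""Synthetic-RGB rendering of hyperspectral data cubes.

Each output channel is the band-weighted sum of the cube against a spectral
response curve, followed by a display normalization. The default curves are
analytic Gaussian-lobe approximations of the CIE 1931 color-matching
functions (the multi-lobe fits of Wyman, Sloan & Shirley), clipped to
nonnegative and normalized to unit sum over the band grid — a response
"similar to the human eye" without requiring tabulated observer data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralResponse", "RGBImage", "build_default_response", "hsi_to_rgb",
           "shift_signed_plane"]


@dataclass
class SpectralResponse:
    """Per-band R/G/B weights on a wavelength grid; each curve sums to > 0."""

    wavelengths: np.ndarray
    r_curve: np.ndarray
    g_curve: np.ndarray
    b_curve: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n = self.wavelengths.size
        for name in ("r_curve", "g_curve", "b_curve"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != (n,):
                raise ValueError(f"{name} length {c.size} != band count {n}")
            if c.min() < 0:
                raise ValueError(f"{name} has negative weights")
            if not c.max() > 0:
                raise ValueError(f"{name} has no positive weight")
            setattr(self, name, c)

    def resampled(self, wavelengths: np.ndarray) -> "SpectralResponse":
        """Linear interpolation of the three curves onto a new band grid."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        curves = [
            np.interp(wavelengths, self.wavelengths, c)
            for c in (self.r_curve, self.g_curve, self.b_curve)
        ]
        return SpectralResponse(wavelengths, *curves)

    def as_matrix(self) -> np.ndarray:
        """(3, bands) weight matrix in R, G, B order."""
        return np.stack([self.r_curve, self.g_curve, self.b_curve])


@dataclass
class RGBImage:
    """Display-normalized 3-channel rendering of one cube plane."""

    rgb: np.ndarray  # (rows, cols, 3) in [0, 1]
    invalid_mask: np.ndarray  # (rows, cols) bool, True where input had NaNs
    provenance: dict = field(default_factory=dict)


# Gaussian-lobe fits of the CIE 1931 standard observer (piecewise sigmas).
def _lobe(wl: np.ndarray, peak: float, s_lo: float, s_hi: float, amp: float) -> np.ndarray:
    s = np.where(wl < peak, s_lo, s_hi)
    return amp * np.exp(-0.5 * ((wl - peak) / s) ** 2)


def _cie_xbar(wl: np.ndarray) -> np.ndarray:
    return (
        _lobe(wl, 599.8, 37.9, 31.0, 1.056)
        + _lobe(wl, 442.0, 16.0, 26.7, 0.362)
        - _lobe(wl, 501.1, 20.4, 26.2, 0.065)
    )


def _cie_ybar(wl: np.ndarray) -> np.ndarray:
    return _lobe(wl, 568.8, 46.9, 40.5, 0.821) + _lobe(wl, 530.9, 16.3, 31.1, 0.286)


def _cie_zbar(wl: np.ndarray) -> np.ndarray:
    return _lobe(wl, 437.0, 11.8, 36.0, 1.217) + _lobe(wl, 459.0, 26.0, 13.8, 0.681)


def build_default_response(wavelengths: np.ndarray) -> SpectralResponse:
    """Eye-like default response curves on the given band grid.

    The red curve is bimodal (main lobe near 600 nm plus the short-wavelength
    lobe of the CIE x-bar function), green peaks near 555 nm and blue near
    445 nm. Negative lobe contributions are clipped to zero and every curve
    is normalized to unit sum over the grid, so a spectrally flat cube maps
    to equal channels.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.ndim != 1 or wavelengths.size < 1:
        raise ValueError("wavelengths must be a non-empty 1-D grid")
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    if wavelengths.min() < 400 or wavelengths.max() > 800:
        raise ValueError("band grid must lie within [400, 800] nm")
    curves = []
    for fn in (_cie_xbar, _cie_ybar, _cie_zbar):
        c = np.clip(fn(wavelengths), 0.0, None)
        total = c.sum()
        if not total > 0:
            raise ValueError("response curve vanishes on this band grid")
        curves.append(c / total)
    return SpectralResponse(wavelengths, *curves)


def shift_signed_plane(plane: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine-shift a signed cube plane (e.g. S1..S3) into [0, 1].

    Returns the shifted plane and the (min, max) recorded for provenance.
    A constant plane maps to all zeros.
    """
    lo, hi = float(np.nanmin(plane)), float(np.nanmax(plane))
    if hi > lo:
        return (plane - lo) / (hi - lo), (lo, hi)
    return np.zeros_like(plane), (lo, hi)


def _normalize(channels: np.ndarray, norm: str) -> np.ndarray:
    """Display normalization of an (rows, cols, 3) channel stack."""
    if norm == "none":
        return channels
    if norm == "global":
        lo, hi = channels.min(), channels.max()
        return (channels - lo) / (hi - lo) if hi > lo else np.zeros_like(channels)
    if norm == "per_channel":
        out = np.empty_like(channels)
        for k in range(3):
            lo, hi = channels[..., k].min(), channels[..., k].max()
            out[..., k] = (
                (channels[..., k] - lo) / (hi - lo) if hi > lo else 0.0
            )
        return out
    m = re.fullmatch(r"p(\d{1,2}(?:\.\d+)?)", norm)
    if m:  # per-channel percentile clip: robust to <= (100-p)% hot pixels
        p = float(m.group(1))
        out = np.empty_like(channels)
        for k in range(3):
            lo = np.percentile(channels[..., k], 100 - p)
            hi = np.percentile(channels[..., k], p)
            if hi > lo:
                out[..., k] = np.clip((channels[..., k] - lo) / (hi - lo), 0.0, 1.0)
            else:
                out[..., k] = 0.0
        return out
    raise ValueError(f"unknown normalization {norm!r} (use global/per_channel/pNN/none)")


def hsi_to_rgb(
    cube_plane: np.ndarray,
    response: SpectralResponse,
    norm: str = "p99",
    plane_name: str = "",
) -> RGBImage:
    """Render one per-band cube plane to a synthetic RGB image.

    Each channel is ``sum_b plane[b] * curve[b]``; NaN pixels are excluded
    into ``invalid_mask`` (value 0 in the rendering) rather than propagated.
    Signed planes should be passed through :func:`shift_signed_plane` first.
    The weighted sum is linear in the plane; only the final display
    normalization (``norm``) is not.
    """
    cube_plane = np.asarray(cube_plane, dtype=float)
    if cube_plane.ndim != 3:
        raise ValueError("cube_plane must have shape (bands, rows, cols)")
    if cube_plane.shape[0] != response.wavelengths.size:
        raise ValueError(
            f"plane has {cube_plane.shape[0]} bands but response has "
            f"{response.wavelengths.size}"
        )
    invalid = np.any(np.isnan(cube_plane), axis=0)
    safe = np.where(np.isnan(cube_plane), 0.0, cube_plane)
    channels = np.einsum("kb,bij->ijk", response.as_matrix(), safe)
    channels[invalid] = 0.0
    out = _normalize(channels, norm)
    if norm != "none":  # "none" returns the raw weighted sums, possibly outside [0,1]
        out = np.clip(out, 0.0, 1.0)
    out[invalid] = 0.0
    return RGBImage(
        rgb=out,
        invalid_mask=invalid,
        provenance={"plane": plane_name, "norm": norm},
    )
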
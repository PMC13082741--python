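"""Mueller-calculus building blocks for polarization optics.

Stokes vectors are length-4 arrays ``(S0, S1, S2, S3)``: total intensity,
horizontal/vertical linear preference, +/-45 deg linear preference, and
circular preference. Optical elements are 4x4 real Mueller matrices acting on
Stokes vectors by matrix multiplication.

Sign conventions
----------------
Two conventions are free in Mueller calculus and are fixed here once:

* Frame rotation by ``theta`` uses ``S2' = -sin(2 theta) S1 + cos(2 theta) S2``
  (``rotation_mueller``), so a polarizer rotated *to* angle ``a`` is
  ``R(-a) . P(0) . R(a)``.
* The linear retarder at fast axis 0 maps ``(S2, S3)`` by
  ``S2' = cos(d) S2 - sin(d) S3``, ``S3' = sin(d) S2 + cos(d) S3``. With this
  handedness a quarter-wave retarder at 45 deg followed by a horizontal
  polarizer analyzes *right*-circular light: its transmitted intensity is
  ``(S0 + S3)/2``, which is what the four-measurement Stokes reconstruction
  assumes.

Both conventions are cross-checked against a brute-force Jones-to-Mueller
conversion in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "UNPOLARIZED",
    "rotation_mueller",
    "linear_polarizer",
    "variable_retarder",
    "partial_depolarizer",
    "stokes_dop",
    "is_physical_stokes",
]

IDENTITY: np.ndarray = np.eye(4)
#: Unit-intensity unpolarized Stokes vector.
UNPOLARIZED: np.ndarray = np.array([1.0, 0.0, 0.0, 0.0])


def _check_finite(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def rotation_mueller(angle_deg: float) -> np.ndarray:
    """Stokes frame-rotation matrix for a rotation by ``angle_deg`` degrees.

    Acts only on the linear components (S1, S2); S0 and S3 are invariant.
    ``rotation_mueller(a) @ rotation_mueller(-a)`` is the identity, and the
    matrix is 180-degree periodic on (S1, S2).
    """
    angle_deg = _check_finite(angle_deg, "angle_deg")
    two_theta = 2.0 * np.deg2rad(angle_deg)
    c, s = np.cos(two_theta), np.sin(two_theta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, s, 0.0],
            [0.0, -s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def linear_polarizer(axis_deg: float) -> np.ndarray:
    """Ideal linear polarizer with transmissive axis at ``axis_deg`` degrees.

    Transmits half of unpolarized light and outputs fully polarized light
    (DOP = 1) whenever the transmitted intensity is nonzero.
    """
    axis_deg = _check_finite(axis_deg, "axis_deg")
    p0 = 0.5 * np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return rotation_mueller(-axis_deg) @ p0 @ rotation_mueller(axis_deg)


def variable_retarder(fast_axis_deg: float, retardance_rad: float) -> np.ndarray:
    """Ideal linear retarder (wave plate / LCVR) Mueller matrix.

    Parameters
    ----------
    fast_axis_deg
        Orientation of the fast axis in degrees.
    retardance_rad
        Phase delay between fast and slow axes in radians; 0 and 2*pi give
        the identity, pi/2 is a quarter-wave plate, pi a half-wave plate.

    The retarder is lossless: it never changes S0.
    """
    fast_axis_deg = _check_finite(fast_axis_deg, "fast_axis_deg")
    retardance_rad = _check_finite(retardance_rad, "retardance_rad")
    c, s = np.cos(retardance_rad), np.sin(retardance_rad)
    r0 = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, c, -s],
            [0.0, 0.0, s, c],
        ]
    )
    return rotation_mueller(-fast_axis_deg) @ r0 @ rotation_mueller(fast_axis_deg)


def partial_depolarizer(d: float) -> np.ndarray:
    """Isotropic partial depolarizer ``diag(1, d, d, d)``.

    ``d`` is the retained polarized fraction: fully polarized input exits
    with DOP exactly ``d``. ``d = 1`` is transparent, ``d = 0`` an ideal
    depolarizer.
    """
    d = _check_finite(d, "d")
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"depolarization factor must be in [0, 1], got {d}")
    return np.diag([1.0, d, d, d])


def stokes_dop(s: np.ndarray) -> float:
    """Degree of polarization of a single Stokes vector (S0 > 0 required)."""
    s = np.asarray(s, dtype=float)
    if s.shape != (4,):
        raise ValueError(f"expected a length-4 Stokes vector, got shape {s.shape}")
    if s[0] <= 0:
        raise ValueError("DOP undefined for S0 <= 0")
    return float(np.sqrt(s[1] ** 2 + s[2] ** 2 + s[3] ** 2) / s[0])


def is_physical_stokes(s: np.ndarray, tol: float = 1e-12) -> bool:
    """True when S0 >= 0 and the polarized intensity does not exceed S0."""
    s = np.asarray(s, dtype=float)
    if s.shape != (4,):
        raise ValueError(f"expected a length-4 Stokes vector, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        return False
    return s[0] >= -tol and np.sqrt(s[1] ** 2 + s[2] ** 2 + s[3] ** 2) <= s[0] + tol
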
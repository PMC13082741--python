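"""Independent brute-force oracles used by the test suite.

The Jones-to-Mueller conversion provides a second, independent derivation of
every non-depolarizing optical element: build the 2x2 complex Jones matrix,
convert with M = A (J kron J*) A^-1, and compare with the analytic Mueller
forms under test. The Jones conventions here (retarder fast axis along x
advances phase by -delta/2) match the package's Stokes handedness, which is
pinned by the requirement that the (0, pi/2) LCVR setting behaves as a
right-circular analyzer.
"""

import numpy as np

_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_A_INV = np.linalg.inv(_A)


def jones_to_mueller(jones: np.ndarray) -> np.ndarray:
    """Brute-force Mueller matrix of a non-depolarizing Jones element."""
    m = _A @ np.kron(jones, jones.conj()) @ _A_INV
    assert np.allclose(m.imag, 0, atol=1e-12)
    return m.real


def jones_rotation(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    return np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])


def jones_polarizer(axis_deg: float) -> np.ndarray:
    p0 = np.array([[1.0, 0.0], [0.0, 0.0]])
    return jones_rotation(-axis_deg) @ p0 @ jones_rotation(axis_deg)


def jones_retarder(fast_axis_deg: float, retardance_rad: float) -> np.ndarray:
    r0 = np.diag([np.exp(-0.5j * retardance_rad), np.exp(0.5j * retardance_rad)])
    return jones_rotation(-fast_axis_deg) @ r0 @ jones_rotation(fast_axis_deg)


def random_physical_stokes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniformly sample physical Stokes vectors: random intensity, DOP and
    polarization direction on the Poincare sphere."""
    s0 = rng.uniform(0.05, 2.0, size=n)
    dop = rng.uniform(0.0, 1.0, size=n)
    vec = rng.standard_normal((n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    out = np.empty((n, 4))
    out[:, 0] = s0
    out[:, 1:] = (s0 * dop)[:, None] * vec
    return out
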
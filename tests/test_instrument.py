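"""PSG/PSA chain: analyzer identities, illumination, simulated acquisition."""

import numpy as np
import pytest

from stokescope import (
    CANONICAL_CONFIGS,
    InstrumentGeometry,
    NoiseModel,
    PhantomSpec,
    SampleScene,
    compute_stokes,
    generate_phantom,
    illumination_after_psg,
    psa_intensity,
    simulate_acquisition,
)
from oracles import random_physical_stokes


def analyzer_projection(label, s):
    s0, s1, s2, s3 = s
    return {
        "Ih": 0.5 * (s0 + s1),
        "Iv": 0.5 * (s0 - s1),
        "I45": 0.5 * (s0 + s2),
        "Irc": 0.5 * (s0 + s3),
    }[label]


@pytest.mark.parametrize(
    "label, s, expected",
    [
        ("Ih", [1, 1, 0, 0], 1.0),  # horizontal analyzer on horizontal light
        ("Iv", [1, 1, 0, 0], 0.0),  # extinction
        ("I45", [1, 0, 1, 0], 1.0),  # 45-deg analyzer on 45-deg light
        ("Irc", [1, 0, 0, 1], 1.0),  # right-circular analyzer fixes handedness
    ],
)
def test_canonical_analyzer_spot_checks(label, s, expected):
    val = psa_intensity(np.array(s, float), CANONICAL_CONFIGS[label])
    assert val == pytest.approx(expected, abs=1e-12)


def test_canonical_analyzer_identities_on_random_light(rng):
    """Every canonical LCVR setting projects exactly the named Stokes component."""
    for s in random_physical_stokes(rng, 200):
        for label, cfg in CANONICAL_CONFIGS.items():
            assert psa_intensity(s, cfg) == pytest.approx(
                analyzer_projection(label, s), abs=1e-12
            )


def test_psa_rejects_nonfinite_input():
    with pytest.raises(ValueError):
        psa_intensity(np.array([1.0, np.nan, 0.0, 0.0]), CANONICAL_CONFIGS["Ih"])


def test_canonical_retardance_values():
    cfgs = CANONICAL_CONFIGS
    assert (cfgs["Ih"].retardance_lcvr1, cfgs["Ih"].retardance_lcvr2) == (0.0, 0.0)
    assert (cfgs["Iv"].retardance_lcvr1, cfgs["Iv"].retardance_lcvr2) == (0.0, np.pi)
    assert (cfgs["I45"].retardance_lcvr1, cfgs["I45"].retardance_lcvr2) == (
        np.pi / 2,
        np.pi / 2,
    )
    assert (cfgs["Irc"].retardance_lcvr1, cfgs["Irc"].retardance_lcvr2) == (0.0, np.pi / 2)


def test_default_geometry():
    geom = InstrumentGeometry()
    assert geom.polarizer1_axis == 45.0
    assert geom.polarizer2_axis == 0.0
    assert geom.lcvr1_fast_axis == 0.0
    assert geom.lcvr2_fast_axis == 45.0


@pytest.mark.parametrize(
    "geom_kwargs, intensity0, expected",
    [
        ({}, 2.0, [1, 0, 1, 0]),  # default 45-deg PSG transmits half
        ({}, 0.0, [0, 0, 0, 0]),  # dark
        ({"polarizer1_axis": 0.0}, 2.0, [1, 1, 0, 0]),
    ],
)
def test_illumination_after_psg(geom_kwargs, intensity0, expected):
    out = illumination_after_psg(InstrumentGeometry(**geom_kwargs), intensity0)
    assert np.allclose(out, expected, atol=1e-12)


def test_illumination_rejects_negative_intensity():
    with pytest.raises(ValueError):
        illumination_after_psg(intensity0=-1.0)


def _single_pixel_scene(mueller):
    wl = np.array([550.0])
    return SampleScene(
        wavelengths=wl,
        transmittance=np.ones((1, 1, 1)),
        depolarization=np.ones((1, 1, 1)),
        mueller_field=np.asarray(mueller, float)[None, None, None],
    )


def test_identity_sample_acquisition():
    """Hand-derived intensities for a transparent sample under 45-deg illumination."""
    stack = _acquire(_single_pixel_scene(np.eye(4)))
    assert stack.i_h[0, 0, 0] == pytest.approx(0.25, abs=1e-12)
    assert stack.i_v[0, 0, 0] == pytest.approx(0.25, abs=1e-12)
    assert stack.i_45[0, 0, 0] == pytest.approx(0.5, abs=1e-12)
    assert stack.i_rc[0, 0, 0] == pytest.approx(0.25, abs=1e-12)


def test_ideal_depolarizer_sample_acquisition():
    """Unpolarized exit light: every analyzer transmits half of S0."""
    stack = _acquire(_single_pixel_scene(np.diag([1.0, 0, 0, 0])))
    for plane in stack.planes().values():
        assert plane[0, 0, 0] == pytest.approx(0.25, abs=1e-12)


def _acquire(scene, **kw):
    return simulate_acquisition(scene, **kw)


def test_noise_seed_determinism(standard_scene):
    noise = NoiseModel(kind="gaussian", level=0.01)
    a = simulate_acquisition(standard_scene, noise=noise, seed=5)
    b = simulate_acquisition(standard_scene, noise=noise, seed=5)
    c = simulate_acquisition(standard_scene, noise=noise, seed=6)
    assert np.array_equal(a.i_h, b.i_h) and np.array_equal(a.i_rc, b.i_rc)
    assert not np.array_equal(a.i_h, c.i_h)


def test_noise_requires_seed(standard_scene):
    with pytest.raises(ValueError, match="seed"):
        simulate_acquisition(standard_scene, noise=NoiseModel(kind="gaussian", level=0.01))


def test_poisson_noise_is_seeded_and_stochastic(standard_scene, clean_stack):
    noise = NoiseModel(kind="poisson", level=1e4)
    a = simulate_acquisition(standard_scene, noise=noise, seed=5)
    b = simulate_acquisition(standard_scene, noise=noise, seed=5)
    assert np.array_equal(a.i_45, b.i_45)
    assert not np.array_equal(a.i_45, clean_stack.i_45)


def test_acquisition_matches_exit_stokes_oracle(standard_scene, clean_stack):
    """Noiseless reconstruction returns the scene's exit Stokes field exactly."""
    s_in = illumination_after_psg()
    exit_field = standard_scene.exit_stokes(s_in)
    cube = compute_stokes(clean_stack)
    assert np.allclose(cube.s0, exit_field[..., 0], atol=1e-12)
    assert np.allclose(cube.s1, exit_field[..., 1], atol=1e-12)
    assert np.allclose(cube.s2, exit_field[..., 2], atol=1e-12)
    assert np.allclose(cube.s3, exit_field[..., 3], atol=1e-12)
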
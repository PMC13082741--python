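"""Stokes reconstruction and degree-of-polarization derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stokescope import (
    AnalyzerStack,
    NoiseModel,
    PhantomSpec,
    StokesCube,
    compute_derived,
    compute_stokes,
    generate_phantom,
    physicality_report,
    simulate_acquisition,
)
from stokescope.spectra import ROIMask, extract_mean_spectrum


def _stack(ih, iv, i45, irc):
    shape = (1, 1, 1)
    return AnalyzerStack(
        i_h=np.full(shape, float(ih)),
        i_v=np.full(shape, float(iv)),
        i_45=np.full(shape, float(i45)),
        i_rc=np.full(shape, float(irc)),
    )


@pytest.mark.parametrize(
    "intensities, expected",
    [
        ((1, 0, 0.5, 0.5), (1, 1, 0, 0)),  # horizontal linear light
        ((0.5, 0.5, 0.5, 0.5), (1, 0, 0, 0)),  # unpolarized
        ((0.5, 0.5, 0.5, 1.0), (1, 0, 0, 1)),  # right-circular
        ((0.25, 0.25, 0.5, 0.25), (0.5, 0, 0.5, 0)),  # transparent sample, 45-deg PSG
    ],
)
def test_reconstruction_examples(intensities, expected):
    cube = compute_stokes(_stack(*intensities))
    got = tuple(float(p[0, 0, 0]) for p in cube.planes().values())
    assert got == pytest.approx(expected, abs=1e-12)


def test_shape_mismatch_names_offending_plane():
    with pytest.raises(ValueError, match="i_45"):
        AnalyzerStack(
            i_h=np.ones((2, 4, 4)),
            i_v=np.ones((2, 4, 4)),
            i_45=np.ones((2, 4, 5)),
            i_rc=np.ones((2, 4, 4)),
        )


@given(c=st.floats(0.1, 100.0))
@settings(max_examples=25, deadline=None)
def test_linearity_in_intensity_scale(c):
    """Scaling all four inputs by c scales Stokes planes by c and leaves the
    derived fractions unchanged."""
    base = np.random.default_rng(0).uniform(0.2, 1.0, size=(4, 2, 3, 3))
    s_a = compute_stokes(AnalyzerStack(*base))
    s_b = compute_stokes(AnalyzerStack(*(c * base)))
    for pa, pb in zip(s_a.planes().values(), s_b.planes().values()):
        assert np.allclose(c * pa, pb, rtol=1e-12, atol=1e-12)
    d_a = compute_derived(s_a, s0_floor=0.0)
    d_b = compute_derived(s_b, s0_floor=0.0)
    assert np.allclose(d_a.dop, d_b.dop, atol=1e-10)
    assert np.allclose(d_a.dolp, d_b.dolp, atol=1e-10)


def _derived_single(s0, s1, s2, s3, **kw):
    cube = StokesCube(
        s0=np.full((1, 1, 1), float(s0)),
        s1=np.full((1, 1, 1), float(s1)),
        s2=np.full((1, 1, 1), float(s2)),
        s3=np.full((1, 1, 1), float(s3)),
    )
    kw.setdefault("s0_floor", 0.0)
    d = compute_derived(cube, **kw)
    return float(d.dop[0, 0, 0]), float(d.dolp[0, 0, 0]), float(d.docp[0, 0, 0])


@pytest.mark.parametrize(
    "stokes, expected",
    [
        ((1, 1, 0, 0), (1.0, 1.0, 0.0)),  # fully linear
        ((1, 0, 0, 1), (1.0, 0.0, 1.0)),  # fully circular
        ((1, 0.6, 0, 0.8), (1.0, 0.6, 0.8)),  # 3-4-5 identity
        ((2, 1, 1, 0), (np.sqrt(2) / 2, np.sqrt(2) / 2, 0.0)),
    ],
)
def test_derived_examples(stokes, expected):
    assert _derived_single(*stokes) == pytest.approx(expected, abs=1e-12)


def test_dop_is_quadrature_sum_of_dolp_docp(noisy_stack):
    d = compute_derived(compute_stokes(noisy_stack))
    valid = d.mask_valid & (d.dop < 1.0)  # clipping breaks the identity by design
    assert np.allclose(
        d.dop[valid], np.hypot(d.dolp[valid], d.docp[valid]), atol=1e-12
    )
    for plane in (d.dop, d.dolp, d.docp):
        assert plane.min() >= 0.0 and plane.max() <= 1.0


def test_clip_policy_counts_and_bounds():
    # constructed unphysical pixel: polarized intensity 1.1 x S0
    dop_clip, _, _ = _derived_single(1, 1.1, 0, 0, clip_policy="clip")
    assert dop_clip == 1.0
    dop_flag, _, _ = _derived_single(1, 1.1, 0, 0, clip_policy="flag")
    assert dop_flag == pytest.approx(1.1, abs=1e-12)


def test_s0_floor_masks_dark_pixels():
    cube = StokesCube(
        s0=np.array([[[1.0, 1e-6]]]).reshape(1, 1, 2),
        s1=np.array([[[0.5, 1e-6]]]).reshape(1, 1, 2),
        s2=np.zeros((1, 1, 2)),
        s3=np.zeros((1, 1, 2)),
    )
    d = compute_derived(cube, s0_floor=1e-3)
    assert d.mask_valid[0, 0, 0] and not d.mask_valid[0, 0, 1]
    assert d.dop[0, 0, 1] == 0.0


def test_physicality_report_counts_constructed_violation():
    cube = StokesCube(
        s0=np.ones((1, 1, 2)),
        s1=np.array([[[1.1, 0.5]]]),
        s2=np.zeros((1, 1, 2)),
        s3=np.zeros((1, 1, 2)),
    )
    rep = physicality_report(cube)
    assert rep.total_violations == 1
    assert rep.max_violation == pytest.approx(0.1, abs=1e-12)


def test_noiseless_cube_has_no_violations(clean_stack):
    rep = physicality_report(compute_stokes(clean_stack))
    assert rep.total_violations == 0
    assert rep.max_violation == 0.0


def test_noisy_cube_violation_fraction_small_but_nonzero(noisy_stack):
    """1% detector noise produces rare physicality violations (at nearly fully
    polarized pixels), far below 5% of all pixels."""
    rep = physicality_report(compute_stokes(noisy_stack))
    assert rep.total_violations > 0
    assert rep.total_fraction < 0.05


def test_mean_dop_monotone_in_depolarization_factor():
    """Masked-mean DOP strictly increases with the phantom depolarization factor."""
    means = []
    for d in (0.1, 0.3, 0.5, 0.7, 0.9):
        spec = PhantomSpec(
            image_size=(64, 64),
            n_cells_per_class={"lymphocyte": 2},
            cell_radius_range=(5.0, 7.0),
            class_depolarization={"lymphocyte": d},
            depolarization_cell_sd=0.0,
            surface_texture_amplitude=0.0,
            seed=9,
        )
        scene = generate_phantom(spec)
        stack = simulate_acquisition(scene, noise=NoiseModel.none())
        derived = compute_derived(compute_stokes(stack))
        mask = scene.cell_id_map > 0
        means.append(float(derived.dop[:, mask].mean()))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_pli_rgb_mode_three_channels():
    """Broadband RGB-mode stacks (three labelled channels) reconstruct per channel."""
    rng = np.random.default_rng(2)
    base = rng.uniform(0.1, 0.9, size=(4, 3, 5, 5))
    stack = AnalyzerStack(*base, band_labels=["R", "G", "B"])
    cube = compute_stokes(stack)
    assert cube.band_labels == ["R", "G", "B"]
    assert np.allclose(cube.s0, base[0] + base[1], atol=1e-15)
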
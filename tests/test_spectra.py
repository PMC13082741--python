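"""ROI spectra, normalization, per-band t-tests and extrema detection."""

import numpy as np
import pytest
from scipy import stats

from stokescope import (
    ROIMask,
    Spectrum,
    extract_mean_spectrum,
    find_spectral_extrema,
    normalize_spectrum,
    per_band_ttest,
)
from stokescope.experiments import class_spectra, two_class_study
from stokescope import NoiseModel

WL = np.array([470.0, 480.0, 490.0])


def _spectrum(values, wavelengths=None, **kw):
    values = np.asarray(values, float)
    if wavelengths is None:
        wavelengths = 470.0 + 10.0 * np.arange(values.size)
    kw.setdefault("n_pixels", 10)
    return Spectrum(wavelengths=wavelengths, values=values, **kw)


class TestExtraction:
    def test_mean_of_constant_plane(self):
        plane = np.full((3, 6, 6), 0.7)
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        s = extract_mean_spectrum(plane, mask, wavelengths=WL)
        assert np.allclose(s.values, 0.7)
        assert s.n_pixels == 4

    def test_single_pixel_mask(self, rng):
        plane = rng.uniform(size=(3, 5, 5))
        mask = np.zeros((5, 5), bool)
        mask[1, 3] = True
        s = extract_mean_spectrum(plane, mask, wavelengths=WL)
        assert np.allclose(s.values, plane[:, 1, 3])

    def test_background_invariance(self, rng):
        plane = rng.uniform(size=(3, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[3:5, 3:5] = True
        s1 = extract_mean_spectrum(plane, mask, wavelengths=WL)
        noisy_bg = plane.copy()
        noisy_bg[:, ~mask] = 1e6
        s2 = extract_mean_spectrum(noisy_bg, mask, wavelengths=WL)
        assert np.array_equal(s1.values, s2.values)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            ROIMask(np.zeros((4, 4), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            extract_mean_spectrum(np.ones((3, 4, 4)), np.ones((5, 5), bool))

    def test_class_separation_on_dop(self):
        """Granulocyte and lymphocyte masks give DOP spectra separated with a
        constant sign at every band."""
        from stokescope import PhantomSpec, generate_phantom

        scene = generate_phantom(
            PhantomSpec(n_cells_per_class={"granulocyte": 2, "lymphocyte": 2}, seed=21)
        )
        by_class = {}
        spectra = class_spectra(scene, NoiseModel.none(), seed=0, parameters=("DOP",))
        for s in spectra["DOP"]:
            by_class.setdefault(s.class_label, []).append(s.values)
        diff = np.mean(by_class["granulocyte"], axis=0) - np.mean(
            by_class["lymphocyte"], axis=0
        )
        assert (diff > 0).all()


class TestNormalization:
    def test_max(self):
        s = normalize_spectrum(_spectrum([2, 4, 8]), "max")
        assert np.allclose(s.values, [0.25, 0.5, 1.0])

    def test_area(self):
        s = normalize_spectrum(_spectrum([1, 1, 2]), "area")
        assert np.allclose(s.values, [0.25, 0.25, 0.5])

    def test_none_is_identity(self):
        s = _spectrum([1, 2, 3])
        assert normalize_spectrum(s, "none") is s

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_spectrum(_spectrum([0, 0, 0]), "max")


class TestTTest:
    def _groups(self, rng, delta=0.0, n=15, bands=5):
        a = [_spectrum(rng.normal(0.5, 0.05, bands)) for _ in range(n)]
        b = [_spectrum(rng.normal(0.5 + delta, 0.05, bands)) for _ in range(n)]
        return a, b

    def test_identical_groups_give_p_one(self):
        g = [_spectrum([0.1, 0.2, 0.3]), _spectrum([0.2, 0.3, 0.4])]
        pv = per_band_ttest(g, list(g))
        assert np.allclose(pv.p_values, 1.0)

    def test_symmetry_under_group_swap(self, rng):
        a, b = self._groups(rng, delta=0.03)
        assert np.allclose(
            per_band_ttest(a, b).p_values, per_band_ttest(b, a).p_values, atol=1e-15
        )

    def test_matches_scipy_welch_per_band(self, rng):
        a, b = self._groups(rng, delta=0.02)
        pv = per_band_ttest(a, b)
        for band in range(5):
            ref = stats.ttest_ind(
                [s.values[band] for s in a], [s.values[band] for s in b], equal_var=False
            )
            assert pv.p_values[band] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_bh_adjustment_attached_not_substituted(self, rng):
        a, b = self._groups(rng, delta=0.05)
        pv = per_band_ttest(a, b, adjust="bh")
        assert pv.adjusted is not None and pv.adjust_method == "bh"
        assert (pv.adjusted >= pv.p_values - 1e-15).all()

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            per_band_ttest([_spectrum([1, 2, 3])], [_spectrum([1, 2, 3])] * 3)

    def test_band_grid_mismatch_rejected(self):
        a = [_spectrum([1, 2, 3])] * 2
        b = [_spectrum([1, 2, 3], wavelengths=np.array([500.0, 510.0, 520.0]))] * 2
        with pytest.raises(ValueError, match="band grid"):
            per_band_ttest(a, b)

    def test_type_i_error_calibrated_under_null(self):
        """Same-distribution groups reject at ~alpha per band (1000 draws)."""
        rng = np.random.default_rng(7)
        rejections = []
        for _ in range(1000):
            a, b = self._groups(rng, delta=0.0, n=15, bands=1)
            rejections.append(per_band_ttest(a, b).p_values[0] < 0.05)
        rate = np.mean(rejections)
        assert 0.03 <= rate <= 0.07

    def test_power_on_separated_classes(self):
        """Effect of >= 2 pooled SD with n = 15 per group is detected at a
        majority of bands on DOP spectra."""
        res = two_class_study(seed=5)
        assert res.fraction_significant("DOP") > 0.5


class TestExtrema:
    def test_single_peak(self):
        ext = find_spectral_extrema(_spectrum([1, 3, 1], wavelengths=WL))
        assert ext == [(480.0, 3.0, "peak")]

    def test_monotone_spectrum_has_no_interior_extrema(self):
        assert find_spectral_extrema(_spectrum([1, 2, 3, 4])) == []

    def test_three_lobe_curve_recovers_designed_extrema(self):
        """Two maxima near 475/550 nm and the stain minimum near 525 nm."""
        wl = np.arange(470.0, 751.0, 10.0)
        curve = (
            np.exp(-0.5 * ((wl - 475) / 12) ** 2)
            + 0.9 * np.exp(-0.5 * ((wl - 552) / 14) ** 2)
            + 0.3 * np.exp(-0.5 * ((wl - 680) / 200) ** 2)
        )
        ext = find_spectral_extrema(_spectrum(curve, wavelengths=wl))
        kinds = {(w, k) for w, _, k in ext}
        assert (480.0, "peak") in kinds or (470.0, "peak") in kinds or (
            490.0,
            "peak",
        ) in kinds
        assert any(k == "trough" and 510 <= w <= 540 for w, _, k in ext)
        assert any(k == "peak" and 540 <= w <= 560 for w, _, k in ext)

    def test_flat_run_attributed_to_shorter_wavelength(self):
        ext = find_spectral_extrema(_spectrum([1, 2, 2, 1]))
        assert len(ext) == 1
        assert ext[0][0] == 480.0 and ext[0][2] == "peak"

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            find_spectral_extrema(_spectrum([1, 2], wavelengths=np.array([470.0, 480.0])))
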
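"""Pseudo-Voigt peak fitting, reference projection and albumin removal."""

import numpy as np
import pytest

from evspec.bands import PseudoVoigtBand, WavenumberAxis, pseudo_voigt, sum_bands
from evspec.deconvolution import (
    assign_peaks,
    deconvolute,
    fit_peak_sum,
    project_reference,
)
from evspec.spectra_io import packaged_band_table
from evspec.synthetic import albumin_reference_bands, default_group_templates

AXIS = WavenumberAxis.default()


class TestFitPeakSum:
    def test_exact_recovery_of_noiseless_band(self):
        truth = PseudoVoigtBand(1402.0, 24.0, 0.35, 1.8)
        spectrum = pseudo_voigt(AXIS.values, truth)
        init = [PseudoVoigtBand(1398.0, 30.0, 0.5, 1.0)]
        fit = fit_peak_sum(AXIS, spectrum, init)
        assert fit.converged
        band = fit.bands[0]
        assert band.center == pytest.approx(truth.center, rel=1e-3)
        assert band.fwhm == pytest.approx(truth.fwhm, rel=1e-3)
        assert band.eta == pytest.approx(truth.eta, abs=1e-3)
        assert band.amplitude == pytest.approx(truth.amplitude, rel=1e-3)

    def test_fit_never_worse_than_initialisation(self):
        rng = np.random.default_rng(0)
        truth = [PseudoVoigtBand(1100.0, 30.0, 0.5, 1.0),
                 PseudoVoigtBand(1600.0, 40.0, 0.5, 2.0)]
        y = sum_bands(AXIS, truth) + 0.02 * rng.normal(size=len(AXIS))
        init = [PseudoVoigtBand(1095.0, 25.0, 0.5, 0.8),
                PseudoVoigtBand(1605.0, 35.0, 0.5, 1.5)]
        fit = fit_peak_sum(AXIS, y, init)
        init_rms = float(np.sqrt(np.mean((sum_bands(AXIS, init) - y) ** 2)))
        assert fit.residual_rms <= init_rms + 1e-12

    def test_two_separated_bands_recovered_within_1cm(self):
        rng = np.random.default_rng(1)
        truth = [PseudoVoigtBand(1080.0, 26.0, 0.4, 1.2),
                 PseudoVoigtBand(1550.0, 34.0, 0.6, 2.2)]
        y = sum_bands(AXIS, truth) + 0.01 * rng.normal(size=len(AXIS))
        init = [PseudoVoigtBand(1075.0, 30.0, 0.5, 1.0),
                PseudoVoigtBand(1555.0, 30.0, 0.5, 2.0)]
        fit = fit_peak_sum(AXIS, y, init)
        centers = sorted(b.center for b in fit.bands)
        assert abs(centers[0] - 1080.0) < 1.0
        assert abs(centers[1] - 1550.0) < 1.0

    def test_empty_initialisation_rejected(self):
        with pytest.raises(ValueError):
            fit_peak_sum(AXIS, np.zeros(len(AXIS)), [])


@pytest.fixture(scope="module")
def albumin_fit():
    ref = sum_bands(AXIS, albumin_reference_bands())
    return fit_peak_sum(AXIS, ref, albumin_reference_bands())


class TestProjectReference:
    def test_self_projection_gives_unit_scales(self, albumin_fit):
        model = np.sum([pseudo_voigt(AXIS.values, b) for b in albumin_fit.bands], axis=0)
        scales, contribution = project_reference(AXIS, model, albumin_fit)
        np.testing.assert_allclose(scales, 1.0, atol=1e-6)
        np.testing.assert_allclose(contribution, model, atol=1e-8)

    def test_disjoint_sample_gives_zero_scales(self, albumin_fit):
        sample = pseudo_voigt(AXIS.values, PseudoVoigtBand(1850.0, 12.0, 0.5, 1.0))
        scales, contribution = project_reference(AXIS, sample, albumin_fit)
        assert np.all(scales >= 0)
        assert np.sum(np.abs(contribution)) < 0.05 * np.sum(np.abs(sample))

    def test_global_mode_single_multiplier(self, albumin_fit):
        model = np.sum([pseudo_voigt(AXIS.values, b) for b in albumin_fit.bands], axis=0)
        scales, _ = project_reference(AXIS, 0.4 * model, albumin_fit, scale_mode="global")
        assert len(set(np.round(scales, 12))) == 1
        assert scales[0] == pytest.approx(0.4, rel=1e-6)

    def test_mixture_fraction_recovered(self, albumin_fit):
        from evspec.deconvolution import default_ev_basis

        ev = sum_bands(AXIS, default_group_templates()["SEC"])
        albumin = sum_bands(AXIS, albumin_reference_bands())
        sample = ev + 0.4 * albumin
        _, contribution = project_reference(AXIS, sample, albumin_fit,
                                            ev_basis=default_ev_basis())
        frac = np.sum(np.abs(contribution)) / np.sum(np.abs(sample))
        true_frac = np.sum(np.abs(0.4 * albumin)) / np.sum(np.abs(sample))
        assert frac == pytest.approx(true_frac, abs=0.05)


class TestDeconvolute:
    def test_subtraction_identity_and_monotone_fraction(self):
        ev = sum_bands(AXIS, default_group_templates()["TEIR"])
        albumin = sum_bands(AXIS, albumin_reference_bands())
        fractions = []
        for f in (0.0, 0.2, 0.4, 0.6):
            sample = ev + f * albumin
            res = deconvolute(AXIS, sample, albumin, albumin_reference_bands())
            np.testing.assert_allclose(res.ev_estimate + res.contribution, sample,
                                       atol=1e-10)
            assert np.all(res.scale_amplitudes >= 0)
            fractions.append(res.fraction_removed)
        assert all(a <= b + 1e-9 for a, b in zip(fractions, fractions[1:]))
        assert 0 <= fractions[0] <= 1

    def test_albumin_free_sample_barely_touched(self):
        ev = sum_bands(AXIS, default_group_templates()["SEC"])
        albumin = sum_bands(AXIS, albumin_reference_bands())
        res = deconvolute(AXIS, ev, albumin, albumin_reference_bands())
        assert np.linalg.norm(res.contribution) < 0.1 * np.linalg.norm(ev)

    def test_pure_albumin_almost_fully_removed(self):
        albumin = sum_bands(AXIS, albumin_reference_bands())
        res = deconvolute(AXIS, albumin, albumin, albumin_reference_bands())
        assert np.linalg.norm(res.ev_estimate) < 0.1 * np.linalg.norm(albumin)

    def test_mixture_recovery_within_ten_percent(self):
        """EV + albumin mixture: recovered EV within 10% RMS of the truth."""
        rng = np.random.default_rng(3)
        ev = sum_bands(AXIS, default_group_templates()["UC"])
        albumin = sum_bands(AXIS, albumin_reference_bands())
        sample = ev + 0.4 * albumin + 0.01 * rng.normal(size=len(AXIS))
        res = deconvolute(AXIS, sample, albumin, albumin_reference_bands())
        rms_err = np.sqrt(np.mean((res.ev_estimate - ev) ** 2))
        assert rms_err < 0.1 * np.sqrt(np.mean(ev**2))


class TestAssignPeaks:
    def test_published_assignments_recovered(self):
        table = packaged_band_table()
        out = dict(assign_peaks([1743.0, 1084.0, 1900.0], table, tolerance=5.0))
        assert out[1743.0] == "CO stretching-phospholipid"
        assert out[1084.0].startswith("υPO2-")
        assert out[1900.0] == "unassigned"

    def test_range_rows_match_across_span(self):
        table = packaged_band_table()
        out = dict(assign_peaks([1560.0], table, tolerance=5.0))
        assert out[1560.0] == "Amide II - proteins"

    def test_tolerance_validated(self):
        with pytest.raises(ValueError):
            assign_peaks([1000.0], packaged_band_table(), tolerance=0.0)
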
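"""Reconstruction chain: apodization, transforms, phasing, integration, maps."""

import math

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from hpflux.exceptions import (
    EmptyInputError,
    InvalidParameterError,
    RangeError,
    ShapeError,
)
from hpflux.phantom import (
    AcqParams,
    CsiDataset,
    PhantomSpec,
    kspace_noise_sd_for_snr,
    make_phantom,
    synthesize_csi,
    synthesize_fid,
)
from hpflux.quantify import RoiMask, roi_ratios
from hpflux.recon import (
    PeakDef,
    Spectrum,
    apodize,
    default_peaks,
    estimate_zero_order_phase,
    fid_to_spectrum,
    integrate_peak_absorption,
    reconstruct_maps,
    spatial_recon,
    validate_peaks,
)
from conftest import spectrum_fwhm_hz


class TestApodize:
    def test_zero_lb_is_identity(self, rng):
        fid = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        np.testing.assert_array_equal(apodize(fid, 0.0, 2e-4), fid)

    def test_closed_form_on_constant_input(self):
        dwell = 2.0e-4
        out = apodize(np.ones(32, dtype=complex), 15.0, dwell)
        j = np.arange(32)
        np.testing.assert_allclose(out, np.exp(-np.pi * 15.0 * j * dwell))

    def test_fwhm_additivity(self):
        # 20 Hz line + 15 Hz broadening -> 35 +- 1 Hz
        params = AcqParams(n_samples=2048)
        fid = synthesize_fid({"pyr": 1.0}, 0.0, {"pyr": 20.0}, params)
        spec = fid_to_spectrum(
            apodize(fid, 15.0, params.dwell_s), params, zerofill_factor=4
        )
        assert spectrum_fwhm_hz(spec) == pytest.approx(35.0, abs=1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            apodize(np.array([]), 15.0, 2e-4)


class TestFidToSpectrum:
    def test_single_tone_lands_at_its_offset(self, acq_params):
        f_true = 500.0
        t = np.arange(acq_params.n_samples) * acq_params.dwell_s
        fid = np.exp(2j * np.pi * f_true * t)
        spec = fid_to_spectrum(fid, acq_params)
        f_axis = (spec.ppm - acq_params.carrier_ppm) * acq_params.f0_mhz
        f_peak = f_axis[np.argmax(np.abs(spec.values))]
        assert f_peak == pytest.approx(f_true, abs=acq_params.bw_hz / 1024)

    def test_zero_fill_factor_four_bins(self, acq_params):
        fid = np.ones(256, dtype=complex)
        assert len(fid_to_spectrum(fid, acq_params).values) == 1024

    def test_parseval_unitary_convention(self, acq_params, rng):
        fid = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        spec = np.fft.fft(fid, norm="ortho")
        assert abs(
            np.sum(np.abs(fid) ** 2) - np.sum(np.abs(spec) ** 2)
        ) / np.sum(np.abs(fid) ** 2) < 1e-12

    def test_area_convention_total_integral(self, acq_params):
        # sum(S) * df equals twice the half-sample-corrected fid(0)
        fid = synthesize_fid({"pyr": 1.0}, 0.0, {"pyr": 20.0}, acq_params)
        spec = fid_to_spectrum(fid, acq_params)
        total = np.sum(spec.values).real * spec.df_hz
        assert total == pytest.approx(1.0, rel=1e-9)


class TestSpatialRecon:
    def test_point_source_psf_is_dirichlet_kernel(self):
        # flat k-space -> the PSF of sinc (zero-fill) interpolation: a
        # single dominant peak with exact zeros at every other native
        # voxel center and Dirichlet sidelobes in between (first axial
        # sidelobe |sin(1.5 pi)| / (16 sin(6 pi/64)) ~ 21.5%)
        k = np.ones((16, 16, 1), dtype=complex)
        img = spatial_recon(k, 4)[:, :, 0]
        o = np.abs(img)
        peak = o[32, 32]
        assert np.unravel_index(np.argmax(o), o.shape) == (32, 32)
        # exact zeros at native-voxel offsets from the source
        for n in (4, 8, 12, 16):
            assert o[32, 32 + n] == pytest.approx(0.0, abs=1e-12 * peak)
        # axial sidelobes match the closed-form Dirichlet ratio
        for n in (6, 14):
            expected = abs(
                math.sin(math.pi * n / 4) / (16 * math.sin(math.pi * n / 64))
            )
            assert o[32, 32 + n] / peak == pytest.approx(expected, rel=1e-9)
        # no off-axis point exceeds the first axial sidelobe
        yy, xx = np.mgrid[0:64, 0:64]
        off_lobe = np.hypot(yy - 32.0, xx - 32.0) > 4
        assert o[off_lobe].max() / peak < 0.22

    def test_zerofill_one_native_grid(self):
        k = np.zeros((16, 16, 2), dtype=complex)
        assert spatial_recon(k, 1).shape == (16, 16, 2)

    def test_forward_inverse_voxel_location(self, acq_params):
        spec = PhantomSpec(seed=0)
        ph = make_phantom(spec)
        amp = {m: np.zeros_like(a) for m, a in ph.amplitudes.items()}
        amp["pyr"][10, 6] = 1.0
        ph_pt = type(ph)(
            labels=ph.labels, amplitudes=amp,
            phases_rad=np.zeros_like(ph.phases_rad),
            linewidths_hz=ph.linewidths_hz, spec=spec, truth_ratios={},
        )
        ds = synthesize_csi(ph_pt, acq_params, 0.0, 0)
        img = np.abs(spatial_recon(ds.kspace, 4)[:, :, 0])
        assert np.unravel_index(np.argmax(img), img.shape) == (40, 24)

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            spatial_recon(np.zeros((8, 16, 4), dtype=complex))


class TestZeroOrderPhase:
    def make_spectrum(self, phi_deg: float, params: AcqParams) -> Spectrum:
        fid = synthesize_fid(
            {"pyr": 1.0}, math.radians(phi_deg), {"pyr": 12.0}, params
        )
        return fid_to_spectrum(apodize(fid, 15.0, params.dwell_s), params)

    @pytest.mark.parametrize("phi_deg", [30.0, -120.0, 0.0, 179.0])
    def test_constructed_phase_recovered(self, phi_deg, acq_params):
        spec = self.make_spectrum(phi_deg, acq_params)
        est = estimate_zero_order_phase(spec, default_peaks()[0])
        err = math.degrees(
            math.atan2(
                math.sin(est.phi_rad - math.radians(phi_deg)),
                math.cos(est.phi_rad - math.radians(phi_deg)),
            )
        )
        assert abs(err) < 0.5
        assert not est.low_signal

    def test_estimate_maximizes_real_integral(self, acq_params):
        # the closed form must beat every candidate on a fine grid
        spec = self.make_spectrum(47.0, acq_params)
        peak = default_peaks()[0]
        mask = (spec.ppm >= peak.lo) & (spec.ppm <= peak.hi)
        z = np.sum(spec.values[mask])
        est = estimate_zero_order_phase(spec, peak)
        grid = np.radians(np.arange(-180, 180, 0.1))
        objective = (z * np.exp(-1j * grid)).real
        assert (z * np.exp(-1j * est.phi_rad)).real >= objective.max() - 1e-12

    @pytest.mark.parametrize("snr,bound_deg", [(10.0, 15.0), (50.0, 5.0)])
    def test_monte_carlo_error_scales_with_snr(self, snr, bound_deg, acq_params):
        """Phase error at spectral peak SNR 10 and 50: 95th percentile
        stays under bounds consistent with the ~1/SNR estimator noise."""
        fid0 = synthesize_fid({"pyr": 1.0}, 0.0, {"pyr": 12.0}, acq_params)
        j = np.arange(256)
        ap = np.exp(-np.pi * 15.0 * j * acq_params.dwell_s)
        ap_half = ap.copy()
        ap_half[0] *= 0.5
        s0 = fid_to_spectrum(apodize(fid0, 15.0, acq_params.dwell_s), acq_params)
        height = np.abs(s0.values).max()
        sigma_t = (height / snr) / (
            2 * acq_params.dwell_s * np.sqrt((ap_half**2).sum())
        )
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(100):
            phi = rng.uniform(-np.pi, np.pi)
            fid = fid0 * np.exp(1j * phi) + sigma_t * (
                rng.standard_normal(256) + 1j * rng.standard_normal(256)
            )
            spec = fid_to_spectrum(apodize(fid, 15.0, acq_params.dwell_s), acq_params)
            est = estimate_zero_order_phase(spec, default_peaks()[0])
            errs.append(
                abs(math.degrees(math.atan2(math.sin(est.phi_rad - phi),
                                            math.cos(est.phi_rad - phi))))
            )
        assert np.percentile(errs, 95) < bound_deg

    def test_low_signal_fallback(self, acq_params, rng):
        noise = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        spec = fid_to_spectrum(noise * 1e-3, acq_params)
        est = estimate_zero_order_phase(spec, default_peaks()[0])
        assert est.low_signal and est.phi_rad == 0.0


class TestIntegratePeak:
    def test_zero_spectrum_zero_area(self, acq_params):
        spec = fid_to_spectrum(np.zeros(256, dtype=complex), acq_params)
        res = integrate_peak_absorption(spec, default_peaks()[0], phase_rad=0.0)
        assert res.value == 0.0

    def test_unit_amplitude_lorentzian_window_fraction(self, acq_params):
        # analytic in-window fraction of a Lorentzian: (2/pi) atan(2w/FWHM);
        # FWHM 15 Hz with window halfwidth 4x FWHM captures 92.1%
        lw = 15.0
        halfwidth_ppm = 4 * lw / acq_params.f0_mhz
        peak = PeakDef("pyr", 171.0, halfwidth_ppm)
        fid = synthesize_fid({"pyr": 1.0}, 0.0, {"pyr": lw}, acq_params)
        spec = fid_to_spectrum(fid, acq_params)
        expected = (2 / math.pi) * math.atan(8.0)
        res = integrate_peak_absorption(spec, peak, phase_rad=0.0)
        assert res.value == pytest.approx(expected, abs=0.03)

    def test_equal_peaks_equal_integrals(self, acq_params):
        fid = synthesize_fid(
            {"lac": 0.7, "bic": 0.7}, 0.0, {"lac": 12.0, "bic": 12.0}, acq_params
        )
        spec = fid_to_spectrum(fid, acq_params)
        peaks = {p.name: p for p in default_peaks()}
        a = integrate_peak_absorption(spec, peaks["lac"], phase_rad=0.0).value
        b = integrate_peak_absorption(spec, peaks["bic"], phase_rad=0.0).value
        assert a == pytest.approx(b, rel=0.01)

    def test_negative_total_clamped_and_flagged(self, acq_params):
        fid = synthesize_fid({"pyr": 1.0}, math.pi, {"pyr": 12.0}, acq_params)
        spec = fid_to_spectrum(fid, acq_params)
        res = integrate_peak_absorption(spec, default_peaks()[0], phase_rad=0.0)
        assert res.value == 0.0 and res.clamped

    def test_window_outside_axis_rejected(self, acq_params):
        spec = fid_to_spectrum(np.ones(256, dtype=complex), acq_params)
        with pytest.raises(RangeError):
            integrate_peak_absorption(spec, PeakDef("x", 1000.0, 0.5))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(InvalidParameterError):
            validate_peaks([PeakDef("a", 170.0, 2.0), PeakDef("b", 172.0, 2.0)])


class TestReconstructMaps:
    def test_uniform_brain_low_cv_away_from_edges(self, acq_params):
        # uniform amplitudes across the brain: interior map CV < 5%
        from hpflux.phantom import TissueAmplitudes

        amps = {
            "pyr": TissueAmplitudes(1.0, 1.0, cv=0.0),
            "lac": TissueAmplitudes(0.5, 0.5, cv=0.0),
            "bic": TissueAmplitudes(0.08, 0.08, cv=0.0),
        }
        ph = make_phantom(PhantomSpec(amplitudes=amps, seed=0))
        ds = synthesize_csi(ph, acq_params, 0.0, 0)
        maps = reconstruct_maps(ds)
        interior = binary_erosion(ph.tissue_mask(1, 4) | ph.tissue_mask(2, 4),
                                  iterations=6)
        for name in ("pyr", "lac", "bic"):
            vals = maps[name][interior]
            assert vals.std() / vals.mean() < 0.05, name

    def test_linearity_of_full_chain(self, acq_params, default_phantom):
        ds = synthesize_csi(default_phantom, acq_params, 0.0, 0)
        scaled = CsiDataset(
            kspace=3.0 * ds.kspace, params=acq_params,
            animal_id=ds.animal_id, timepoint=ds.timepoint, seed=ds.seed,
        )
        m1 = reconstruct_maps(ds)
        m3 = reconstruct_maps(scaled)
        for name in ("pyr", "lac", "bic"):
            np.testing.assert_allclose(m3[name], 3.0 * m1[name], rtol=1e-9, atol=1e-12)
        mask = RoiMask(default_phantom.tissue_mask(2, 4), "tumor")
        assert roi_ratios(m3, mask).lac_bic == pytest.approx(
            roi_ratios(m1, mask).lac_bic, rel=1e-9
        )

    @pytest.mark.parametrize("phi_deg", [10.0, 45.0, 170.0])
    def test_global_phase_invariance(self, phi_deg, acq_params, default_phantom):
        ds = synthesize_csi(default_phantom, acq_params, 0.0, 0)
        rotated = CsiDataset(
            kspace=ds.kspace * np.exp(1j * math.radians(phi_deg)),
            params=acq_params, animal_id=ds.animal_id,
            timepoint=ds.timepoint, seed=ds.seed,
        )
        m0 = reconstruct_maps(ds)
        m1 = reconstruct_maps(rotated)
        brain = default_phantom.tissue_mask(1, 4) | default_phantom.tissue_mask(2, 4)
        for name in ("pyr", "lac", "bic"):
            a, b = m0[name][brain], m1[name][brain]
            assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 0.01, name

    def test_apodization_reduces_noise_at_small_bias(self, acq_params,
                                                     default_phantom):
        noise_sd = kspace_noise_sd_for_snr(acq_params, 20.0)
        ds0 = synthesize_csi(default_phantom, acq_params, 0.0, 11)
        dsn = synthesize_csi(default_phantom, acq_params, noise_sd, 11)
        brain = default_phantom.tissue_mask(1, 4) | default_phantom.tissue_mask(2, 4)
        res = {}
        for lb in (15.0, 0.0):
            truth = reconstruct_maps(ds0, lb_hz=lb).raw["pyr"]
            noisy = reconstruct_maps(dsn, lb_hz=lb).raw["pyr"]
            err = (noisy - truth)[brain]
            bias_ref = reconstruct_maps(ds0, lb_hz=15.0).raw["pyr"]
            res[lb] = err.std()
        assert res[15.0] < res[0.0]
        # equal bias: noiseless pyr ROI sums with and without broadening
        # agree within 3% after the common normalization
        s15 = reconstruct_maps(ds0, lb_hz=15.0).raw["pyr"][brain].sum()
        s0 = reconstruct_maps(ds0, lb_hz=0.0).raw["pyr"][brain].sum()
        cap15 = (2 / math.pi) * math.atan(2 * 0.5 * acq_params.f0_mhz / (12.0 + 15.0))
        cap0 = (2 / math.pi) * math.atan(2 * 0.5 * acq_params.f0_mhz / 12.0)
        assert s15 / cap15 == pytest.approx(s0 / cap0, rel=0.03)

    def test_resolution_contract(self, acq_params, default_phantom):
        ds = synthesize_csi(default_phantom, acq_params, 0.0, 0)
        maps = reconstruct_maps(ds)
        assert maps.shape == (64, 64)
        assert acq_params.fov_mm / maps.shape[0] == pytest.approx(1.0)

    def test_recovery_at_snr20_within_10pct(self, acq_params):
        """End-to-end Lac/Bic recovery: 20-seed mean within 10% of the
        phantom ratio-of-sums truth, tumor core ROI (2 mm erosion)."""
        noise_sd = kspace_noise_sd_for_snr(acq_params, 20.0)
        rel = []
        for seed in range(20):
            ph = make_phantom(PhantomSpec(seed=seed))
            ds = synthesize_csi(ph, acq_params, noise_sd, seed)
            maps = reconstruct_maps(ds)
            core = binary_erosion(ph.tissue_mask(2, 4), iterations=2)
            ratios = roi_ratios(maps, RoiMask(core, "tumor"))
            rel.append(ratios.lac_bic / ph.truth_ratios["lac_bic_tumor"])
        assert np.mean(rel) == pytest.approx(1.0, abs=0.10)

    def test_noiseless_recovery_small_bias(self, acq_params, default_phantom):
        ds = synthesize_csi(default_phantom, acq_params, 0.0, 1)
        maps = reconstruct_maps(ds)
        core = binary_erosion(default_phantom.tissue_mask(2, 4), iterations=2)
        rel = (
            roi_ratios(maps, RoiMask(core, "tumor")).lac_bic
            / default_phantom.truth_ratios["lac_bic_tumor"]
        )
        assert rel == pytest.approx(1.0, abs=0.10)
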
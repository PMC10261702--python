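import numpy as np
import pytest

from pasa import (
    AcquisitionConfig,
    PASignalRecord,
    build_papcs,
    calibrate,
    peak_to_peak,
    simulate_blackbody_reference,
    simulate_pa_signal,
    welch_psd,
)
from pasa.simulate import TissuePhantom

from conftest import brute_force_welch


def _rec(waveform, fs=2.5e8, wl=1210.0, **kw):
    return PASignalRecord(waveform=np.asarray(waveform, float), sampling_rate=fs,
                          wavelength=wl, **kw)


class TestPeakToPeak:
    def test_constant_waveform_is_zero(self):
        assert peak_to_peak(_rec(np.full(100, 3.7))) == 0.0

    def test_max_minus_min(self):
        assert peak_to_peak(_rec([-1.0, 0.0, 3.0])) == 4.0

    def test_unit_sine_close_to_two(self):
        t = np.arange(10000) / 2.5e8
        w = np.sin(2 * np.pi * 3e6 * t)  # >= 1 full period, densely sampled
        assert peak_to_peak(_rec(w)) == pytest.approx(2.0, abs=1e-3)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peak_to_peak(_rec([]))


class TestCalibrate:
    def test_divides_by_blackbody_peak_to_peak(self):
        tissue = _rec([0.0, 1.0, -1.0])
        bb = _rec([1.0, -1.0, 0.0])  # p2p = 2
        cal = calibrate(tissue, bb)
        np.testing.assert_allclose(cal.waveform, tissue.waveform / 2.0)
        assert cal.calibrated and not tissue.calibrated

    def test_wavelength_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            calibrate(_rec([0, 1], wl=1210.0), _rec([0, 1], wl=1220.0))

    def test_dead_reference_channel_rejected(self):
        with pytest.raises(ValueError, match="dead reference"):
            calibrate(_rec([0.0, 1.0]), _rec(np.zeros(10)))

    def test_calibrating_twice_rejected(self):
        cal = calibrate(_rec([0.0, 1.0]), _rec([0.0, 2.0]))
        with pytest.raises(ValueError, match="already calibrated"):
            calibrate(cal, _rec([0.0, 2.0]))

    def test_calibration_cancels_laser_energy(self, fast_config):
        """Doubling the pulse energy leaves the calibrated tissue waveform
        unchanged when the blackbody channel shares the energy draw."""
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        phantom = TissuePhantom(class_label="normal", lipid_fraction=0.3,
                                collagen_fraction=0.2, water_fraction=0.2,
                                absorber_radii=(0.3, 0.2),
                                absorber_positions=(10.0, 18.0), seed=0)
        out = []
        for energy in (0.2, 0.4):
            tis = simulate_pa_signal(phantom, 1210.0, cfg, energy=energy)
            bb = simulate_blackbody_reference(1210.0, cfg, energy=energy)
            out.append(calibrate(tis, bb).waveform)
        np.testing.assert_allclose(out[0], out[1], rtol=1e-10)

    def test_calibrated_p2p_flat_across_wavelengths_for_flat_absorber(
            self, fast_config):
        """A spectrally flat absorber yields < 1% coefficient of variation
        of calibrated peak-to-peak across wavelengths despite the
        wavelength-dependent, fluctuating pulse energy."""
        from pasa.chromophores import ChromophoreSpectrum, WAVELENGTH_GRID

        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        flat = {name: ChromophoreSpectrum(name, WAVELENGTH_GRID,
                                          np.ones_like(WAVELENGTH_GRID))
                for name in ("lipid", "collagen", "water")}
        phantom = TissuePhantom(class_label="normal", lipid_fraction=0.3,
                                collagen_fraction=0.2, water_fraction=0.2,
                                absorber_radii=(0.3,), absorber_positions=(12.0,),
                                seed=0)
        p2ps = []
        for i, wl in enumerate([1200.0, 1310.0, 1450.0, 1700.0]):
            energy = cfg.pulse_energy.sample(wl, np.random.default_rng(i))
            tis = simulate_pa_signal(phantom, wl, cfg, energy=energy, spectra=flat)
            bb = simulate_blackbody_reference(wl, cfg, energy=energy)
            p2ps.append(peak_to_peak(calibrate(tis, bb)))
        assert np.std(p2ps) / np.mean(p2ps) < 0.01


class TestWelchPSD:
    def test_zero_waveform_gives_zero_psd(self, fast_config):
        ps = welch_psd(_rec(np.zeros(6250)))
        assert np.all(ps.psd == 0.0)

    def test_frequency_resolution_is_inverse_window(self):
        ps = welch_psd(_rec(np.random.default_rng(0).normal(size=6250)))
        assert ps.frequencies[1] - ps.frequencies[0] == pytest.approx(200e3)

    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(62500) / 2.5e9
        rec = _rec(np.sin(2 * np.pi * 3e6 * t), fs=2.5e9)
        ps = welch_psd(rec)
        assert ps.frequencies[np.argmax(ps.psd)] == pytest.approx(3e6)

    def test_too_short_waveform_rejected_with_required_length(self):
        with pytest.raises(ValueError, match="1250"):
            welch_psd(_rec(np.zeros(1000)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=6250)
            ps = welch_psd(_rec(x))
            f_ref, p_ref = brute_force_welch(x, 2.5e8)
            np.testing.assert_allclose(ps.frequencies, f_ref)
            assert np.max(np.abs(ps.psd - p_ref)) <= 1e-10 * np.max(p_ref)

    def test_white_noise_band_power_matches_variance(self):
        """Parseval-type check: the integral of the PSD estimate recovers
        the noise variance (Monte-Carlo over 200 records)."""
        rng = np.random.default_rng(7)
        sigma = 0.8
        integrals = []
        for _ in range(200):
            x = sigma * rng.standard_normal(6250)
            ps = welch_psd(_rec(x))
            integrals.append(np.trapezoid(ps.psd, ps.frequencies))
        assert np.mean(integrals) == pytest.approx(sigma ** 2, rel=0.15)

    def test_time_gate_restricts_the_analysis_window(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(size=3125), 10 * rng.normal(size=3125)])
        full = welch_psd(_rec(x))
        early = welch_psd(_rec(x), time_gate=(0.0, 3125 / 2.5e8))
        assert np.trapezoid(early.psd, early.frequencies) < \
            np.trapezoid(full.psd, full.frequencies)


class TestBuildPAPCS:
    def _calibrated(self, wl, pos, waveform, sid="S1"):
        r = _rec(waveform, wl=wl, sample_id=sid, position=pos)
        r.calibrated = True
        return r

    def test_shape_and_wavelength_ordering(self):
        rng = np.random.default_rng(0)
        recs = [self._calibrated(wl, pos, rng.normal(size=6250))
                for wl in (1220.0, 1200.0, 1210.0) for pos in (0, 1)]
        papcs = build_papcs(recs)
        assert papcs.power.shape[0] == 3
        np.testing.assert_array_equal(papcs.wavelengths, [1200.0, 1210.0, 1220.0])
        assert np.all(papcs.power >= 0)

    def test_identical_positions_average_to_single_psd(self):
        x = np.random.default_rng(3).normal(size=6250)
        recs = [self._calibrated(1210.0, p, x) for p in (0, 1)]
        papcs = build_papcs(recs)
        single = welch_psd(recs[0])
        np.testing.assert_allclose(papcs.power[0], single.psd)

    def test_record_order_is_irrelevant(self):
        rng = np.random.default_rng(5)
        recs = [self._calibrated(wl, pos, rng.normal(size=6250))
                for wl in (1200.0, 1210.0) for pos in (0, 1)]
        a = build_papcs(recs)
        b = build_papcs(recs[::-1])
        np.testing.assert_array_equal(a.power, b.power)

    def test_missing_wavelength_rejected_listing_gaps(self):
        recs = [self._calibrated(1200.0, 0, np.random.default_rng(0).normal(size=6250))]
        with pytest.raises(ValueError, match="1210"):
            build_papcs(recs, wavelengths=[1200.0, 1210.0])

    def test_uncalibrated_records_rejected(self):
        rec = _rec(np.zeros(6250))
        with pytest.raises(ValueError, match="calibrated"):
            build_papcs([rec])
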
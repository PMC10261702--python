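import numpy as np
import pytest

from pasa import (
    AcquisitionConfig,
    EnergyProfile,
    TissuePhantom,
    generate_phantom,
    peak_to_peak,
    simulate_blackbody_reference,
    simulate_dataset,
    simulate_pa_signal,
    welch_psd,
)
from pasa.features import apsd
from pasa.simulate import CLASS_FRACTIONS, CLASS_LABELS


def _phantom(lipid=0.0, collagen=0.0, water=0.0, radii=(0.3,), dists=(15.0,), seed=0):
    return TissuePhantom(class_label="normal", lipid_fraction=lipid,
                         collagen_fraction=collagen, water_fraction=water,
                         absorber_radii=radii, absorber_positions=dists, seed=seed)


class TestGeneratePhantom:
    def test_deterministic_under_fixed_seed(self):
        assert generate_phantom("normal", seed=1) == generate_phantom("normal", seed=1)

    def test_unknown_class_rejected_naming_valid_labels(self):
        with pytest.raises(ValueError, match="normal"):
            generate_phantom("melanoma", seed=0)

    @pytest.mark.parametrize("label", CLASS_LABELS)
    def test_fractions_truncated_and_bounded(self, label):
        for seed in range(200):
            p = generate_phantom(label, seed=seed)
            fr = (p.lipid_fraction, p.collagen_fraction, p.water_fraction)
            assert all(f >= 0 for f in fr) and sum(fr) <= 1 + 1e-12

    def test_monte_carlo_class_ordering_of_mean_fractions(self):
        means = {}
        for label in CLASS_LABELS:
            ps = [generate_phantom(label, seed=s) for s in range(1000)]
            means[label] = (np.mean([p.lipid_fraction for p in ps]),
                            np.mean([p.collagen_fraction for p in ps]))
        for i in (0, 1):  # lipid then collagen
            assert means["normal"][i] > means["SCC"][i] > means["BCC"][i]

    def test_radii_give_characteristic_frequency_in_band(self):
        for seed in range(50):
            p = generate_phantom("SCC", seed=seed)
            f_char = 1500.0 / (2 * np.asarray(p.absorber_radii) * 1e-3)
            assert np.all((f_char >= 1e6) & (f_char <= 8e6))


class TestSimulatePASignal:
    def test_zero_fractions_and_no_noise_gives_zero_waveform(self, fast_config):
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        rec = simulate_pa_signal(_phantom(), 1210.0, cfg, seed=3)
        assert np.all(rec.waveform == 0.0)

    def test_single_absorber_peak_frequency_near_c_over_2a(self):
        # a = 0.375 mm, c = 1500 m/s -> c/(2a) = 2 MHz; peak within +/-25%
        cfg = AcquisitionConfig(noise_sigma=0.0)
        rec = simulate_pa_signal(_phantom(lipid=0.3, radii=(0.375,)), 1210.0,
                                 cfg, seed=0)
        ps = welch_psd(rec)
        f_peak = ps.frequencies[np.argmax(ps.psd)]
        assert 1.5e6 <= f_peak <= 2.5e6

    def test_amplitude_linear_in_lipid_fraction(self, fast_config):
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        p1 = _phantom(lipid=0.2)
        p2 = _phantom(lipid=0.4)
        r1 = simulate_pa_signal(p1, 1210.0, cfg, seed=1)
        r2 = simulate_pa_signal(p2, 1210.0, cfg, seed=1)
        assert peak_to_peak(r2) == pytest.approx(2 * peak_to_peak(r1), rel=1e-12)

    def test_off_grid_wavelength_rejected(self, fast_config):
        with pytest.raises(ValueError, match="not on the acquisition grid"):
            simulate_pa_signal(_phantom(lipid=0.2), 1205.0, fast_config)

    def test_empty_absorber_list_warns_and_flags_pure_noise(self, fast_config):
        phantom = _phantom(lipid=0.2, radii=(), dists=())
        with pytest.warns(UserWarning, match="no absorbers"):
            rec = simulate_pa_signal(phantom, 1210.0, fast_config, seed=4)
        assert rec.pure_noise

    def test_deterministic_under_fixed_seed(self, fast_config):
        p = _phantom(lipid=0.2, water=0.3)
        r1 = simulate_pa_signal(p, 1300.0, fast_config, seed=9)
        r2 = simulate_pa_signal(p, 1300.0, fast_config, seed=9)
        np.testing.assert_array_equal(r1.waveform, r2.waveform)

    def test_positions_share_composition_but_differ_in_geometry(self, fast_config):
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        p = _phantom(lipid=0.2, radii=(0.3, 0.2), dists=(10.0, 20.0))
        r0 = simulate_pa_signal(p, 1210.0, cfg, position=0, seed=1)
        r1 = simulate_pa_signal(p, 1210.0, cfg, position=1, seed=1)
        assert not np.array_equal(r0.waveform, r1.waveform)
        assert peak_to_peak(r1) > 0


class TestBlackbodyReference:
    def test_constant_energy_gives_identical_p2p_at_all_wavelengths(self, fast_config):
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        p2ps = [peak_to_peak(simulate_blackbody_reference(wl, cfg, energy=0.3))
                for wl in (1200.0, 1450.0, 1700.0)]
        assert np.ptp(p2ps) < 1e-12 * p2ps[0]

    def test_p2p_proportional_to_energy(self, fast_config):
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0)
        a = peak_to_peak(simulate_blackbody_reference(1210.0, cfg, energy=0.2))
        b = peak_to_peak(simulate_blackbody_reference(1210.0, cfg, energy=0.4))
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_fluctuation_std_recovered_by_monte_carlo(self, fast_config):
        cfg = AcquisitionConfig(sampling_rate=fast_config.sampling_rate,
                                record_length=fast_config.record_length,
                                noise_sigma=0.0,
                                pulse_energy=EnergyProfile(fluctuation_std=0.05))
        p2ps = np.array([peak_to_peak(simulate_blackbody_reference(1210.0, cfg,
                                                                   seed=s))
                         for s in range(500)])
        assert abs(np.std(p2ps) / np.mean(p2ps) - 0.05) < 0.01


class TestSimulateDataset:
    def test_study_size_counts(self, fast_config):
        ss = simulate_dataset({"normal": 2, "SCC": 3, "BCC": 2}, fast_config, seed=0)
        assert len(ss.sample_ids) == 7
        assert len(ss.signals) == 7 * 52 * 2  # 51 scan wavelengths + 690 nm ref
        assert len(ss.blackbody) == 52
        ss.validate()

    def test_same_seed_gives_bit_identical_waveforms(self, fast_config):
        s1 = simulate_dataset({"normal": 1, "SCC": 1, "BCC": 1}, fast_config, seed=5)
        s2 = simulate_dataset({"normal": 1, "SCC": 1, "BCC": 1}, fast_config, seed=5)
        for key in s1.signals:
            np.testing.assert_array_equal(s1.signals[key].waveform,
                                          s2.signals[key].waveform)

    def test_shuffled_class_order_leaves_per_class_statistics_unchanged(
            self, fast_config):
        s1 = simulate_dataset({"normal": 2, "SCC": 2, "BCC": 2}, fast_config, seed=3)
        s2 = simulate_dataset({"BCC": 2, "normal": 2, "SCC": 2}, fast_config, seed=3)
        for label in CLASS_LABELS:
            m1 = np.mean([p.lipid_fraction for p in s1.phantoms
                          if p.class_label == label])
            m2 = np.mean([p.lipid_fraction for p in s2.phantoms
                          if p.class_label == label])
            assert m1 == m2

    def test_rejects_unknown_class_and_zero_counts(self, fast_config):
        with pytest.raises(ValueError, match="unknown class"):
            simulate_dataset({"melanoma": 2}, fast_config)
        with pytest.raises(ValueError, match="at least one"):
            simulate_dataset({"normal": 0}, fast_config)


def test_spectral_placement_in_analysis_band():
    """Noise-free default-geometry records put >= 80% of their spectral
    energy inside the 1-8 MHz analysis band."""
    cfg = AcquisitionConfig(noise_sigma=0.0)
    for seed in range(5):
        p = generate_phantom("normal", seed=seed)
        rec = simulate_pa_signal(p, 1210.0, cfg, seed=seed)
        ps = welch_psd(rec)
        band = apsd(ps).apsd
        total = np.trapezoid(ps.psd, ps.frequencies)
        assert band / total >= 0.80
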
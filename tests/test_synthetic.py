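"""Ground-truth generator: pulse shape, record assembly, noise model,
decimation, and dataset reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from eogdiff.detection import DetectionConfig
from eogdiff.synthetic import (
    DatasetConfig,
    NoiseConfig,
    SaccadeParameters,
    SyntheticRecord,
    add_noise,
    build_record,
    decimate_record,
    default_noise,
    generate_dataset,
    saccade_velocity_pulse,
    sample_parameters,
)


class TestParameters:
    def test_healthy_defaults_without_jitter(self):
        rng = np.random.default_rng(0)
        p = sample_parameters("healthy", 20, rng, jitter=False)
        assert p.duration == pytest.approx(0.025 + 0.0025 * 20)
        assert p.peak_velocity == pytest.approx(2 * 20 / 0.075, rel=1e-12)

    def test_sca2_slower_than_healthy(self):
        rng = np.random.default_rng(0)
        h = sample_parameters("healthy", 20, rng, jitter=False)
        s = sample_parameters("sca2", 20, rng, jitter=False)
        assert s.duration == pytest.approx(0.060 + 0.006 * 20)
        assert s.peak_velocity == pytest.approx(2 * 20 / 0.180, rel=1e-12)
        assert s.peak_velocity < h.peak_velocity

    def test_sca2_latencies_longer_and_truncated(self):
        rng = np.random.default_rng(1)
        lat_h = [sample_parameters("healthy", 30, rng).latency for _ in range(400)]
        lat_s = [sample_parameters("sca2", 30, rng).latency for _ in range(400)]
        assert np.mean(lat_s) > np.mean(lat_h)
        assert min(lat_h + lat_s) >= 0.10

    def test_invalid_class_and_angle_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="class"):
            sample_parameters("unknown", 20, rng)
        with pytest.raises(ValueError, match="angle"):
            sample_parameters("healthy", 45, rng)

    def test_physical_invariants_enforced(self):
        with pytest.raises(ValueError, match="integrate"):
            SaccadeParameters(
                amplitude=20, duration=0.05, peak_velocity=100, latency=0.2
            )


class TestPulse:
    def _params(self, a=20.0, d=0.075):
        return SaccadeParameters(
            amplitude=a, duration=d, peak_velocity=2 * abs(a) / d, latency=0.2
        )

    def test_integrates_to_amplitude(self):
        pulse = saccade_velocity_pulse(self._params(), fs=1000.0)
        area = np.trapezoid(pulse, dx=1e-3)
        assert area == pytest.approx(20.0, abs=0.1)

    def test_peak_on_grid_equals_vp(self):
        # D = 0.075 at 1000 Hz: t = D/2 falls on a sample, but the two
        # samples flanking an off-grid apex are within sin^2 curvature
        pulse = saccade_velocity_pulse(self._params(), fs=1000.0)
        vp = 2 * 20 / 0.075
        assert np.abs(pulse).max() == pytest.approx(vp, rel=1e-3)

    def test_endpoints_zero_and_sign_follows_amplitude(self):
        pulse = saccade_velocity_pulse(self._params(a=-30.0), fs=1000.0)
        assert pulse[0] == 0.0
        assert pulse[-1] == pytest.approx(0.0, abs=1e-9)
        assert pulse.min() < 0 and pulse.max() <= 0.0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            saccade_velocity_pulse(self._params(d=0.01), fs=200.0)


@pytest.fixture(scope="module")
def record():
    return build_record(20, "healthy", 20, fs=1000.0, seed=42)


class TestRecord:
    def test_event_and_transition_counts(self, record):
        assert len(record.exact_events) == 20
        assert len(record.stimulus_transitions) >= 20

    def test_each_event_preceded_by_a_transition(self, record):
        for ev in record.exact_events:
            assert np.any(record.stimulus_transitions <= ev.onset_time(record.fs))

    def test_position_telescopes_to_amplitude_sum(self, record):
        total = sum(p.amplitude for p in record.parameters)
        drift = record.position[-1] - record.position[0]
        assert drift == pytest.approx(total, abs=0.5)

    def test_evp_compactly_supported(self, record):
        mask = np.ones(record.n_samples, bool)
        for p in record.parameters:
            i0 = int(np.round(p.onset_time * record.fs))
            i1 = i0 + int(np.floor(p.duration * record.fs)) + 1
            mask[i0:i1] = False
        np.testing.assert_array_equal(record.evp[mask], 0.0)

    def test_alternates_between_target_levels(self, record):
        # position starts at -angle/2 and steps by +-angle each saccade
        assert record.position[0] == pytest.approx(-10.0)
        signs = [np.sign(p.amplitude) for p in record.parameters]
        assert signs == [(-1) ** i for i in range(20)]


class TestNoise:
    def test_zero_amplitudes_are_a_noop(self):
        rec = build_record(3, "healthy", 20, fs=1000.0, seed=1)
        silent = NoiseConfig(mains_amplitude=0, white_sigma=0, colored_sigma=0)
        noisy = add_noise(rec, silent, np.random.default_rng(0))
        np.testing.assert_array_equal(noisy.position, rec.position)

    def test_ground_truth_untouched(self):
        rec = build_record(3, "sca2", 30, fs=1000.0, seed=2)
        noisy = add_noise(rec, default_noise("sca2"), np.random.default_rng(0))
        np.testing.assert_array_equal(noisy.evp, rec.evp)
        assert noisy.exact_events == rec.exact_events
        assert noisy.position is not rec.position

    def test_white_noise_sigma_calibrated(self):
        rec = build_record(4, "healthy", 20, fs=1000.0, seed=3)
        cfg = NoiseConfig(mains_amplitude=0, white_sigma=0.1, colored_sigma=0)
        noisy = add_noise(rec, cfg, np.random.default_rng(4))
        sd = (noisy.position - rec.position).std()
        assert sd == pytest.approx(0.1, rel=0.10)

    def test_mains_power_concentrated_at_60hz(self):
        rec = build_record(4, "healthy", 20, fs=1000.0, seed=5)
        cfg = NoiseConfig(mains_amplitude=0.3, white_sigma=0, colored_sigma=0)
        noisy = add_noise(rec, cfg, np.random.default_rng(6))
        diff = noisy.position - rec.position
        f, pxx = signal.periodogram(diff, fs=1000.0)
        band = (f >= 59.0) & (f <= 61.0)
        assert pxx[band].sum() / pxx.sum() >= 0.99

    def test_colored_noise_sigma_and_band(self):
        rec = build_record(4, "sca2", 20, fs=1000.0, seed=7)
        cfg = NoiseConfig(mains_amplitude=0, white_sigma=0, colored_sigma=0.1)
        noisy = add_noise(rec, cfg, np.random.default_rng(8))
        diff = noisy.position - rec.position
        assert diff.std() == pytest.approx(0.1, rel=1e-6)  # rescaled exactly
        f, pxx = signal.periodogram(diff, fs=1000.0)
        inband = pxx[(f >= 2.0) & (f <= 9.0)].sum()
        assert inband / pxx.sum() >= 0.95


class TestDecimation:
    def test_length_and_rate(self):
        rec = build_record(5, "healthy", 20, fs=1000.0, seed=9)
        dec = decimate_record(rec)
        assert dec.fs == 200.0
        assert dec.n_samples == int(np.ceil(rec.n_samples / 5))
        assert dec.position.shape == dec.evp.shape

    def test_dc_preserved(self):
        rec = SyntheticRecord(
            fs=1000.0,
            position=np.full(10000, 7.0),
            evp=np.zeros(10000),
            stimulus_transitions=np.array([1.0]),
            exact_events=(),
            subject_class="healthy",
            stimulation_angle=20,
        )
        dec = decimate_record(rec)
        # the 8th-order Chebyshev-I antialiasing filter has its 0.05 dB
        # passband ripple at DC (even order), applied twice (zero phase):
        # DC gain is 10**(-0.1/20) ~= 0.9886, identical for position and
        # EVP, so the benchmark comparisons are unaffected
        np.testing.assert_allclose(dec.position, 7.0 * 10 ** (-0.1 / 20), rtol=1e-6)

    def test_passband_sinusoid_amplitude_preserved(self):
        t = np.arange(10000) / 1000.0
        rec = SyntheticRecord(
            fs=1000.0,
            position=np.sin(2 * np.pi * 3.0 * t),
            evp=np.zeros(10000),
            stimulus_transitions=np.array([1.0]),
            exact_events=(),
            subject_class="healthy",
            stimulation_angle=20,
        )
        dec = decimate_record(rec)
        inner = dec.position[100:-100]
        assert np.abs(inner).max() == pytest.approx(1.0, rel=0.02)

    def test_non_integer_factor_rejected(self):
        rec = build_record(2, "healthy", 20, fs=1000.0, seed=10)
        with pytest.raises(ValueError, match="integer multiple"):
            decimate_record(rec, target_fs=300.0)

    def test_events_survive_decimation(self):
        rec = build_record(10, "sca2", 60, fs=1000.0, seed=11)
        dec = decimate_record(rec)
        assert len(dec.exact_events) == 10
        # onset times agree with the 1000 Hz annotations to ~1 coarse sample
        for e1000, e200 in zip(rec.exact_events, dec.exact_events):
            assert abs(e1000.onset_time(rec.fs) - e200.onset_time(dec.fs)) <= 1.5 / 200


class TestDataset:
    def test_grid_counts(self):
        man = generate_dataset(DatasetConfig(records_per_cell=2), master_seed=0)
        assert len(man) == 12
        assert set(man.counts().values()) == {2}
        assert man.total_exact_saccades() == 240

    def test_determinism(self):
        cfg = DatasetConfig(records_per_cell=1, angles=(20,))
        a = generate_dataset(cfg, master_seed=5)
        b = generate_dataset(cfg, master_seed=5)
        c = generate_dataset(cfg, master_seed=6)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.position, rb.position)
        assert not np.array_equal(a.records[0].position, c.records[0].position)

    def test_sca2_peak_velocities_below_healthy_at_every_angle(self):
        man = generate_dataset(DatasetConfig(records_per_cell=1), master_seed=2)
        peak = {}
        for entry, rec in zip(man.entries, man.records):
            vals = [
                np.abs(rec.evp[ev.onset_index : ev.offset_index + 1]).max()
                for ev in rec.exact_events
            ]
            peak.setdefault((entry.subject_class, entry.angle), []).extend(vals)
        for angle in (20, 30, 60):
            assert np.mean(peak[("sca2", angle)]) < np.mean(peak[("healthy", angle)])

    def test_noiseless_flag_silences_all_noise(self):
        cfg = DatasetConfig(records_per_cell=1, angles=(20,), noiseless=True)
        for cls in ("healthy", "sca2"):
            n = cfg.noise_for(cls)
            assert (n.mains_amplitude, n.white_sigma, n.colored_sigma) == (0, 0, 0)
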
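"""Speckle simulator: statistics, shift exactness, signal model, datasets."""

import numpy as np
import pytest
from scipy import stats

import specklenose as sn
from specklenose.simulate import (
    ConfigurationError,
    DatasetDesign,
    RecordingProtocol,
    SensorConfig,
    _crop_center,
    generate_dataset,
    make_phase_screen,
    render_frame,
    shift_intensity,
    speckle_intensity,
    tilt_signal,
    video_seed,
)

FLOAT_SENSOR = SensorConfig(bit_depth=None)


class TestPhaseScreen:
    def test_same_seed_reproduces(self):
        a = make_phase_screen(64, seed=5)
        b = make_phase_screen(64, seed=5)
        np.testing.assert_array_equal(a.phases, b.phases)

    def test_different_seeds_differ_almost_everywhere(self):
        a = make_phase_screen(64, seed=5)
        b = make_phase_screen(64, seed=6)
        assert (a.phases != b.phases).mean() > 0.99

    def test_phases_uniform_on_two_pi(self):
        screen = make_phase_screen(512, seed=0)
        ks = stats.kstest(screen.phases.ravel() / (2 * np.pi), "uniform")
        assert ks.pvalue > 0.01

    def test_guard_band_enforced(self):
        with pytest.raises(ConfigurationError):
            make_phase_screen(300, seed=0, frame_size=224)


class TestRenderFrame:
    def test_deterministic_at_zero_noise(self):
        screen = make_phase_screen(256, seed=1)
        a = render_frame(screen, frame_size=112, sensor=FLOAT_SENSOR)
        b = render_frame(screen, frame_size=112, sensor=FLOAT_SENSOR)
        np.testing.assert_array_equal(a, b)

    def test_fully_developed_contrast(self):
        screen = make_phase_screen(512, seed=2)
        frame = render_frame(screen, frame_size=224, sensor=FLOAT_SENSOR)
        contrast = frame.std() / frame.mean()
        assert contrast == pytest.approx(1.0, abs=0.1)

    def test_negative_exponential_intensity(self):
        screen = make_phase_screen(512, seed=3)
        frame = render_frame(screen, frame_size=224, sensor=FLOAT_SENSOR)
        ks = stats.kstest(frame.ravel() / frame.mean(), "expon")
        assert ks.pvalue > 0.01

    def test_integer_shift_equals_rolled_pattern(self):
        screen = make_phase_screen(256, seed=4)
        base = speckle_intensity(screen)
        shifted = render_frame(screen, shift=(5.0, 0.0), frame_size=112, sensor=FLOAT_SENSOR)
        rolled = _crop_center(np.roll(base, 5, axis=1), 112) / base.mean()
        # quantization-free path: agreement far below 1 DN equivalent
        assert np.abs(shifted - rolled).max() < 1e-9

    def test_quantized_shift_within_one_dn(self):
        screen = make_phase_screen(256, seed=4)
        rng = np.random.default_rng(0)
        sensor = SensorConfig(read_noise_dn=0.0)
        a = render_frame(screen, shift=(5.0, 0.0), frame_size=112, sensor=sensor, rng=rng)
        base = speckle_intensity(screen)
        rolled = np.clip(
            np.rint(_crop_center(np.roll(base, 5, axis=1), 112) * (sensor.mean_fill * 255 / base.mean())),
            0, 255,
        )
        assert np.abs(a.astype(int) - rolled.astype(int)).max() <= 1

    def test_subpixel_shift_property_is_consistent(self):
        screen = make_phase_screen(256, seed=5)
        base = speckle_intensity(screen)
        once = shift_intensity(shift_intensity(base, (0.3, -0.4)), (0.7, 0.4))
        direct = shift_intensity(base, (1.0, 0.0))
        assert np.abs(once - direct).max() / base.mean() < 1e-9

    def test_shift_outside_guard_band_rejected(self):
        screen = make_phase_screen(256, seed=6)
        with pytest.raises(ValueError):
            render_frame(screen, shift=(100.0, 0.0), frame_size=112)


class TestTiltSignal:
    def null_params(self, **overrides):
        base = dict(
            smell="alcohol", region="amygdala",
            component_freqs=(10.0,), component_amps=(0.0,),
            pulse_amp=0.0, noise_floor=0.0,
        )
        base.update(overrides)
        return sn.ClassSignalParams(**base)

    def test_null_signal_is_zero(self):
        trace = tilt_signal(self.null_params(), 1.0, 200.0, np.random.default_rng(0))
        assert np.all(trace.theta_x == 0) and np.all(trace.theta_y == 0)
        assert len(trace) == 200

    def test_single_tone_peaks_at_its_frequency(self):
        params = self.null_params(component_amps=(1.0,))
        trace = tilt_signal(params, 2.0, 200.0, np.random.default_rng(1))
        mag = np.abs(np.fft.rfft(trace.theta_x - trace.theta_x.mean()))
        freqs = np.fft.rfftfreq(len(trace), 1 / 200.0)
        assert abs(freqs[np.argmax(mag)] - 10.0) <= freqs[1]

    def test_amplitude_linearity(self):
        p1 = self.null_params(component_amps=(1.0,))
        p2 = self.null_params(component_amps=(2.0,))
        t1 = tilt_signal(p1, 1.0, 200.0, np.random.default_rng(3))
        t2 = tilt_signal(p2, 1.0, 200.0, np.random.default_rng(3))
        r1 = np.sqrt((t1.theta_x**2).mean())
        r2 = np.sqrt((t2.theta_x**2).mean())
        assert r2 == pytest.approx(2.0 * r1, rel=1e-9)

    def test_distance_gain_attenuates(self):
        params = self.null_params(component_amps=(1.0,))
        near = tilt_signal(params, 1.0, 200.0, np.random.default_rng(4), distance_m=0.1)
        far = tilt_signal(params, 1.0, 200.0, np.random.default_rng(4), distance_m=1.0)
        assert np.sqrt((far.theta_x**2).mean()) == pytest.approx(
            0.4 * np.sqrt((near.theta_x**2).mean()), rel=1e-9
        )

    def test_aliasing_component_rejected(self):
        with pytest.raises(ConfigurationError):
            tilt_signal(
                self.null_params(component_freqs=(120.0,), component_amps=(1.0,)),
                1.0, 200.0, np.random.default_rng(0),
            )


class TestRecordingsAndDatasets:
    def test_default_protocol_frame_count(self):
        # 5 s x 200 FPS x 4 repeats
        assert RecordingProtocol().frames_per_video == 4000

    def test_recording_deterministic_for_fixed_seed(self):
        params = sn.default_signal_params("menthol", "hippocampus")
        proto = RecordingProtocol(duration_s=0.2, repeats=2, frame_size=64, field_size=128)
        a = sn.simulate_recording(params, proto, rng=9)
        b = sn.simulate_recording(params, proto, rng=9)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert a.n_frames == 80

    def test_tracker_recovers_injected_tilt(self, tone_video):
        """Round trip: tracking the simulated video recovers theta up to
        the tilt-to-shift gain with small residual."""
        trace = sn.track(tone_video)
        g = 0.5  # protocol default gain px/urad
        params = sn.ClassSignalParams(
            smell="alcohol", region="amygdala",
            component_freqs=(10.0,), component_amps=(1.0,),
            pulse_amp=0.0, noise_floor=0.02,
        )
        rng = np.random.default_rng(123)
        rng.integers(0, 2**31)  # screen seed drawn first inside the simulator
        theta = sn.tilt_signal(params, 1.0, 200.0, rng)
        rmse = np.sqrt(np.mean((trace.pos_x - (g * theta.theta_x - g * theta.theta_x[0])) ** 2))
        assert rmse < 0.1

    def test_dataset_size_and_manifest(self):
        design = DatasetDesign(
            protocol=RecordingProtocol(duration_s=0.1, repeats=1, frame_size=64, field_size=128)
        )
        assert design.n_videos == 4 * 3 * 5 * 2 * 3 == 360
        small = DatasetDesign(
            dogs=("a", "b"), regions=("amygdala",), smells=("garlic", "menthol"),
            distances_m=(0.1,), videos_per_cell=2,
            protocol=RecordingProtocol(duration_s=0.1, repeats=1, frame_size=64, field_size=128),
        )
        videos, manifest = generate_dataset(small, master_seed=11)
        assert len(manifest) == small.n_videos == 8
        assert manifest["video_tag"].is_unique
        _, manifest2 = generate_dataset(small, master_seed=11)
        assert manifest.equals(manifest2)
        videos2, _ = generate_dataset(small, master_seed=11)
        np.testing.assert_array_equal(videos[3].frames, videos2[3].frames)

    def test_empty_design_yields_empty_manifest(self):
        design = DatasetDesign(
            dogs=("a",), regions=("amygdala",), smells=(), distances_m=(0.1,),
        )
        videos, manifest = generate_dataset(design, master_seed=0)
        assert videos == [] and len(manifest) == 0

    def test_video_seed_is_counter_based(self):
        seeds = {video_seed(3, i) for i in range(100)}
        assert len(seeds) == 100
        assert video_seed(3, 7) == video_seed(3, 7)
        assert video_seed(3, 7) != video_seed(4, 7)


def test_shift_linear_in_tilt():
    """Recovered shift vs injected tilt amplitude: slope = gain within 2%,
    intercept below 0.05 px, across 20 amplitudes."""
    g = 0.5
    screen = make_phase_screen(256, seed=20)
    base = speckle_intensity(screen)
    ref = _crop_center(base, 112) / base.mean()
    tilts = np.linspace(-4.0, 4.0, 20)  # urad
    recovered = []
    for theta in tilts:
        frame = render_frame(
            screen, shift=(g * theta, 0.0), frame_size=112, sensor=FLOAT_SENSOR,
            _base_intensity=base,
        )
        dx, _ = sn.estimate_shift(ref, frame)
        recovered.append(dx)
    slope, intercept = np.polyfit(tilts, recovered, 1)
    assert slope == pytest.approx(g, rel=0.02)
    assert abs(intercept) < 0.05
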
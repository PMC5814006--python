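"""Filter chain, MVC scaling, side averaging and subject renormalization."""

import numpy as np
import pytest

import emglift as eg
from emglift.preprocessing import FilterSpec
from emglift.synthetic import LiftTrial

FS = 1200.0


def _tone(freq, amp=1.0, duration=5.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestLinearEnvelope:
    def test_mains_tone_suppressed_below_one_percent(self):
        """A pure 60 Hz tone falls inside the bandstop: the steady-state
        envelope (central third, clear of the notch filter's long edge
        transients) stays below 1% of the input amplitude."""
        out = eg.linear_envelope(_tone(60.0), FS)
        n = len(out)
        assert np.abs(out[n // 3 : 2 * n // 3]).max() < 0.01

    def test_zero_input_zero_output(self):
        out = eg.linear_envelope(np.zeros(6000), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_inband_tone_envelope_matches_rectified_sine_mean(self):
        """Full-wave rectified sine of amplitude A has mean 2A/π; a
        DC-preserving lowpass of the rectified tone approaches it."""
        A = 2.5
        out = eg.linear_envelope(_tone(100.0, amp=A), FS)
        steady = out[len(out) // 3 : 2 * len(out) // 3]
        expected = 2 * A / np.pi
        assert abs(steady.mean() - expected) / expected < 0.10

    def test_corner_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            eg.linear_envelope(_tone(10.0, fs=500.0, duration=2.0), 500.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            eg.linear_envelope(np.ones(10), FS)

    def test_zero_phase_symmetric_burst_stays_symmetric(self):
        """Zero-phase contract: a symmetric tone burst yields an output whose
        peak stays at the centre within 1 sample."""
        n = 6001
        t = (np.arange(n) - n // 2) / FS
        burst = np.cos(2 * np.pi * 100.0 * t) * np.exp(-0.5 * (t / 0.3) ** 2)
        out = eg.linear_envelope(burst, FS)
        assert abs(int(np.argmax(out)) - n // 2) <= 1
        # symmetry of the envelope about the centre
        np.testing.assert_allclose(out, out[::-1], atol=1e-6 * np.abs(out).max())


class TestNormalizeToMvc:
    @pytest.mark.parametrize("scale,expected", [(1.0, 100.0), (0.5, 50.0)])
    def test_constant_fractions(self, scale, expected):
        env = np.full(100, 0.8 * scale)
        np.testing.assert_allclose(eg.normalize_to_mvc(env, 0.8), expected * np.ones(100))

    def test_doubling_mvc_halves_output(self, rng):
        env = rng.random(50)
        np.testing.assert_allclose(
            eg.normalize_to_mvc(env, 2.0), eg.normalize_to_mvc(env, 1.0) / 2.0
        )

    def test_nonpositive_mvc_rejected(self):
        with pytest.raises(ValueError):
            eg.normalize_to_mvc(np.ones(3), 0.0)


class TestAverageSides:
    def test_identical_channels_pass_through(self, rng):
        x = rng.random(100)
        chans = {"left-lateral": x, "left-medial": x.copy(),
                 "right-medial": rng.random(100), "right-lateral": rng.random(100)}
        left, _, report = eg.average_sides(chans)
        np.testing.assert_array_equal(left, x)
        assert report.pairs[("left-lateral", "left-medial")] == pytest.approx(1.0)

    def test_simple_arithmetic(self):
        chans = {
            "left-lateral": np.array([1.0, 2.0, 3.0]),
            "left-medial": np.array([3.0, 4.0, 5.0]),
            "right-medial": np.array([0.0, 0.0, 1.0]),
            "right-lateral": np.array([2.0, 2.0, 3.0]),
        }
        left, right, _ = eg.average_sides(chans)
        np.testing.assert_array_equal(left, [2.0, 3.0, 4.0])
        np.testing.assert_array_equal(right, [1.0, 1.0, 2.0])

    def test_faulty_right_medial_uses_right_lateral_verbatim(self, rng):
        chans = {"left-lateral": rng.random(60), "left-medial": rng.random(60),
                 "right-medial": rng.random(60), "right-lateral": rng.random(60)}
        _, right, report = eg.average_sides(chans, faulty="right-medial")
        np.testing.assert_array_equal(right, chans["right-lateral"])
        assert not any("right-medial" in pair for pair in report.pairs)

    def test_low_correlation_pairs_flagged(self, rng):
        n = 500
        common = rng.random(n)
        chans = {"left-lateral": common, "left-medial": common + 1e-3 * rng.random(n),
                 "right-medial": rng.random(n), "right-lateral": rng.random(n)}
        _, _, report = eg.average_sides(chans)
        assert ("right-medial", "right-lateral") in report.flagged

    def test_whole_side_faulty_errors(self, rng):
        chans = {"left-lateral": rng.random(10), "left-medial": rng.random(10),
                 "right-lateral": rng.random(10)}
        with pytest.raises(ValueError, match="right"):
            eg.average_sides(chans, faulty="right-lateral")


def _toy_subject(peaks_by_lift):
    """Subject with one lift per (lift_index, label, peak %MVC)."""
    trials = []
    for idx, (label, peak) in enumerate(peaks_by_lift):
        env = np.linspace(0, peak, 50)
        trials.append(
            LiftTrial(subject_id="S01", lift_index=idx, label=label,
                      emg=np.vstack([env, env * 0.9]),
                      channel_names=("left-avg", "right-avg"),
                      event_signal=np.zeros(50), event_kind="circuit",
                      fs=100.0, true_onset_sample=25)
        )
    return trials


class TestRenormalizeSubject:
    def test_divides_by_first_heavy_lift_peak(self):
        trials = _toy_subject([("no-weight", 20.0), ("24-lbs", 80.0), ("24-lbs", 90.0)])
        out, factor = eg.renormalize_subject(trials)
        assert factor == 80.0
        assert out[1].emg.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out[0].emg, trials[0].emg / 80.0)

    def test_identity_when_first_heavy_peak_is_one(self):
        trials = _toy_subject([("24-lbs", 1.0), ("10-lbs", 0.5)])
        out, factor = eg.renormalize_subject(trials)
        assert factor == 1.0
        np.testing.assert_array_equal(out[0].emg, trials[0].emg)

    def test_chronological_order_decides_the_factor(self):
        """Scaling is order-dependent: the factor follows the recorded
        lift_index, not list position."""
        trials = _toy_subject([("24-lbs", 80.0), ("24-lbs", 40.0)])
        out_fwd, f_fwd = eg.renormalize_subject(trials)
        out_rev, f_rev = eg.renormalize_subject(list(reversed(trials)))
        assert f_fwd == f_rev == 80.0  # same chronology, either list order
        swapped = _toy_subject([("24-lbs", 40.0), ("24-lbs", 80.0)])
        _, f_sw = eg.renormalize_subject(swapped)
        assert f_sw == 40.0

    def test_missing_heavy_lift_errors(self):
        trials = _toy_subject([("no-weight", 20.0), ("10-lbs", 50.0)])
        with pytest.raises(ValueError, match="24-lbs"):
            eg.renormalize_subject(trials)

    def test_rescaling_preserves_shape(self):
        """Pure scaling: every lift correlates 1.0 with its pre-scaling self."""
        trials = _toy_subject([("24-lbs", 70.0), ("10-lbs", 30.0)])
        out, _ = eg.renormalize_subject(trials)
        for before, after in zip(trials, out):
            r = np.corrcoef(before.emg.ravel(), after.emg.ravel())[0, 1]
            assert r == pytest.approx(1.0)
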
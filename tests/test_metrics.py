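"""Kinematic metrics: reach amplitude, R^2, ellipse fit, lag, spectra."""

import numpy as np
import pytest

from delayrep import (
    ReachSpec,
    Trajectory,
    dominant_frequency,
    fft_amplitude,
    fit_ellipse,
    gain_model,
    min_jerk,
    periodogram_amplitude,
    reach_amplitude,
    target_hand_delay,
    tracking_r2,
)
from delayrep.metrics import DegenerateFitError, moving_average
from delayrep.tasksim import FrequencyResponse, amplitude_to_db

RATE = 200.0


def make_traj(y, x=None, rate=RATE):
    y = np.asarray(y, float)
    x = np.zeros_like(y) if x is None else np.asarray(x, float)
    return Trajectory(t=np.arange(len(y)) / rate, x=x, y=y, rate=rate)


# ---------------------------------------------------------------------
# reaching
# ---------------------------------------------------------------------

class TestReachAmplitude:
    @staticmethod
    def padded_reach(gain=None):
        """Min-jerk reach with stationary lead-in/out, as recorded trials have."""
        traj = min_jerk(ReachSpec(start=(0, 0), target=(0, 10), tf=0.3))
        if gain is not None:
            traj = gain_model(traj, gain, (0.0, 0.0))
        y = np.concatenate([np.zeros(40), traj.y, np.full(40, traj.y[-1])])
        return make_traj(y)

    def test_min_jerk_amplitude(self):
        *_, amp = reach_amplitude(self.padded_reach())
        assert amp == pytest.approx(10.0, abs=0.05)

    def test_time_reversal_symmetry(self):
        traj = self.padded_reach()
        *_, amp = reach_amplitude(traj)
        *_, amp_rev = reach_amplitude(make_traj(traj.y[::-1]))
        assert amp_rev == pytest.approx(amp, abs=0.05)

    def test_gain_scales_amplitude(self):
        *_, amp = reach_amplitude(self.padded_reach(gain=1.2))
        assert amp == pytest.approx(12.0, abs=0.06)

    def test_endpoint_is_position_at_end_index(self):
        traj = self.padded_reach()
        onset, end, endpoint, _ = reach_amplitude(traj)
        assert onset < end
        assert np.array_equal(endpoint, traj.positions[end])

    def test_no_movement_rejected(self):
        with pytest.raises(ValueError, match="movement"):
            reach_amplitude(make_traj(np.full(100, 3.0)))


# ---------------------------------------------------------------------
# tracking accuracy
# ---------------------------------------------------------------------

class TestTrackingR2:
    def test_perfect_tracking(self, sine_cycle):
        assert tracking_r2(sine_cycle, sine_cycle) == pytest.approx(1.0)

    def test_constant_offset_scores_one(self, sine_cycle):
        hand = sine_cycle.with_xy(sine_cycle.x + 3.0, sine_cycle.y - 2.0)
        assert tracking_r2(hand, sine_cycle) == pytest.approx(1.0)

    def test_uncorrelated_scores_minus_one(self, rng):
        """Independent equal-variance signals average R^2 ~ -1 (MC oracle).

        var(h - t) = 2 sigma^2 against a denominator of var(h) = sigma^2,
        so uncorrelated tracking is penalized well below the 0.6 filter.
        """
        vals = []
        for _ in range(200):
            a = make_traj(rng.normal(size=400))
            b = make_traj(rng.normal(size=400))
            vals.append(tracking_r2(a, b))
        assert np.mean(vals) == pytest.approx(-1.0, abs=0.05)
        assert np.mean(vals) < 0.6

    def test_zero_variance_rejected(self, sine_cycle):
        hand = sine_cycle.with_xy(np.zeros(len(sine_cycle)),
                                  np.zeros(len(sine_cycle)))
        with pytest.raises(ValueError, match="variance"):
            tracking_r2(hand, sine_cycle)


# ---------------------------------------------------------------------
# ellipse fit
# ---------------------------------------------------------------------

def parametric_ellipse(theta, center, a=3.0, b=1.2, n=400):
    ph = np.linspace(0, 2 * np.pi, n, endpoint=False)
    uu, vv = a * np.cos(ph), b * np.sin(ph)
    u = center[0] + uu * np.cos(theta) - vv * np.sin(theta)
    v = center[1] + uu * np.sin(theta) + vv * np.cos(theta)
    return u, v


class TestFitEllipse:
    def test_axis_aligned_canonical(self):
        """b=0, a<c branch: theta = 0, slope = 0, intercept = 0."""
        ph = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        fit = fit_ellipse(np.cos(ph), 0.5 * np.sin(ph))
        assert fit.theta == pytest.approx(0.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_vertical_canonical(self):
        """b=0, a>c branch: theta = pi/2."""
        ph = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        fit = fit_ellipse(0.5 * np.cos(ph), np.sin(ph))
        assert fit.theta == pytest.approx(np.pi / 2, abs=1e-9)

    @pytest.mark.parametrize("theta", [np.pi / 6, np.pi / 3])
    def test_oblique_branches_recover_angle(self, theta):
        """The two oblique branches of the angle rule, exact to 1e-6."""
        u, v = parametric_ellipse(theta, (1.0, 2.0))
        fit = fit_ellipse(u, v)
        assert fit.theta == pytest.approx(theta, abs=1e-6)
        assert fit.center[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.center[1] == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [2 * np.pi / 3, 3 * np.pi / 4])
    def test_reflected_quadrant_convention(self, theta):
        """For major axes past pi/2 the printed rule reports theta - pi/2.

        Negative target-hand coupling does not occur in tracking data;
        the angle rule's quadrant convention folds such axes back.
        """
        u, v = parametric_ellipse(theta, (0.0, 0.0))
        fit = fit_ellipse(u, v)
        assert fit.theta == pytest.approx(theta - np.pi / 2, abs=1e-6)

    def test_lagged_offset_tracking_scatter(self, sine_cycle):
        """Shift-model scatter: slope 1, intercept = the 4 cm shift."""
        lag = int(0.2 * RATE)
        hand = np.concatenate([np.full(lag, sine_cycle.y[0]),
                               sine_cycle.y[:-lag]]) + 4.0
        fit = fit_ellipse(sine_cycle.y, hand)
        # the held start-up samples perturb the pure Lissajous slightly
        assert fit.slope == pytest.approx(1.0, rel=5e-3)
        assert fit.intercept == pytest.approx(4.0, abs=0.05)

    def test_translation_equivariance(self):
        u, v = parametric_ellipse(np.pi / 5, (0.0, 0.0))
        f0 = fit_ellipse(u, v)
        du, dv = 3.7, -1.9
        f1 = fit_ellipse(u + du, v + dv)
        assert f1.center[0] == pytest.approx(f0.center[0] + du, abs=1e-6)
        assert f1.center[1] == pytest.approx(f0.center[1] + dv, abs=1e-6)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-9)
        assert f1.intercept == pytest.approx(
            f0.intercept + dv - f0.slope * du, abs=1e-6)

    def test_near_collinear_falls_back_to_principal_axis(self, rng):
        u = np.linspace(-8, 8, 1000)
        v = 1.5 * u + rng.normal(0, 1e-5, 1000)
        fit = fit_ellipse(u, v)
        assert fit.degenerate
        assert fit.slope == pytest.approx(1.5, rel=1e-3)

    def test_exactly_collinear_raises(self):
        u = np.linspace(0, 10, 50)
        with pytest.raises(DegenerateFitError, match="collinear"):
            fit_ellipse(u, 2 * u + 1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 points"):
            fit_ellipse([0, 1, 2, 3, 4], [0, 1, 0, 1, 0])


# ---------------------------------------------------------------------
# cross-correlation lag
# ---------------------------------------------------------------------

def brute_force_lag(h, g, rate, max_lag=2.0):
    """Independent oracle: explicit per-lag Pearson correlation search."""
    h = np.asarray(h, float)
    g = np.asarray(g, float)
    n = len(h)
    K = min(int(round(max_lag * rate)), n - 1)
    best, bestk = -np.inf, 0
    for k in range(-K, K + 1):
        if k >= 0:
            a, b = h[k:], g[:n - k]
        else:
            a, b = h[:n + k], g[-k:]
        ac, bc = a - a.mean(), b - b.mean()
        d = np.sqrt((ac @ ac) * (bc @ bc))
        c = (ac @ bc) / d if d > 0 else -np.inf
        if c > best:
            best, bestk = c, k
    return -bestk / rate


class TestTargetHandDelay:
    def test_identical_signals(self, sine_cycle):
        assert target_hand_delay(sine_cycle.y, sine_cycle.y, RATE) == 0.0

    def test_advance_and_delay_signs(self, sine_cycle):
        k = int(0.2 * RATE)
        delayed = np.concatenate([np.full(k, sine_cycle.y[0]),
                                  sine_cycle.y[:-k]])
        advanced = np.concatenate([sine_cycle.y[k:],
                                   np.full(k, sine_cycle.y[-1])])
        assert target_hand_delay(delayed, sine_cycle.y, RATE) == pytest.approx(
            -0.2, abs=1e-12)
        assert target_hand_delay(advanced, sine_cycle.y, RATE) == pytest.approx(
            0.2, abs=1e-12)

    def test_matches_brute_force_on_varied_signals(self, rng):
        """Argmax equals an explicit shift-and-correlate search exactly."""
        from scipy.ndimage import uniform_filter1d

        for _ in range(10):
            n = int(rng.integers(400, 900))
            sig = uniform_filter1d(rng.normal(size=n), 25)
            noise = 0.01 * rng.normal(size=n)
            shift = int(rng.integers(1, 60))
            h = np.concatenate([sig[shift:], np.full(shift, sig[-1])]) + noise
            ml = 0.4 * (n - 1) / 100.0
            assert target_hand_delay(h, sig, 100.0, max_lag=ml) == \
                brute_force_lag(h, sig, 100.0, max_lag=ml)

    def test_constant_signal_rejected(self, sine_cycle):
        with pytest.raises(ValueError, match="constant"):
            target_hand_delay(np.ones(len(sine_cycle)), sine_cycle.y, RATE)

    def test_excessive_max_lag_rejected(self, sine_cycle):
        with pytest.raises(ValueError, match="max_lag"):
            target_hand_delay(sine_cycle.y, sine_cycle.y, RATE, max_lag=3.0)


# ---------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------

class TestPeriodogram:
    def test_pure_sine_recovery(self):
        t = np.arange(0, 120, 1 / RATE)
        resp = periodogram_amplitude(2 * np.sin(2 * np.pi * 0.42 * t), RATE,
                                     probe_freqs=[0.42])
        assert resp.amp_cm[0] == pytest.approx(2.0, rel=0.02)

    def test_zero_signal(self):
        resp = periodogram_amplitude(np.zeros(1000), RATE,
                                     probe_freqs=[0.3, 0.6])
        assert np.allclose(resp.amp_cm, 0.0)

    def test_two_separated_sines(self):
        t = np.arange(0, 120, 1 / RATE)
        sig = 1.0 * np.sin(2 * np.pi * 0.3 * t) + 3.0 * np.sin(2 * np.pi * 0.9 * t)
        resp = periodogram_amplitude(sig, RATE, probe_freqs=[0.3, 0.9])
        assert resp.amp_cm[0] == pytest.approx(1.0, rel=0.02)
        assert resp.amp_cm[1] == pytest.approx(3.0, rel=0.02)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            periodogram_amplitude(np.ones(100), RATE, probe_freqs=[150.0])

    def test_parseval(self, rng):
        """Total spectral power equals windowed-signal energy to 0.1%."""
        from scipy.signal import get_window

        x = rng.normal(size=2048)
        pad = 4
        resp_pow = periodogram_amplitude(x, RATE, pad_factor=pad).amp_cm**2 / 2
        # invert the one-sided spectrum scaling back to |X|^2 and apply
        # Parseval: sum |X_k|^2 = nfft * sum |w x|^2
        w = get_window("hann", len(x))
        nfft = pad * len(x)
        two_sided = resp_pow * (np.sum(w)) ** 2
        two_sided[1:] /= 2.0  # undo one-sided doubling (DC not doubled)
        total = 2 * np.sum(two_sided[1:]) + two_sided[0]
        energy = nfft * np.sum((w * x) ** 2)
        assert total == pytest.approx(energy, rel=1e-3)


class TestFFTAmplitude:
    def test_integral_cycles_exact(self):
        t = np.arange(0, 10, 1 / RATE)
        resp = fft_amplitude(3 * np.sin(2 * np.pi * 1.0 * t), RATE,
                             pad_factor=1)
        k = np.argmin(np.abs(resp.freqs - 1.0))
        assert resp.amp_cm[k] == pytest.approx(3.0, abs=1e-6)

    def test_dc_only(self):
        resp = fft_amplitude(np.full(1000, 2.0), RATE, pad_factor=1)
        assert np.all(resp.amp_cm[1:] < 1e-9)

    def test_linearity(self, rng):
        x = rng.normal(size=512)
        r1 = fft_amplitude(x, RATE)
        r2 = fft_amplitude(2 * x, RATE)
        assert np.allclose(r2.amp_cm, 2 * r1.amp_cm)


class TestDominantFrequency:
    def _resp(self, amps, freqs):
        return FrequencyResponse(freqs=freqs, amp_cm=amps,
                                 amp_db=amplitude_to_db(amps))

    def test_single_peak_in_band(self):
        f = np.linspace(0.01, 3, 3000)
        a = 0.1 + np.exp(-((f - 1.0) / 0.05) ** 2)
        freq, peak = dominant_frequency(self._resp(a, f))
        assert freq == pytest.approx(1.0, abs=0.02)

    def test_band_excludes_larger_outside_peak(self):
        f = np.linspace(0.01, 3, 3000)
        a = (0.1 + 5 * np.exp(-((f - 0.3) / 0.03) ** 2)
             + np.exp(-((f - 1.0) / 0.05) ** 2))
        freq, _ = dominant_frequency(self._resp(a, f))
        assert freq == pytest.approx(1.0, abs=0.02)

    def test_flat_ties_break_low(self):
        f = np.linspace(0.01, 3, 300)
        freq, _ = dominant_frequency(self._resp(np.ones(300), f))
        assert freq == f[np.argmax(f >= 0.5)]

    def test_empty_band_rejected(self):
        f = np.linspace(0.01, 3, 300)
        with pytest.raises(ValueError):
            dominant_frequency(self._resp(np.ones(300), f), band=(2.0, 1.0))

    def test_moving_average_edges_shrink(self):
        v = np.arange(10, dtype=float)
        out = moving_average(v, 5)
        assert out[0] == v[0]                # window shrinks to 1 at the edge
        assert out[1] == pytest.approx(np.mean(v[:3]))
        assert out[5] == pytest.approx(np.mean(v[3:8]))
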
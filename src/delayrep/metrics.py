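"""Kinematic metrics that discriminate the delay-representation models.

* reach amplitude with velocity-threshold onset/offset — overshoot in
  blind reaching separates state-based from time-based representations;
* tracking R^2 with a < 0.6 exclusion filter;
* conic ellipse fit of target-vs-hand position scatter, and the slope
  and ordinate intercept of its major axis — slope > 1 indicates a gain
  (or mechanical) representation, a raised intercept a spatial shift;
* target-hand cross-correlation delay — a change indicates a time
  representation;
* Hann-windowed periodogram and plain FFT amplitude spectra with dB
  conversion, moving-average smoothing and dominant-frequency
  extraction — a frequency-dependent amplitude increase indicates a
  mechanical representation, a flat one a gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .models import _deriv1
from .tasksim import FrequencyResponse, amplitude_to_db
from .trajectory import Trajectory

__all__ = [
    "EllipseFit",
    "DegenerateFitError",
    "reach_amplitude",
    "tracking_r2",
    "R2_EXCLUSION",
    "fit_ellipse",
    "target_hand_delay",
    "periodogram_amplitude",
    "fft_amplitude",
    "dominant_frequency",
    "moving_average",
]

#: trials with tracking R^2 below this are excluded from analysis
R2_EXCLUSION = 0.6


class DegenerateFitError(ValueError):
    """Raised when the target-hand scatter is exactly collinear."""


# ---------------------------------------------------------------------
# reaching
# ---------------------------------------------------------------------

def reach_amplitude(
    traj: Trajectory,
    onset_frac: float = 0.02,
    offset_frac: float = 0.05,
    offset_hold: float = 0.1,
):
    """Reach onset, end, endpoint and amplitude from velocity thresholds.

    Onset is the first sample whose speed exceeds ``onset_frac`` of the
    maximum speed; the movement ends ``offset_hold`` seconds after the
    speed first drops below ``offset_frac`` of the maximum following
    the peak (clipped to the last sample).  Amplitude is the Euclidean
    distance between the positions at onset and end.

    Returns ``(onset_index, end_index, endpoint, amplitude_cm)``.
    """
    dt = traj.dt
    vx = _deriv1(traj.x, dt)
    vy = _deriv1(traj.y, dt)
    speed = np.hypot(vx, vy)
    vmax = float(np.max(speed))
    if vmax <= 0:
        raise ValueError("no movement: velocity is zero throughout")
    onset_candidates = np.flatnonzero(speed > onset_frac * vmax)
    onset = int(onset_candidates[0])
    peak = int(np.argmax(speed))
    below = np.flatnonzero(speed[peak:] < offset_frac * vmax)
    if len(below) == 0:
        stop = len(speed) - 1
    else:
        stop = peak + int(below[0])
    end = min(stop + int(round(offset_hold * traj.rate)), len(speed) - 1)
    endpoint = traj.positions[end].astype(float)
    amplitude = float(np.linalg.norm(endpoint - traj.positions[onset]))
    return onset, end, endpoint, amplitude


# ---------------------------------------------------------------------
# tracking accuracy
# ---------------------------------------------------------------------

def tracking_r2(hand: Trajectory, target: Trajectory) -> float:
    """Tracking accuracy: R^2 = 1 - var(hand-target error)/var(hand).

    Both variances sum the two coordinates.  Note a constant positional
    offset does not reduce R^2 (the variance of a constant is zero), so
    the measure scores pattern fidelity, not absolute accuracy.
    """
    if len(hand) != len(target):
        raise ValueError("hand and target must have equal length")
    denom = float(np.var(hand.x) + np.var(hand.y))
    if denom <= 0:
        raise ValueError("undefined R^2: hand trajectory has zero variance")
    num = float(np.var(hand.x - target.x) + np.var(hand.y - target.y))
    return 1.0 - num / denom


# ---------------------------------------------------------------------
# ellipse fit of the target-hand position scatter
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseFit:
    """Conic ellipse fitted to paired (target, hand) position samples.

    ``conic`` holds (a, b, c, d, e, f) in the cross-term convention
    a u^2 + 2b uv + c v^2 + 2d u + 2e v + f = 0 with u the target and v
    the hand coordinate.  ``theta`` is the counterclockwise angle from
    the target axis to the major axis; ``slope`` = tan(theta) and
    ``intercept`` = o_h - slope * o_t, the major line's parameters in
    hand-vs-target space.  ``degenerate`` flags the principal-axis
    fallback used for near-collinear scatter.
    """

    conic: tuple[float, float, float, float, float, float]
    center: tuple[float, float]
    theta: float
    slope: float
    intercept: float
    axes: tuple[float, float]
    degenerate: bool = False


def _fit_conic(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Direct least-squares ellipse fit (ellipse-specific constraint).

    Returns conic coefficients [A, B, C, D, E, F] for
    A u^2 + B uv + C v^2 + D u + E v + F = 0 with 4AC - B^2 = 1.
    Solved on mean-centred data for conditioning, then shifted back.
    """
    mu, mv = u.mean(), v.mean()
    uc, vc = u - mu, v - mv
    D1 = np.column_stack([uc**2, uc * vc, vc**2])
    D2 = np.column_stack([uc, vc, np.ones_like(uc)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    # inverse of the constraint matrix [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    eigval, eigvec = eigval.real, eigvec.real
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.flatnonzero((cond > 0) & np.isfinite(eigval))
    if len(ok) == 0:
        raise DegenerateFitError(
            "no ellipse solution; scatter is degenerate (the near-collinear "
            "principal-axis fallback applies only to non-collinear data)"
        )
    k = ok[np.argmax(eigval[ok].real)]
    a1 = eigvec[:, k].real
    coeffs_c = np.concatenate([a1, T @ a1])
    A, B, C, D, E, F = coeffs_c
    # undo the centring: substitute u -> u - mu, v -> v - mv
    D0 = D - 2 * A * mu - B * mv
    E0 = E - B * mu - 2 * C * mv
    F0 = F + A * mu**2 + B * mu * mv + C * mv**2 - D * mu - E * mv
    return np.array([A, B, C, D0, E0, F0])


def _acot(z: float) -> float:
    """Arc-cotangent with range (-pi/2, pi/2] (acot(0) = pi/2)."""
    if z == 0:
        return np.pi / 2
    return float(np.arctan(1.0 / z))


def _major_axis_angle(a: float, b: float, c: float) -> float:
    """Counterclockwise angle of the ellipse's major axis, in [0, pi).

    Four-case rule on the cross term b (half-coefficient convention):
    axis-aligned ellipses give 0 or pi/2; otherwise the half
    arc-cotangent of (a - c)/(2b), offset by pi/2 when the sign pattern
    of b and a - c puts the major axis past 45 degrees.  At a = c the
    two oblique branches agree (pi/4 for b < 0, 3 pi/4 for b > 0).
    """
    if abs(b) <= 1e-10 * (abs(a) + abs(c)):
        return 0.0 if a <= c else np.pi / 2
    half = 0.5 * _acot((a - c) / (2.0 * b))
    if (b < 0 and a <= c) or (b > 0 and a >= c):
        return half % np.pi
    return (np.pi / 2 + half) % np.pi


def _axis_lengths(a, b, c, d, e, f) -> tuple[float, float]:
    """Semi-axis lengths (major, minor) of the conic (half-coeff form)."""
    # standard closed form for a u^2 + 2b uv + c v^2 + 2d u + 2e v + f = 0
    num = 2 * (a * e**2 + c * d**2 + f * b**2 - 2 * b * d * e - a * c * f)
    s = np.sqrt((a - c) ** 2 + 4 * b**2)
    den1 = (b**2 - a * c) * (s - (a + c))
    den2 = (b**2 - a * c) * (-s - (a + c))
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.sqrt(num / den1) if den1 != 0 else np.nan
        r2 = np.sqrt(num / den2) if den2 != 0 else np.nan
    axes = sorted([float(r1), float(r2)], reverse=True)
    return axes[0], axes[1]


def _principal_axis_fallback(u: np.ndarray, v: np.ndarray) -> EllipseFit:
    """Slope from the principal axis of the centred scatter.

    Used when the scatter is too close to a line for a stable conic
    fit; the intercept passes through the centroid.
    """
    mu, mv = float(u.mean()), float(v.mean())
    cov = np.cov(u - mu, v - mv)
    w, vecs = np.linalg.eigh(cov)
    principal = vecs[:, int(np.argmax(w))]
    if principal[0] == 0:
        theta = np.pi / 2
        slope = np.inf
        intercept = np.nan
    else:
        theta = float(np.arctan2(principal[1], principal[0])) % np.pi
        slope = float(np.tan(theta))
        intercept = mv - slope * mu
    major = 2.0 * np.sqrt(max(w))
    minor = 2.0 * np.sqrt(max(min(w), 0.0))
    return EllipseFit(
        conic=(np.nan,) * 6,
        center=(mu, mv),
        theta=theta,
        slope=slope,
        intercept=float(intercept),
        axes=(major, minor),
        degenerate=True,
    )


def fit_ellipse(
    target_pos: np.ndarray,
    hand_pos: np.ndarray,
    *,
    degeneracy_ratio: float = 1e-3,
) -> EllipseFit:
    """Fit an ellipse to paired target/hand positions of one dimension.

    The scatter of (target, hand) samples over a cyclic tracking trial
    traces an ellipse; its major-axis slope measures the amplitude
    mapping between target and hand (gain), and its intercept any
    constant offset (spatial shift).

    Uses the direct least-squares conic fit with the ellipse-specific
    constraint; when the fitted minor/major axis ratio falls below
    ``degeneracy_ratio`` (near-collinear scatter, e.g. lag-free
    tracking), the slope is taken from the principal axis of the
    centred scatter instead, with the intercept through the centroid.
    Exactly collinear input raises :class:`DegenerateFitError`.
    """
    u = np.asarray(target_pos, float).ravel()
    v = np.asarray(hand_pos, float).ravel()
    if len(u) != len(v):
        raise ValueError("target and hand sample lists must have equal length")
    if len(u) < 6:
        raise ValueError(f"need at least 6 points to fit a conic, got {len(u)}")
    # exact collinearity: zero secondary variance of the centred scatter
    cov = np.cov(u - u.mean(), v - v.mean())
    eigs = np.linalg.eigvalsh(cov)
    if max(eigs) <= 0:
        raise DegenerateFitError("all points coincide; no ellipse or axis exists")
    if min(eigs) / max(eigs) < 1e-24:
        raise DegenerateFitError(
            "points are exactly collinear; the principal-axis fallback "
            "needs non-degenerate scatter"
        )
    try:
        A, B, C, D, E, F = _fit_conic(u, v)
    except DegenerateFitError:
        return _principal_axis_fallback(u, v)
    # half-coefficient (cross-term) convention
    a, b, c = A, B / 2.0, C
    d, e = D / 2.0, E / 2.0
    f = F
    denom = b**2 - a * c
    if denom == 0 or not np.isfinite(denom):
        return _principal_axis_fallback(u, v)
    ot = (c * d - b * e) / denom
    oh = (a * e - b * d) / denom
    major, minor = _axis_lengths(a, b, c, d, e, f)
    if not (np.isfinite(major) and np.isfinite(minor)) or (
        minor / major < degeneracy_ratio
    ):
        return _principal_axis_fallback(u, v)
    theta = _major_axis_angle(a, b, c)
    slope = float(np.tan(theta))
    intercept = float(oh - slope * ot)
    return EllipseFit(
        conic=(float(a), float(b), float(c), float(d), float(e), float(f)),
        center=(float(ot), float(oh)),
        theta=float(theta),
        slope=slope,
        intercept=intercept,
        axes=(major, minor),
        degenerate=False,
    )


# ---------------------------------------------------------------------
# cross-correlation target-hand delay
# ---------------------------------------------------------------------

def target_hand_delay(
    hand: np.ndarray,
    target: np.ndarray,
    rate: float,
    max_lag: float = 2.0,
) -> float:
    """Lag of maximal cross-correlation between hand and target, seconds.

    For each integer-sample lag within ``+-max_lag`` the Pearson
    correlation of the two overlapping segments is computed (each
    segment centred on its own mean), and the lag maximizing it is
    returned in seconds.  A signal that is an exact sample-shifted copy
    of the other therefore peaks exactly at the true shift, regardless
    of how much of it slides out of view or how padding at the edges
    offsets the segment means.  Positive output means the hand movement
    preceded the target's.
    """
    h = np.asarray(hand, float).ravel()
    g = np.asarray(target, float).ravel()
    if len(h) != len(g):
        raise ValueError("hand and target must have equal length")
    n = len(h)
    if np.ptp(h) == 0 or np.ptp(g) == 0:
        raise ValueError("undefined lag: constant signal")
    if max_lag >= (n - 1) / rate / 2:
        raise ValueError("max_lag must be below half the signal duration")
    # c[k] = sum_n h[n] g[n - k]; hand leading the target by L samples
    # (h[n] = g[n + L]) peaks at k = -L, so the delay is -k_max / rate
    c = _sig.correlate(h, g, mode="full", method="auto")
    lags = _sig.correlation_lags(n, n, mode="full")
    kmax = min(int(round(max_lag * rate)), n - 1)
    keep = np.abs(lags) <= kmax
    c, lags = c[keep], lags[keep]
    # per-overlap sums via cumulative sums: for lag k >= 0 the overlap
    # is h[k:] vs g[:n-k], for k < 0 it is h[:n+k] vs g[-k:]
    def _tail(cs, k):  # sum over h-side overlap
        return np.where(k >= 0, cs[-1] - cs[np.abs(k)], cs[n - np.abs(k)])

    def _head(cs, k):  # sum over g-side overlap
        return np.where(k >= 0, cs[n - np.clip(k, 0, None)],
                        cs[-1] - cs[np.abs(k)])

    cs_h = np.concatenate([[0.0], np.cumsum(h)])
    cs_g = np.concatenate([[0.0], np.cumsum(g)])
    cs_h2 = np.concatenate([[0.0], np.cumsum(h**2)])
    cs_g2 = np.concatenate([[0.0], np.cumsum(g**2)])
    m = (n - np.abs(lags)).astype(float)
    sh, sg = _tail(cs_h, lags), _head(cs_g, lags)
    sh2, sg2 = _tail(cs_h2, lags), _head(cs_g2, lags)
    cov = c - sh * sg / m
    var_h = sh2 - sh**2 / m
    var_g = sg2 - sg**2 / m
    denom = np.sqrt(np.clip(var_h, 0, None) * np.clip(var_g, 0, None))
    score = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), -np.inf)
    return float(-lags[np.argmax(score)] / rate)


# ---------------------------------------------------------------------
# amplitude spectra
# ---------------------------------------------------------------------

def periodogram_amplitude(
    x: np.ndarray,
    rate: float,
    pad_factor: int = 25,
    probe_freqs: np.ndarray | None = None,
    probe_halfwidth: float = 0.05,
) -> FrequencyResponse:
    """Hann-windowed, zero-padded periodogram amplitude spectrum.

    Power is scaled so that a pure sinusoid of amplitude A gives a peak
    power of A^2/2, whence amplitude = sqrt(2 * pow).  Zero padding to
    ``pad_factor`` times the signal length refines the frequency grid
    so sharp peaks are not missed between bins.

    With ``probe_freqs`` given, the local peak power within
    ``probe_halfwidth`` Hz of each probe is extracted and the response
    is returned at the (sorted) probe frequencies; otherwise the full
    grid is returned.
    """
    x = np.asarray(x, float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError("signal too short")
    nfft = int(pad_factor) * n
    freqs, pxx = _sig.periodogram(
        x, fs=rate, window="hann", nfft=nfft, detrend=False, scaling="spectrum"
    )
    if probe_freqs is None:
        amp = np.sqrt(2.0 * pxx)
        return FrequencyResponse(freqs=freqs, amp_cm=amp,
                                 amp_db=amplitude_to_db(amp))
    probes = np.sort(np.asarray(probe_freqs, float).ravel())
    if np.any(probes > rate / 2):
        raise ValueError("probe frequency above the Nyquist frequency")
    amps = np.empty_like(probes)
    for i, f0 in enumerate(probes):
        sel = np.abs(freqs - f0) <= probe_halfwidth
        if not np.any(sel):
            sel = np.argmin(np.abs(freqs - f0))
        amps[i] = np.sqrt(2.0 * np.max(pxx[sel]))
    return FrequencyResponse(freqs=probes, amp_cm=amps,
                             amp_db=amplitude_to_db(amps))


def fft_amplitude(
    x: np.ndarray, rate: float, pad_factor: int = 25
) -> FrequencyResponse:
    """Zero-padded FFT amplitude spectrum: A(f) = 2 |FFT| / L.

    L is the unpadded signal length, so an integral-cycle sinusoid of
    amplitude A shows a bin of height A.
    """
    x = np.asarray(x, float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError("signal too short")
    nfft = int(pad_factor) * n
    spec = np.fft.rfft(x, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    amp = 2.0 * np.abs(spec) / n
    return FrequencyResponse(freqs=freqs, amp_cm=amp, amp_db=amplitude_to_db(amp))


def moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetric window shrink at the edges.

    At index i the window is the largest symmetric span [i-h, i+h] that
    fits, with h at most (window-1)//2.
    """
    v = np.asarray(v, float).ravel()
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    n = len(v)
    hmax = (window - 1) // 2
    # cumulative-sum trick; per-index symmetric half-width
    csum = np.concatenate([[0.0], np.cumsum(v)])
    out = np.empty(n)
    for i in range(n):
        h = min(hmax, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def dominant_frequency(
    resp: FrequencyResponse,
    band: tuple[float, float] = (0.5, 1.5),
    smooth_window: int = 101,
) -> tuple[float, float]:
    """Frequency of the maximal smoothed dB amplitude within a band.

    The dB profile is smoothed with a centred moving average (window
    ``smooth_window`` samples) before the in-band argmax; ties break
    toward the lowest frequency.  Returns (frequency_hz, peak_db).
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError("empty frequency band")
    sel = (resp.freqs >= lo) & (resp.freqs <= hi)
    if not np.any(sel):
        raise ValueError("band contains no frequency samples")
    smooth = moving_average(resp.amp_db, smooth_window)
    idx = np.flatnonzero(sel)
    vals = smooth[idx]
    peak = float(np.max(vals))
    # ties (to within rounding noise) break toward the lowest frequency
    tol = 1e-9 * max(1.0, abs(peak))
    best = idx[int(np.flatnonzero(vals >= peak - tol)[0])]
    return float(resp.freqs[best]), float(smooth[best])
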
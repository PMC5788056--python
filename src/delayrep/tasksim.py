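"""Target-trajectory generators and blind-task simulators.

Three transfer tasks probe what a player learned during delayed pong:

* blind reaching — fast point-to-point movements to one of three
  targets, simulated as minimum-jerk trajectories;
* blind figure-eight tracking — the target runs a Lissajous
  figure-eight (one frontal cycle per two sagittal cycles);
* blind sinusoid-mixture tracking — the target is a sum of five
  equal-amplitude sines at incommensurate frequencies, which makes the
  hand's frequency response measurable component by component.

In every blind task the participant moves an *imagined* cursor; the
hand they actually produce is the imagined cursor mapped through their
delay representation (see :mod:`delayrep.models`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    RepresentationParams,
    apply_model,
    mechanical_amplitude_gain,
    time_model,
)
from .trajectory import Trajectory

__all__ = [
    "ReachSpec",
    "TrackSpec",
    "FrequencyResponse",
    "DEFAULT_RATE",
    "MIXTURE_FREQS",
    "MIXTURE_PHASES",
    "min_jerk",
    "figure_eight",
    "sinusoid_mixture",
    "delay_trajectory",
    "simulate_blind_reach",
    "simulate_blind_tracking",
    "frequency_response_prediction",
]

#: default sampling rate for simulated transfer-task trajectories, Hz
#: (the recording rate of the motion-capture setup being emulated)
DEFAULT_RATE = 200.0

#: the five mixture component frequencies (Hz) and phases (rad)
MIXTURE_FREQS = (0.31, 0.67, 0.23, 0.42, 0.54)
MIXTURE_PHASES = (0.0, np.pi / 4, np.pi, 3 * np.pi / 2, np.pi / 3)


@dataclass(frozen=True)
class ReachSpec:
    """A point-to-point reach: start and target in cm, duration in s."""

    start: tuple[float, float] = (0.0, 0.0)
    target: tuple[float, float] = (0.0, 10.0)
    tf: float = 0.3
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.tf <= 0:
            raise ValueError("tf must be positive")
        if np.allclose(self.start, self.target):
            raise ValueError("start and target coincide")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from start to target."""
        d = np.asarray(self.target, float) - np.asarray(self.start, float)
        return d / np.linalg.norm(d)

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(
            np.asarray(self.target, float) - np.asarray(self.start, float)))


@dataclass(frozen=True)
class TrackSpec:
    """A tracking path: figure-eight or five-sine mixture.

    ``A`` is the amplitude in cm (path amplitude for the figure-eight,
    per-component amplitude for the mixture), ``T`` the figure-eight
    cycle time in s, ``fr``/``phi`` the mixture frequencies (Hz) and
    phases (rad).
    """

    path_kind: str = "figure_eight"
    A: float = 8.0
    T: float = 5.0
    fr: tuple[float, ...] = MIXTURE_FREQS
    phi: tuple[float, ...] = MIXTURE_PHASES
    center: tuple[float, float] = (0.0, 0.0)
    duration: float | None = None
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.path_kind not in ("figure_eight", "sinusoid_mixture"):
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.path_kind == "sinusoid_mixture" and len(self.fr) != len(self.phi):
            raise ValueError("fr and phi must have the same length")

    @property
    def effective_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        # one full figure-eight cycle, or the standard 2 min mixture trial
        return self.T if self.path_kind == "figure_eight" else 120.0


@dataclass(frozen=True)
class FrequencyResponse:
    """Paired frequency / amplitude vectors, in cm and in dB.

    The dB convention is dB = 10*log10(A^2/2), i.e. decibels of the
    power of a sinusoid with amplitude A.
    """

    freqs: np.ndarray
    amp_cm: np.ndarray
    amp_db: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        a = np.asarray(self.amp_cm, float)
        db = np.asarray(self.amp_db, float)
        if not (len(f) == len(a) == len(db)):
            raise ValueError("freqs, amp_cm, amp_db must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "amp_cm", a)
        object.__setattr__(self, "amp_db", db)


def amplitude_to_db(amp_cm: np.ndarray) -> np.ndarray:
    """dB of sinusoid power: 10*log10(A^2/2)."""
    amp_cm = np.asarray(amp_cm, float)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(amp_cm**2 / 2.0)


# ---------------------------------------------------------------------
# target generators
# ---------------------------------------------------------------------

def min_jerk(spec: ReachSpec) -> Trajectory:
    """Minimum-jerk point-to-point reach.

    Position follows the quintic profile s(u) = 10u^3 - 15u^4 + 6u^5 per
    axis, the unique polynomial with zero velocity and acceleration at
    both ends; peak speed is 1.875 * distance / tf at the midpoint.
    """
    n = int(round(spec.tf * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    u = np.clip(t / spec.tf, 0.0, 1.0)
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    x0, y0 = spec.start
    x1, y1 = spec.target
    return Trajectory(t=t, x=x0 + (x1 - x0) * s, y=y0 + (y1 - y0) * s,
                      rate=spec.rate)


def figure_eight(spec: TrackSpec) -> Trajectory:
    """Figure-eight Lissajous path: x = A sin(2 pi t / T), y = A sin(4 pi t / T)."""
    if spec.path_kind != "figure_eight":
        raise ValueError("spec.path_kind must be 'figure_eight'")
    n = int(round(spec.effective_duration * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    cx, cy = spec.center
    x = cx + spec.A * np.sin(2 * np.pi * t / spec.T)
    y = cy + spec.A * np.sin(4 * np.pi * t / spec.T)
    return Trajectory(t=t, x=x, y=y, rate=spec.rate)


def sinusoid_mixture(spec: TrackSpec) -> Trajectory:
    """Sagittal five-sine mixture: y(t) = A * sum_i sin(2 pi fr_i t + phi_i).

    The listed ``fr`` values are true frequencies in Hz.  x is constant
    at the path centre (the target moves along a 1D sagittal path).
    """
    if spec.path_kind != "sinusoid_mixture":
        raise ValueError("spec.path_kind must be 'sinusoid_mixture'")
    if len(spec.fr) != len(spec.phi):
        raise ValueError("fr and phi must have the same length")
    n = int(round(spec.effective_duration * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    cx, cy = spec.center
    y = np.zeros(n)
    for f, p in zip(spec.fr, spec.phi):
        y += np.sin(2 * np.pi * f * t + p)
    return Trajectory(t=t, x=np.full(n, cx), y=cy + spec.A * y, rate=spec.rate)


def target_trajectory(spec: TrackSpec) -> Trajectory:
    """Dispatch on path_kind."""
    if spec.path_kind == "figure_eight":
        return figure_eight(spec)
    return sinusoid_mixture(spec)


# ---------------------------------------------------------------------
# blind-task simulators
# ---------------------------------------------------------------------

def delay_trajectory(traj: Trajectory, lag: float) -> Trajectory:
    """Delay a trajectory by ``lag`` seconds, holding the initial sample.

    The inverse of the time model's advance: output(t) = traj(t - lag),
    with the first ``lag`` seconds pinned at traj's first sample.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    shift = int(round(lag * traj.rate))
    if shift == 0:
        return traj.copy()
    if shift >= len(traj):
        raise ValueError("lag exceeds the signal duration")
    x = np.concatenate([np.full(shift, traj.x[0]), traj.x[:-shift]])
    y = np.concatenate([np.full(shift, traj.y[0]), traj.y[:-shift]])
    return traj.with_xy(x, y)


def simulate_blind_reach(
    spec: ReachSpec,
    params: RepresentationParams,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one blind reach and return the endpoint (x, y) in cm.

    The imagined cursor performs the minimum-jerk reach to the target;
    the hand is the active representation applied to it (gain anchored
    at the movement start, shift along the reach direction).  The
    reported endpoint is the hand position at its maximal along-reach
    excursion, plus isotropic Gaussian noise of SD ``noise_sd`` per axis
    — the composite read-out noise of the motor periphery.

    A time representation predicts on-target endpoints (advancing a
    reach in time does not change where it ends); shift, gain and
    mechanical representations all predict overshoot.
    """
    cursor = min_jerk(spec)
    hand = apply_model(cursor, params, origin=spec.start,
                       direction=spec.direction)
    u = spec.direction
    start = np.asarray(spec.start, float)
    excursion = (hand.positions - start) @ u
    idx = int(np.argmax(excursion))
    endpoint = hand.positions[idx].astype(float)
    if noise_sd > 0:
        gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        endpoint = endpoint + gen.normal(0.0, noise_sd, size=2)
    return endpoint


def simulate_blind_tracking(
    spec: TrackSpec,
    params: RepresentationParams,
    baseline_lag: float = 0.2,
) -> tuple[Trajectory, Trajectory]:
    """Simulate one blind tracking trial; returns (target, hand).

    Even without any delay exposure, a tracked hand trails its target by
    a reaction lag (``baseline_lag``, default 0.2 s): the imagined
    cursor is the target delayed by that much, with the target's initial
    sample held over the start-up interval.  The hand is then the active
    representation applied to the imagined cursor; ``variant='none'``
    gives the baseline (post-no-delay) behaviour.

    The time representation is the exception: it predicts a hand that
    precedes the *target* by tau_hat outright, because pre-empting in
    time is exactly what that representation compensates.  Its lead over
    the baseline hand is therefore tau_hat + baseline_lag (0.7 s for
    tau_hat = 0.5 s over a 0.2 s baseline lag).  The state models keep
    the baseline lag; their diagnostics (ellipse slope and intercept,
    amplitude ratio) are lag-invariant.

    Gain is anchored at the path centre (the mean of the cursor path);
    the spatial shift acts along +y, the sagittal axis.
    """
    if baseline_lag < 0:
        raise ValueError("baseline_lag must be >= 0")
    target = target_trajectory(spec)
    cursor = delay_trajectory(target, baseline_lag)
    if params.variant == "time":
        hand = time_model(target, params.tau_hat)
    else:
        hand = apply_model(cursor, params, origin=None, direction=(0.0, 1.0))
    return target, hand


def frequency_response_prediction(
    params: RepresentationParams,
    freqs: np.ndarray,
    At: np.ndarray,
) -> tuple[FrequencyResponse, np.ndarray]:
    """Predicted hand amplitude per frequency under each representation.

    Given a baseline amplitude profile ``At`` (cm) at frequencies
    ``freqs`` (Hz):

    * gain      — Ah = g_hat * At at every frequency (flat dB offset);
    * mechanical — Ah = At * sqrt(1 + tau^4 w^4 / 4) with
      B/K, M/K read as a single tau via B/K (w = 2 pi f): the dB
      difference grows with frequency;
    * time, spatial_shift, none — Ah = At (no amplitude change).

    Returns the predicted response and the dB difference profile
    relative to baseline.
    """
    freqs = np.asarray(freqs, float)
    At = np.asarray(At, float)
    if len(freqs) != len(At):
        raise ValueError("freqs and At must have the same length")
    v = params.variant
    if v == "gain":
        Ah = params.g_hat * At
    elif v == "mechanical":
        omega = 2 * np.pi * freqs
        # single-lag reading of the mechanical ratios: tau = B/K
        Ah = At * mechanical_amplitude_gain(omega, params.b_over_k)
    elif v in ("time", "spatial_shift", "none"):
        Ah = At.copy()
    else:
        raise ValueError(f"unknown variant {v!r}")
    resp = FrequencyResponse(freqs=freqs, amp_cm=Ah, amp_db=amplitude_to_db(Ah))
    db_diff = resp.amp_db - amplitude_to_db(At)
    return resp, db_diff
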
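"""Desk-scale simulator of the delayed pong game.

The game that induces the delay representation: a ball bounces inside a
rectangular arena; the player's hand drives a horizontal paddle whose
displayed position can be delayed by a buffered lag tau; hits are only
registered when the paddle moves upward against a downward-moving ball,
and transfer paddle velocity to the ball through fixed coupling
coefficients.  The upper wall reflects with a stochastic horizontal
jitter so the game never settles into a fixed rally.

The simulator exposes the individual physics rules (delay buffer, wall
reflection, paddle hit, haptic-pulse magnitude, delay schedules) and a
trial loop driven by a paddle-control policy, so the game is
exercisable without human input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "PongConfig",
    "DelaySchedule",
    "PongState",
    "TrialRecord",
    "delay_buffer",
    "reflect_wall",
    "paddle_hit",
    "haptic_pulse",
    "schedule_tau",
    "run_trial",
    "hit_rate",
    "dead_policy",
    "scripted_policy",
    "ball_chaser_policy",
]

#: fraction of pre-hit ball velocity retained through a paddle hit
BALL_RETENTION = 0.7
#: fraction of paddle velocity transferred to the ball at a hit
PADDLE_COUPLING = 0.42


@dataclass(frozen=True)
class DelaySchedule:
    """How the paddle delay evolves over trials.

    ``none`` keeps zero delay; ``abrupt`` applies ``tau_max`` from the
    first trial; ``gradual`` ramps by ``increment`` per trial until
    ``tau_max`` is reached (0.004 s/trial reaches 0.1 s at trial 25).
    """

    kind: str = "none"
    tau_max: float = 0.1
    increment: float = 0.004

    def __post_init__(self) -> None:
        if self.kind not in ("none", "abrupt", "gradual"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.tau_max < 0 or self.increment < 0:
            raise ValueError("tau_max and increment must be >= 0")


def schedule_tau(schedule: DelaySchedule, trial_index: int) -> float:
    """Paddle delay (s) on the given 1-based trial."""
    if trial_index < 1:
        raise ValueError("trial_index is 1-based")
    if schedule.kind == "none":
        return 0.0
    if schedule.kind == "abrupt":
        return schedule.tau_max
    return min(schedule.increment * trial_index, schedule.tau_max)


@dataclass(frozen=True)
class PongConfig:
    """Arena geometry, physics coefficients and schedule for one session.

    Distances in cm, times in s.  The arena spans [0, width] x
    [0, height]; the paddle is a horizontal segment of half-width
    ``paddle_halfwidth`` at the (delayed) hand position.  ``dt`` is the
    control-loop step (1 kHz by default).
    """

    arena_width: float = 24.0
    arena_height: float = 16.0
    dt: float = 0.001
    ball_speed0: float = 20.0
    ball_mass: float = 0.15
    restitution_ball: float = BALL_RETENTION
    paddle_coupling: float = PADDLE_COUPLING
    paddle_halfwidth: float = 2.0
    jitter_kind: str = "normal_angle"
    jitter_scale: float = 0.05 * np.pi   # variance (rad^2) or bound (cm/s)
    delay_schedule: DelaySchedule = field(default_factory=DelaySchedule)
    trial_duration: float = 60.0
    pulse_dt: float = 0.025

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.restitution_ball < 1 and 0 < self.paddle_coupling < 1):
            raise ValueError("coupling coefficients must lie in (0, 1)")
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.jitter_kind not in ("normal_angle", "uniform_velocity", "off"):
            raise ValueError(f"unknown jitter_kind {self.jitter_kind!r}")


@dataclass
class PongState:
    """Evolving state of one trial."""

    ball_pos: np.ndarray
    ball_vel: np.ndarray
    hand_pos: np.ndarray
    paddle_pos: np.ndarray
    hit_count: int = 0
    t: float = 0.0


@dataclass(frozen=True)
class TrialRecord:
    """Recorded trajectories and hit bookkeeping of one trial."""

    t: np.ndarray
    hand: np.ndarray        # (n, 2)
    paddle: np.ndarray      # (n, 2)
    ball: np.ndarray        # (n, 2)
    hit_times: np.ndarray
    hit_count: int
    tau: float
    seed: int | None


# ---------------------------------------------------------------------
# physics rules
# ---------------------------------------------------------------------

def delay_buffer(hand_history: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Displayed paddle position: the hand sample tau seconds back.

    ``hand_history`` is an (n, 2) array of hand samples ending at the
    current step.  The lag is rounded to the nearest whole step; while
    the buffer is shorter than the lag, the earliest sample is shown.
    """
    hist = np.asarray(hand_history, float)
    if hist.ndim == 1:
        hist = hist[None, :]
    if len(hist) == 0:
        raise ValueError("empty hand-history buffer")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    steps = int(round(tau / dt))
    idx = max(len(hist) - 1 - steps, 0)
    return hist[idx].copy()


def reflect_wall(
    ball_vel: np.ndarray,
    wall: str,
    rng: np.random.Generator | None = None,
    jitter_kind: str = "normal_angle",
    jitter_scale: float = 0.05 * np.pi,
) -> np.ndarray:
    """Reflect the ball velocity off an arena wall.

    Side and bottom walls mirror the normal component and conserve
    speed.  The upper wall additionally perturbs the horizontal
    component with a stochastic jitter: either j = -vy * tan(alpha)
    with alpha ~ N(0, jitter_scale) (variance in rad^2), or
    j ~ U(-jitter_scale, +jitter_scale) in cm/s, so the game never
    locks into a repeating vertical rally.
    """
    v = np.asarray(ball_vel, float).copy()
    moving_into = {
        "left": v[0] < 0,
        "right": v[0] > 0,
        "bottom": v[1] < 0,
        "top": v[1] > 0,
    }
    if wall not in moving_into:
        raise ValueError(f"unknown wall {wall!r}")
    if not moving_into[wall]:
        import warnings

        warnings.warn(f"ball not moving toward the {wall} wall; no-op")
        return v
    if wall in ("left", "right"):
        v[0] = -v[0]
        return v
    if wall == "bottom":
        v[1] = -v[1]
        return v
    # upper wall: mirror vertical, jitter horizontal
    vy_pre = v[1]
    v[1] = -v[1]
    if jitter_kind == "off" or rng is None:
        return v
    if jitter_kind == "normal_angle":
        alpha = rng.normal(0.0, np.sqrt(jitter_scale))
        v[0] = v[0] - vy_pre * np.tan(alpha)
    elif jitter_kind == "uniform_velocity":
        v[0] = v[0] + rng.uniform(-jitter_scale, jitter_scale)
    else:
        raise ValueError(f"unknown jitter_kind {jitter_kind!r}")
    return v


def paddle_hit(
    ball_vel: np.ndarray,
    paddle_vel: np.ndarray,
    retention: float = BALL_RETENTION,
    coupling: float = PADDLE_COUPLING,
) -> tuple[bool, np.ndarray]:
    """Resolve a geometric ball-paddle contact.

    A hit registers only when the paddle moves upward and the ball moves
    downward; otherwise the ball passes through the paddle unchanged.
    On a hit the frontal ball velocity becomes
    retention * vx_ball + coupling * vx_paddle and the sagittal one
    -retention * vy_ball + coupling * vy_paddle, which is strictly
    positive given the hit condition — the ball always leaves upward.
    To return the ball at its incoming speed the paddle must move up at
    at least (1 - retention)/coupling (~0.71) of that speed.
    """
    bv = np.asarray(ball_vel, float)
    pv = np.asarray(paddle_vel, float)
    if not (pv[1] > 0 and bv[1] < 0):
        return False, bv.copy()
    new = np.array([
        retention * bv[0] + coupling * pv[0],
        -retention * bv[1] + coupling * pv[1],
    ])
    return True, new


def haptic_pulse(ball_mass: float, dv: float, pulse_dt: float) -> float:
    """Peak force (N) of the haptic pulse rendered at a hit.

    ``ball_mass`` in kg, ``dv`` the sagittal ball velocity change in
    cm/s, ``pulse_dt`` the force-application interval in s; converted to
    SI (m/s) before m * dv / dt.  The triangular force time-profile is a
    rendering detail and is not simulated.
    """
    if pulse_dt <= 0:
        raise ValueError("pulse_dt must be positive")
    return ball_mass * (dv / 100.0) / pulse_dt


# ---------------------------------------------------------------------
# reference paddle policies
# ---------------------------------------------------------------------

def dead_policy(t, ball_pos, ball_vel, paddle_pos):
    """Never moves: produces zero hits."""
    return np.zeros(2)


def scripted_policy(amplitude: float = 30.0, freq: float = 1.0,
                    x_speed: float = 0.0):
    """Open-loop vertical oscillation with optional constant drift."""

    def policy(t, ball_pos, ball_vel, paddle_pos):
        return np.array([x_speed,
                         amplitude * 2 * np.pi * freq * np.cos(2 * np.pi * freq * t)])

    return policy


def ball_chaser_policy(gain: float = 8.0, v_up: float = 40.0,
                       home_y: float = 2.0, reaction_lag: float = 0.0):
    """Proportional tracker: chase the ball in x, swat upward when it falls.

    Tracks the ball's frontal position with a proportional controller,
    and when the ball descends toward the paddle's height, drives the
    paddle upward at ``v_up`` to meet it; otherwise sinks back toward
    ``home_y``.  ``reaction_lag`` delays the policy's view of the ball.
    """
    history: list[tuple[float, np.ndarray, np.ndarray]] = []

    def policy(t, ball_pos, ball_vel, paddle_pos):
        history.append((t, np.array(ball_pos), np.array(ball_vel)))
        if reaction_lag > 0:
            t_look = t - reaction_lag
            while len(history) > 1 and history[0][0] < t_look - 1e-9:
                history.pop(0)
        tb, bp, bv = history[0] if reaction_lag > 0 else history[-1]
        if reaction_lag == 0:
            history.clear()
        vx = gain * (bp[0] - paddle_pos[0])
        gap = bp[1] - paddle_pos[1]
        falling_near = bv[1] < 0 and 0.0 <= gap < 8.0
        vy = v_up if falling_near else gain * (home_y - paddle_pos[1])
        return np.array([vx, vy])

    return policy


# ---------------------------------------------------------------------
# trial loop
# ---------------------------------------------------------------------

def run_trial(
    config: PongConfig,
    policy: Callable = None,
    seed: int | None = 0,
    trial_index: int = 1,
    record_every: int = 1,
) -> TrialRecord:
    """Run one pong trial under a paddle-control policy.

    The policy maps (t, ball_pos, ball_vel, paddle_pos) to a hand
    velocity command in cm/s; the hand integrates it, the paddle shows
    the hand ``tau`` seconds ago (per the delay schedule), and the ball
    flies ballistically between wall and paddle collisions.  Wall
    collisions resolve before paddle collisions within a step; a paddle
    contact is detected when the ball's sagittal position crosses the
    paddle's line within its frontal extent during the step, by linear
    interpolation within the step.  Deterministic given the seed.
    """
    if policy is None:
        policy = dead_policy
    rng = np.random.default_rng(seed)
    dt = config.dt
    n_steps = int(round(config.trial_duration / dt))
    tau = schedule_tau(config.delay_schedule, trial_index)
    lag_steps = int(round(tau / dt))
    w, hgt = config.arena_width, config.arena_height

    hand = np.array([w / 2.0, 2.0])
    hand_hist = np.empty((n_steps + 1, 2))
    hand_hist[0] = hand
    paddle_prev = hand.copy()

    ball = np.array([w / 2.0, hgt / 2.0])
    angle = rng.uniform(np.pi / 4, 3 * np.pi / 4)
    bvel = config.ball_speed0 * np.array([np.cos(angle), np.sin(angle)])

    rec_idx = range(0, n_steps + 1, record_every)
    n_rec = len(rec_idx)
    rec_t = np.empty(n_rec)
    rec_hand = np.empty((n_rec, 2))
    rec_paddle = np.empty((n_rec, 2))
    rec_ball = np.empty((n_rec, 2))
    hit_times: list[float] = []

    jitter_kind = config.jitter_kind
    jitter_scale = config.jitter_scale
    r = 0
    for i in range(n_steps + 1):
        t = i * dt
        paddle = hand_hist[max(i - lag_steps, 0)]
        if i % record_every == 0:
            rec_t[r] = t
            rec_hand[r] = hand
            rec_paddle[r] = paddle
            rec_ball[r] = ball
            r += 1
        if i == n_steps:
            break
        cmd = np.asarray(policy(t, ball, bvel, paddle), float)
        if not np.all(np.isfinite(cmd)):
            raise RuntimeError(
                f"policy returned a non-finite command {cmd} at t={t:.3f} s"
            )
        hand = hand + cmd * dt
        hand[0] = min(max(hand[0], 0.0), w)
        hand[1] = min(max(hand[1], -5.0), hgt)
        hand_hist[i + 1] = hand
        paddle_next = hand_hist[max(i + 1 - lag_steps, 0)]
        paddle_vel = (paddle_next - paddle) / dt

        ball_next = ball + bvel * dt
        # walls first (D11); simultaneous corner hits reflect both axes
        if ball_next[0] < 0 and bvel[0] < 0:
            bvel = reflect_wall(bvel, "left")
            ball_next[0] = -ball_next[0]
        elif ball_next[0] > w and bvel[0] > 0:
            bvel = reflect_wall(bvel, "right")
            ball_next[0] = 2 * w - ball_next[0]
        if ball_next[1] < 0 and bvel[1] < 0:
            bvel = reflect_wall(bvel, "bottom")
            ball_next[1] = -ball_next[1]
        elif ball_next[1] > hgt and bvel[1] > 0:
            vy_pre = bvel[1]
            bvel = reflect_wall(bvel, "top", rng=rng,
                                jitter_kind=jitter_kind,
                                jitter_scale=jitter_scale)
            ball_next[1] = 2 * hgt - ball_next[1]
        # then the paddle: the ball crosses the (moving) paddle line from
        # above within the step, tracked in the relative coordinate so an
        # upward paddle overtaking a falling ball also makes contact
        rel_prev = ball[1] - paddle[1]
        rel_next = ball_next[1] - paddle_next[1]
        if bvel[1] < 0 and paddle_vel[1] > 0 and rel_prev >= 0 > rel_next:
            frac = rel_prev / (rel_prev - rel_next)
            x_at = ball[0] + frac * (ball_next[0] - ball[0])
            p_y = paddle[1] + frac * (paddle_next[1] - paddle[1])
            x_paddle = paddle[0] + frac * (paddle_next[0] - paddle[0])
            if abs(x_at - x_paddle) <= config.paddle_halfwidth:
                hit, new_vel = paddle_hit(
                    bvel, paddle_vel,
                    retention=config.restitution_ball,
                    coupling=config.paddle_coupling,
                )
                if hit:
                    hit_times.append(t + frac * dt)
                    remain = (1.0 - frac) * dt
                    ball_next = np.array([x_at, p_y]) + new_vel * remain
                    bvel = new_vel
        ball = ball_next
        ball[0] = min(max(ball[0], 0.0), w)
        ball[1] = min(max(ball[1], 0.0), hgt)

    return TrialRecord(
        t=rec_t,
        hand=rec_hand,
        paddle=rec_paddle,
        ball=rec_ball,
        hit_times=np.asarray(hit_times),
        hit_count=len(hit_times),
        tau=tau,
        seed=seed,
    )


def hit_rate(hit_times: np.ndarray, duration: float, n_bins: int = 1) -> np.ndarray:
    """Hits per second in equal-duration bins spanning [0, duration].

    Bins are right-closed: a hit exactly on a bin boundary counts in the
    earlier bin.  sum(rate * t_bin) recovers the total hit count.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    hit_times = np.asarray(hit_times, float)
    t_bin = duration / n_bins
    idx = np.clip(np.ceil(hit_times / t_bin).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins) if len(idx) else np.zeros(
        n_bins, dtype=int)
    return counts / t_bin
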
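"""The four candidate representations of a visuomotor delay.

After prolonged play with a paddle that trails the hand by a lag tau, a
player's internal mapping from displayed paddle to hand can take one of
four forms, each of which predicts a different hand trajectory when the
player later moves an *imagined* cursor with no visual feedback:

``time``
    The lag is represented explicitly in time: the estimated hand is the
    paddle a fixed interval tau_hat in the future.
``spatial_shift``
    The lag is folded into a constant spatial offset dx_hat between
    paddle and hand.
``gain``
    The lag is folded into an amplitude gain g_hat > 1 (the paddle
    "moves less" than the hand).
``mechanical``
    The paddle is treated as a damped mass on a spring driven by the
    hand; to second order this is the Taylor form
    hand(t) = paddle(t) + (B/K) paddle'(t) + (M/K) paddle''(t),
    equivalent to the time form when B/K = tau and M/K = tau^2 / 2.

Each model here maps an imagined-cursor trajectory to the hand
trajectory a participant holding that representation would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "RepresentationParams",
    "VARIANTS",
    "identity_map",
    "time_model",
    "spatial_shift_model",
    "gain_model",
    "mechanical_model",
    "taylor_params",
    "mechanical_amplitude_gain",
    "apply_model",
]

VARIANTS = ("none", "time", "spatial_shift", "gain", "mechanical")


@dataclass(frozen=True)
class RepresentationParams:
    """Which representation is active, and its parameter values.

    Only the fields relevant to ``variant`` are read: ``tau_hat`` (s) for
    the time model, ``dx_hat`` (cm) for the spatial shift, ``g_hat``
    (dimensionless, > 1 for a delay) for the gain, and the ratios
    ``b_over_k`` (s) / ``m_over_k`` (s^2) for the mechanical model.  The
    two mechanical ratios are independent: a single-tau Taylor expansion
    constrains them via :func:`taylor_params`, but the model itself does
    not.
    """

    variant: str = "none"
    tau_hat: float = 0.0
    dx_hat: float = 0.0
    g_hat: float = 1.0
    b_over_k: float = 0.0
    m_over_k: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.variant == "time" and self.tau_hat < 0:
            raise ValueError("tau_hat must be >= 0")
        if self.variant == "gain" and self.g_hat <= 0:
            raise ValueError("g_hat must be positive")
        if self.variant == "mechanical" and (
            self.b_over_k < 0 or self.m_over_k < 0
        ):
            raise ValueError("b_over_k and m_over_k must be >= 0")


def identity_map(cursor: Trajectory) -> Trajectory:
    """No-delay mapping: the hand is the cursor, sample for sample."""
    return cursor.copy()


def time_model(cursor: Trajectory, tau_hat: float) -> Trajectory:
    """Time representation: hand(t) = cursor(t + tau_hat).

    The output keeps the input's length and time base; the final
    tau_hat seconds, for which no future cursor sample exists, hold the
    cursor's terminal sample (the cursor is stationary at trial end in
    every simulated task, so the hold is exact there).
    """
    if tau_hat < 0:
        raise ValueError("tau_hat must be >= 0")
    n = len(cursor)
    shift = int(round(tau_hat * cursor.rate))
    if shift >= n:
        raise ValueError(
            f"tau_hat={tau_hat} s exceeds the signal duration "
            f"({(n - 1) * cursor.dt:.3f} s)"
        )
    if shift == 0:
        return cursor.copy()
    x = np.concatenate([cursor.x[shift:], np.full(shift, cursor.x[-1])])
    y = np.concatenate([cursor.y[shift:], np.full(shift, cursor.y[-1])])
    return cursor.with_xy(x, y)


def spatial_shift_model(
    cursor: Trajectory, dx_hat: float, direction: Sequence[float]
) -> Trajectory:
    """Spatial-shift representation: hand = cursor + dx_hat * direction."""
    d = np.asarray(direction, dtype=float)
    if d.shape != (2,):
        raise ValueError("direction must be a 2-vector")
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError(f"direction must be a unit vector, |d|={np.linalg.norm(d)}")
    return cursor.with_xy(cursor.x + dx_hat * d[0], cursor.y + dx_hat * d[1])


def gain_model(
    cursor: Trajectory, g_hat: float, origin: Sequence[float]
) -> Trajectory:
    """Gain representation: hand = origin + g_hat * (cursor - origin).

    ``origin`` is the point the scaling is anchored at — the movement
    start for reaching, the path centre for tracking.
    """
    if g_hat <= 0:
        raise ValueError("g_hat must be positive")
    ox, oy = float(origin[0]), float(origin[1])
    return cursor.with_xy(ox + g_hat * (cursor.x - ox),
                          oy + g_hat * (cursor.y - oy))


def _deriv1(v: np.ndarray, dt: float) -> np.ndarray:
    """First derivative: 2nd-order central, 2nd-order one-sided at ends."""
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    d[0] = (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * dt)
    d[-1] = (3.0 * v[-1] - 4.0 * v[-2] + v[-3]) / (2.0 * dt)
    return d


def _deriv2(v: np.ndarray, dt: float) -> np.ndarray:
    """Second derivative: central 3-point, 2nd-order one-sided at ends."""
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / dt**2
    d[0] = (2.0 * v[0] - 5.0 * v[1] + 4.0 * v[2] - v[3]) / dt**2
    d[-1] = (2.0 * v[-1] - 5.0 * v[-2] + 4.0 * v[-3] - v[-4]) / dt**2
    return d


def mechanical_model(
    cursor: Trajectory, b_over_k: float, m_over_k: float
) -> Trajectory:
    """Mechanical-system representation, in its second-order Taylor form.

    hand(t) = cursor(t) + (B/K) cursor'(t) + (M/K) cursor''(t), with
    derivatives by finite differences (central in the interior,
    one-sided 2nd-order at the endpoints).
    """
    if len(cursor) < 5:
        raise ValueError("trajectory too short for finite-difference derivatives")
    if b_over_k < 0 or m_over_k < 0:
        raise ValueError("b_over_k and m_over_k must be >= 0")
    dt = cursor.dt
    x = cursor.x + b_over_k * _deriv1(cursor.x, dt) + m_over_k * _deriv2(cursor.x, dt)
    y = cursor.y + b_over_k * _deriv1(cursor.y, dt) + m_over_k * _deriv2(cursor.y, dt)
    return cursor.with_xy(x, y)


def taylor_params(tau_hat: float) -> tuple[float, float]:
    """Mechanical ratios matching a single-lag Taylor expansion.

    Expanding cursor(t + tau) to second order gives B/K = tau and
    M/K = tau^2 / 2.
    """
    if tau_hat < 0:
        raise ValueError("tau_hat must be >= 0")
    return tau_hat, tau_hat**2 / 2.0


def mechanical_amplitude_gain(omega: float | np.ndarray, tau_hat: float):
    """Amplitude ratio |hand| / |cursor| of the Taylor mechanical model.

    The transfer function at angular frequency omega is
    1 - (tau^2/2) omega^2 + j tau omega, whose modulus simplifies to
    sqrt(1 + tau^4 omega^4 / 4).  It is 1 at omega = 0 and grows
    monotonically with frequency — the signature that separates the
    mechanical model from a frequency-flat gain.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")
    out = np.sqrt(1.0 + tau_hat**4 * omega**4 / 4.0)
    return float(out) if out.ndim == 0 else out


def apply_model(
    cursor: Trajectory,
    params: RepresentationParams,
    *,
    origin: Sequence[float] | None = None,
    direction: Sequence[float] | None = None,
) -> Trajectory:
    """Map an imagined-cursor trajectory through the active representation.

    ``origin`` (gain anchor) defaults to the cursor's mean position (the
    path centre); ``direction`` (shift axis) defaults to +y, the
    sagittal axis along which paddle-ball hits occur.
    """
    v = params.variant
    if v == "none":
        return identity_map(cursor)
    if v == "time":
        return time_model(cursor, params.tau_hat)
    if v == "spatial_shift":
        d = (0.0, 1.0) if direction is None else direction
        return spatial_shift_model(cursor, params.dx_hat, d)
    if v == "gain":
        o = (float(np.mean(cursor.x)), float(np.mean(cursor.y))) if origin is None else origin
        return gain_model(cursor, params.g_hat, o)
    if v == "mechanical":
        return mechanical_model(cursor, params.b_over_k, params.m_over_k)
    raise ValueError(f"unknown variant {v!r}")
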
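"""Time-dependent segment kinematics and periodic Fourier gait models.

The discretized bell is described per frame by segment (chord) lengths
l_k and deflection angles phi_k.  Angle convention: phi_1 is the angle
of segment 1 below the body-frame horizontal (positive when the segment
points downward); for k >= 2, phi_k is the signed angle (CCW positive)
from segment k-1's direction to segment k's direction.  Forward
kinematics from the apex inverts this exactly, so extraction and
reconstruction round-trip.

Each channel over one swimming cycle is tiled nine times and fitted by
linear least squares on the trigonometric basis
{1, cos(n w t), sin(n w t)}, n = 1..order, w = 2 pi / T, giving a
T-periodic model that reproduces the gait for any number of cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .types import ValidationError

__all__ = [
    "SegmentTimeSeries",
    "FourierChannel",
    "FourierKinematicModel",
    "PhaseSegmentation",
    "chain_lengths_angles",
    "segment_kinematics",
    "clip_and_shift_cycle",
    "fit_fourier",
    "eval_fourier",
    "fit_kinematic_model",
    "reconstruct_profile",
    "detect_phases",
]


# ---------------------------------------------------------------------------
# segment geometry


def chain_lengths_angles(nodes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Chord lengths and deflection angles (degrees) of a node polyline."""
    nodes = np.asarray(nodes, dtype=float)
    d = np.diff(nodes, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    if np.any(lengths == 0.0):
        raise ValidationError("zero-length segment in node polyline")
    ang = np.arctan2(d[:, 1], d[:, 0])
    phi = np.empty(len(lengths))
    phi[0] = -np.degrees(ang[0])
    rel = np.diff(ang)
    rel = (rel + np.pi) % (2.0 * np.pi) - np.pi
    phi[1:] = np.degrees(rel)
    return lengths, phi


@dataclass
class SegmentTimeSeries:
    """Per-frame segment lengths and deflection angles over time."""

    times: np.ndarray
    lengths: np.ndarray  # (n_frames, n_segments)
    angles: np.ndarray  # degrees, unwrapped along time

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.atleast_2d(np.asarray(self.lengths, dtype=float))
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.lengths <= 0):
            raise ValidationError("segment lengths must be positive")

    @property
    def n_segments(self) -> int:
        return self.lengths.shape[1]

    def channels(self) -> Dict[str, np.ndarray]:
        out = {}
        for k in range(self.n_segments):
            out[f"l_{k + 1}"] = self.lengths[:, k]
            out[f"phi_{k + 1}"] = self.angles[:, k]
        return out


def segment_kinematics(model) -> SegmentTimeSeries:
    """Segment lengths and angles over time for a discrete bell model.

    ``model`` provides ``times`` and ``node_positions`` (frames x nodes
    x 2).  Angle channels are unwrapped over time so no +-180 deg jumps
    remain.
    """
    nodes = np.asarray(model.node_positions, dtype=float)
    if len(nodes) < 2:
        raise ValidationError("need >= 2 frames")
    lengths = np.empty((len(nodes), nodes.shape[1] - 1))
    angles = np.empty_like(lengths)
    for j, frame_nodes in enumerate(nodes):
        lengths[j], angles[j] = chain_lengths_angles(frame_nodes)
    angles = np.unwrap(angles, axis=0, period=360.0)
    return SegmentTimeSeries(times=np.asarray(model.times, float), lengths=lengths, angles=angles)


def clip_and_shift_cycle(
    series: SegmentTimeSeries, cycle_start: float, cycle_end: float
) -> SegmentTimeSeries:
    """Extract one cycle and re-originate time at contraction onset.

    Samples within [cycle_start, cycle_end) are shifted so t = 0 is the
    cycle start.  When the window spans at least the whole record (or
    lies outside it), the record is treated as one cycle of duration
    T = cycle_end - cycle_start and rotated cyclically, preserving the
    sample multiset.
    """
    if cycle_end <= cycle_start:
        raise ValidationError("cycle_end must exceed cycle_start")
    T = cycle_end - cycle_start
    t = series.times
    dt = np.median(np.diff(t)) if len(t) > 1 else 0.0
    record_T = t[-1] - t[0] + dt
    mask = (t >= cycle_start) & (t < cycle_end)
    if mask.sum() >= 2 and T < record_T - 1e-9:
        new_t = t[mask] - cycle_start
        order = np.argsort(new_t)
        sel = np.where(mask)[0][order]
        return SegmentTimeSeries(new_t[order], series.lengths[sel], series.angles[sel])
    new_t = np.mod(t - cycle_start, T)
    order = np.argsort(new_t, kind="stable")
    return SegmentTimeSeries(new_t[order], series.lengths[order], series.angles[order])


# ---------------------------------------------------------------------------
# Fourier model


@dataclass
class FourierChannel:
    """One T-periodic channel: a0 + sum a_n cos(n w t) + b_n sin(n w t)."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    T: float
    residual_rms: float = 0.0

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if len(self.a) != len(self.b) or len(self.a) < 1:
            raise ValidationError("need matching a_n, b_n arrays with order >= 1")
        if self.T <= 0:
            raise ValidationError("period must be positive")

    @property
    def order(self) -> int:
        return len(self.a)

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.T

    def __call__(self, t):
        return eval_fourier(self, t)


@dataclass
class FourierKinematicModel:
    """Named Fourier channels (segment lengths and angles) sharing T."""

    channels: Dict[str, FourierChannel]
    T: float
    order: int

    def eval(self, name: str, t):
        if name not in self.channels:
            raise ValidationError(f"missing channel {name!r}")
        return self.channels[name](t)

    @property
    def n_segments(self) -> int:
        k = 0
        while f"l_{k + 1}" in self.channels and f"phi_{k + 1}" in self.channels:
            k += 1
        return k


def _design_matrix(t: np.ndarray, T: float, order: int) -> np.ndarray:
    w = 2.0 * np.pi / T
    cols = [np.ones_like(t)]
    for n in range(1, order + 1):
        cols.append(np.cos(n * w * t))
        cols.append(np.sin(n * w * t))
    return np.column_stack(cols)


def fit_fourier(
    times: np.ndarray,
    values: np.ndarray,
    T: float,
    order: int,
    tiles: int = 9,
) -> FourierChannel:
    """Least-squares Fourier fit of one cycle, tiled ``tiles`` times.

    Tiling replicates the clipped cycle end to end before fitting, as
    one would fit a steady gait record; for an exactly periodic signal
    the coefficients equal the single-cycle fit.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) != len(y):
        raise ValidationError("times/values length mismatch")
    if len(t) < 2 * order + 1:
        raise ValidationError(
            f"need >= {2 * order + 1} samples per cycle for order {order}, got {len(t)}"
        )
    tt = np.concatenate([t + k * T for k in range(tiles)])
    yy = np.tile(y, tiles)
    X = _design_matrix(tt, T, order)
    coef, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    if rank < X.shape[1]:
        raise ValidationError("rank-deficient Fourier design; too few distinct samples")
    resid = yy - X @ coef
    return FourierChannel(
        a0=float(coef[0]),
        a=coef[1::2].copy(),
        b=coef[2::2].copy(),
        T=T,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def eval_fourier(channel: FourierChannel, t):
    """Evaluate a Fourier channel at any real time(s)."""
    t = np.asarray(t, dtype=float)
    w = channel.omega
    n = np.arange(1, channel.order + 1)
    phase = np.multiply.outer(t, n) * w
    out = channel.a0 + np.cos(phase) @ channel.a + np.sin(phase) @ channel.b
    return out if out.shape else float(out)


def fit_kinematic_model(
    series: SegmentTimeSeries, T: float, order: int = 8, tiles: int = 9
) -> FourierKinematicModel:
    """Fit every length and angle channel of a one-cycle series."""
    channels = {
        name: fit_fourier(series.times, vals, T, order, tiles)
        for name, vals in series.channels().items()
    }
    return FourierKinematicModel(channels=channels, T=T, order=order)


def reconstruct_profile(model: FourierKinematicModel, t: float) -> np.ndarray:
    """Node polyline in the body frame from the Fourier channels at time t.

    Segment 1 leaves the apex (origin) at phi_1 below horizontal; each
    later segment's direction adds its deflection phi_k.
    """
    K = model.n_segments
    if K == 0:
        raise ValidationError("model has no complete l_k/phi_k channel pairs")
    nodes = [np.zeros(2)]
    theta = 0.0
    for k in range(1, K + 1):
        l = float(model.eval(f"l_{k}", t))
        phi = float(model.eval(f"phi_{k}", t))
        theta = -np.radians(phi) if k == 1 else theta + np.radians(phi)
        nodes.append(nodes[-1] + l * np.array([np.cos(theta), np.sin(theta)]))
    return np.vstack(nodes)


# ---------------------------------------------------------------------------
# phase detection


@dataclass
class PhaseSegmentation:
    """Contraction / cruise / relaxation partition of one cycle."""

    contraction: Tuple[float, float]
    cruise: Tuple[float, float]
    relaxation: Tuple[float, float]
    period: float

    @property
    def durations(self) -> Tuple[float, float, float]:
        return (
            self.contraction[1] - self.contraction[0],
            self.cruise[1] - self.cruise[0],
            self.relaxation[1] - self.relaxation[0],
        )

    @property
    def duty_cycle_cruise_as_relaxation(self) -> float:
        """Contraction fraction of the cycle, cruise counted as relaxation (%)."""
        return 100.0 * self.durations[0] / self.period

    @property
    def duty_cycle_cruise_as_contraction(self) -> float:
        """Contraction-plus-cruise fraction of the cycle (%): the duty cycle
        when actuators are powered to hold the contracted shape."""
        return 100.0 * (self.durations[0] + self.durations[1]) / self.period

    @property
    def frequency(self) -> float:
        return 1.0 / self.period


def detect_phases(
    times: np.ndarray,
    angle: np.ndarray,
    eps: float = 0.05,
    period: Optional[float] = None,
) -> PhaseSegmentation:
    """Segment one cycle of the actively driven angle channel into phases.

    The channel must start at contraction onset.  Velocities are taken
    on sample intervals (midpoint finite differences), so a sharp
    turning point does not smear into a spurious cruise sample; a
    3-point median pass removes isolated sign flips from digitization
    noise without moving a monotone run's boundary by more than one
    interval.  Contraction is the maximal run of intervals from the
    start with inward — negative — velocity of magnitude >= ``eps``
    times the peak speed; cruise follows while |velocity| < eps * peak;
    relaxation is the remainder.  The three intervals partition the
    cycle exactly.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(angle, dtype=float)
    if len(t) < 3:
        raise ValidationError("need >= 3 samples for phase detection")
    dt = np.diff(t)
    T = period if period is not None else float(t[-1] - t[0] + np.median(dt))
    v = np.diff(y) / dt  # velocity on interval [t_k, t_k+1]
    if len(v) >= 3:
        from scipy.signal import medfilt

        inner = medfilt(v, 3)
        v = np.concatenate([[v[0]], inner[1:-1], [v[-1]]])
    peak = float(np.max(np.abs(v)))
    if peak == 0.0:
        raise ValidationError("constant angle series has no phases")
    thresh = eps * peak
    n = len(v)
    i = 0
    while i < n and v[i] < 0.0 and abs(v[i]) >= thresh:
        i += 1
    j = i
    while j < n and abs(v[j]) < thresh:
        j += 1
    t0 = float(t[0])
    t_c = float(t[i]) if i < n else t0 + T
    t_r = float(t[j]) if j < n else t0 + T
    return PhaseSegmentation(
        contraction=(t0, t_c),
        cruise=(t_c, t_r),
        relaxation=(t_r, t0 + T),
        period=T,
    )
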
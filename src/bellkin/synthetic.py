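"""Synthetic swimming scenes with known kinematics and camera corruption.

The generator builds a four-segment bell skeleton whose deflection
angles follow trapezoidal (ramp - plateau - ramp) waveforms with
per-segment lags — contraction, cruise and relaxation phases are then
exactly specifiable, mirroring the phase structure of a rowing
jellyfish with a passive lagging flap.  Segment lengths pulse with the
contraction (the exumbrella lengthens as the swimming muscles compress
the subumbrella).  Corners are rounded with circular fillets so the
smooth curve has detectable curvature extrema at the joints, and the
curve is sampled densely and uniformly in arclength.

A pinhole-style camera then corrupts the truth: monotone magnification
(the diver approaches), a residual linear scale drift (the animal
drifts relative to the camera), roll about the optical axis, and pixel
noise.  A background reference point tracks the magnification component
only, and a near-apex marker is carried on the outline — exactly the
observables the correction pipeline consumes, so every stage has a
parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .correction import correct_sequence, cumulative_arclength, polyline_arclength
from .discretize import ANATOMICAL_FRACTIONS, evaluate_model
from .kinematics import PhaseSegmentation, SegmentTimeSeries, detect_phases, segment_kinematics
from .types import (
    BodyFrame,
    DigitizedFrame,
    HalfProfile,
    ScaleSeries,
    SequenceConfig,
    ValidationError,
)

__all__ = [
    "SwimmerSpec",
    "CameraSpec",
    "SyntheticScene",
    "trapezoid_wave",
    "generate_true_profiles",
    "apply_camera",
    "make_scene",
    "recovery_report",
]


def trapezoid_wave(t, contraction: float, cruise: float, relaxation: float):
    """Periodic activation waveform: 0 relaxed, ramp to 1, hold, ramp back.

    One period is contraction + cruise + relaxation; the wave starts at
    contraction onset (value 0, rising).
    """
    T = contraction + cruise + relaxation
    u = np.mod(np.asarray(t, dtype=float), T)
    w = np.where(
        u < contraction,
        u / contraction,
        np.where(u < contraction + cruise, 1.0, (T - u) / relaxation),
    )
    return w


@dataclass
class SwimmerSpec:
    """Ground-truth bell kinematics.

    Node fractions are % of the unit relaxed half arclength; rest
    lengths default to the fraction gaps so the relaxed half arclength
    is exactly 1.  Angles are the deflection channels of the segment
    chain (first below horizontal, later ones relative, CCW positive);
    each follows rest + amplitude * trapezoid(t - lag).
    """

    node_fractions: Tuple[float, ...] = ANATOMICAL_FRACTIONS
    rest_angles_deg: Tuple[float, ...] = (5.0, -10.0, -10.0, -8.0)
    amplitudes_deg: Tuple[float, ...] = (12.0, -28.0, -14.0, -22.0)
    lags_s: Tuple[float, ...] = (0.0, 0.0, 0.6, 0.9)
    contraction_s: float = 2.0
    cruise_s: float = 1.0
    relaxation_s: float = 2.4
    arclength_pulsation: float = 0.05
    rounding_radius: float = 0.04
    asymmetry: float = 0.0  # fractional amplitude difference of the left side

    def __post_init__(self):
        k = len(self.node_fractions) - 1
        if not (len(self.rest_angles_deg) == len(self.amplitudes_deg) == len(self.lags_s) == k):
            raise ValidationError("per-segment fields must match the node count minus one")
        if min(self.contraction_s, self.cruise_s, self.relaxation_s) < 0 or (
            self.contraction_s <= 0 or self.relaxation_s <= 0
        ):
            raise ValidationError("contraction and relaxation must be positive, cruise >= 0")
        if self.rounding_radius < 0:
            raise ValidationError("rounding radius must be >= 0")
        rest = self.rest_lengths
        if np.any(rest <= 0):
            raise ValidationError("node fractions must increase")
        if self.rounding_radius >= rest.min() / 2.0:
            raise ValidationError("rounding radius must be < shortest rest segment / 2")

    @property
    def period(self) -> float:
        return self.contraction_s + self.cruise_s + self.relaxation_s

    @property
    def rest_lengths(self) -> np.ndarray:
        return np.diff(np.asarray(self.node_fractions, dtype=float)) / 100.0

    def phase_segmentation(self) -> PhaseSegmentation:
        T = self.period
        tc = self.contraction_s
        tr = tc + self.cruise_s
        return PhaseSegmentation(
            contraction=(0.0, tc), cruise=(tc, tr), relaxation=(tr, T), period=T
        )

    def angles_at(self, t: float, side: str = "right") -> np.ndarray:
        amp = np.asarray(self.amplitudes_deg, dtype=float)
        if side == "left":
            amp = amp * (1.0 + self.asymmetry)
        w = np.array(
            [
                trapezoid_wave(t - lag, self.contraction_s, self.cruise_s, self.relaxation_s)
                for lag in self.lags_s
            ]
        )
        return np.asarray(self.rest_angles_deg, dtype=float) + amp * w

    def lengths_at(self, t: float) -> np.ndarray:
        w = trapezoid_wave(t, self.contraction_s, self.cruise_s, self.relaxation_s)
        return self.rest_lengths * (1.0 + self.arclength_pulsation * float(w))


def _skeleton_nodes(lengths: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
    nodes = [np.zeros(2)]
    theta = 0.0
    for k, (l, phi) in enumerate(zip(lengths, phi_deg)):
        theta = -np.radians(phi) if k == 0 else theta + np.radians(phi)
        nodes.append(nodes[-1] + l * np.array([np.cos(theta), np.sin(theta)]))
    return np.vstack(nodes)


def _rounded_curve(nodes: np.ndarray, radius: float, pts_per_unit: int = 400) -> np.ndarray:
    """Polyline along the skeleton with circular fillets at interior nodes."""
    d = np.diff(nodes, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    units = d / lengths[:, None]
    pieces: List[np.ndarray] = []
    cursor = nodes[0]
    for k in range(len(lengths)):
        if k < len(lengths) - 1 and radius > 0:
            u0, u1 = units[k], units[k + 1]
            turn = np.arctan2(
                u0[0] * u1[1] - u0[1] * u1[0], float(np.dot(u0, u1))
            )
            tan_off = radius * np.tan(abs(turn) / 2.0)
            start = nodes[k + 1] - tan_off * u0
            end = nodes[k + 1] + tan_off * u1
            seg = np.linspace(cursor, start, max(2, int(np.hypot(*(start - cursor)) * pts_per_unit)))
            pieces.append(seg[:-1])
            if abs(turn) > 1e-12:
                normal = np.array([-u0[1], u0[0]]) * np.sign(turn)
                center = start + radius * normal
                a0 = np.arctan2(*(start - center)[::-1])
                arc_n = max(6, int(abs(turn) * radius * pts_per_unit) + 2)
                angs = a0 + np.linspace(0.0, turn, arc_n)
                arc = center + radius * np.column_stack([np.cos(angs), np.sin(angs)])
                pieces.append(arc[:-1])
            cursor = end
        else:
            seg = np.linspace(cursor, nodes[k + 1], max(2, int(lengths[k] * pts_per_unit)))
            pieces.append(seg)
            cursor = nodes[k + 1]
    return np.vstack(pieces)


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    s = cumulative_arclength(pts)
    targets = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])])


def generate_true_profiles(
    spec: SwimmerSpec,
    times: Sequence[float],
    n_points: int = 201,
) -> Tuple[List[HalfProfile], SegmentTimeSeries]:
    """Ground-truth half profiles and the planted segment kinematics.

    For each time, the segment chain is posed from the lagged angle
    waveforms, segment lengths are scaled by the arclength pulsation,
    corners are rounded and the smooth curve resampled to ``n_points``
    uniform in arclength.  The returned series holds the skeleton's
    exact lengths and deflection angles (right side).
    """
    times = np.asarray(times, dtype=float)
    halves: List[HalfProfile] = []
    lengths_t = np.empty((len(times), len(spec.rest_lengths)))
    angles_t = np.empty_like(lengths_t)
    for j, t in enumerate(times):
        lengths = spec.lengths_at(t)
        lengths_t[j] = lengths
        for side in ("right", "left"):
            phi = spec.angles_at(t, side)
            if side == "right":
                angles_t[j] = phi
            nodes = _skeleton_nodes(lengths, phi)
            curve = _resample_polyline(
                _rounded_curve(nodes, spec.rounding_radius), n_points
            )
            if side == "left":
                curve = curve * np.array([-1.0, 1.0])
            halves.append(
                HalfProfile(time=float(t), side=side, points=curve, frame_index=j + 1)
            )
    truth = SegmentTimeSeries(times=times, lengths=lengths_t, angles=angles_t)
    return halves, truth


# ---------------------------------------------------------------------------
# camera model


@dataclass
class CameraSpec:
    """Hand-held camera artifacts applied to the true profiles.

    Magnification m(t) = zoom(t) * drift(t): the zoom ramps linearly to
    ``zoom_total`` over the record (the camera approaching) and is what
    the background reference point sees; drift(t) = 1 + drift_rate * t
    is the residual scale change from the animal moving relative to the
    camera, invisible to the reference.  Roll is a sinusoid of
    ``roll_amplitude_deg`` (or a linear ramp when no period is given).
    """

    zoom_total: float = 1.0
    drift_rate: float = 0.0  # 1 / s
    roll_amplitude_deg: float = 0.0
    roll_period_s: Optional[float] = None
    noise_sd: float = 0.0  # pixels
    pixels_per_unit: float = 150.0
    frame_center: Tuple[float, float] = (320.0, 180.0)
    frame_width: float = 640.0
    reference_x0: float = 80.0
    reference_y: float = 40.0
    marker_arclength_offset: float = 0.08  # body units along the right half
    n_digitized: int = 121

    def __post_init__(self):
        if self.zoom_total <= 0 or self.pixels_per_unit <= 0:
            raise ValidationError("zoom and pixel scale must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def zoom(self, t, t_end: float):
        frac = np.asarray(t, dtype=float) / t_end if t_end > 0 else 0.0
        return 1.0 + (self.zoom_total - 1.0) * frac

    def drift(self, t):
        return 1.0 + self.drift_rate * np.asarray(t, dtype=float)

    def magnification(self, t, t_end: float):
        m = self.zoom(t, t_end) * self.drift(t)
        if np.any(np.asarray(m) <= 0):
            raise ValidationError("magnification must stay positive")
        return m

    def roll_deg(self, t, t_end: float):
        t = np.asarray(t, dtype=float)
        if self.roll_period_s:
            return self.roll_amplitude_deg * np.sin(2.0 * np.pi * t / self.roll_period_s)
        return self.roll_amplitude_deg * (t / t_end if t_end > 0 else 0.0)


@dataclass
class SyntheticScene:
    """A corrupted scene plus everything needed to score a recovery."""

    times: np.ndarray
    frames: List[DigitizedFrame]
    true_halves: List[HalfProfile]
    truth: SegmentTimeSeries
    true_magnification: np.ndarray
    true_roll_deg: np.ndarray
    phases: PhaseSegmentation
    spec: SwimmerSpec
    camera: CameraSpec
    config: SequenceConfig
    reference_truncated: bool = False


def apply_camera(
    true_halves: Sequence[HalfProfile],
    camera: CameraSpec,
    spec: SwimmerSpec,
    seed: int = 0,
    config: Optional[SequenceConfig] = None,
) -> SyntheticScene:
    """Project true profiles through the camera into digitized frames.

    Each frame's full outline (left margin to right margin) is sampled
    to ``camera.n_digitized`` points, scaled about the frame center by
    m(t), rolled about the image of the apex (which the camera keeps at
    the frame center) and jittered with Gaussian pixel noise.  The
    reference and marker tracks are placed consistently with the scale
    and roll models.
    """
    rng = np.random.default_rng(seed)
    by_frame: Dict[int, Dict[str, HalfProfile]] = {}
    for h in true_halves:
        by_frame.setdefault(h.frame_index, {})[h.side] = h
    indices = sorted(by_frame)
    times = np.array([by_frame[i]["right"].time for i in indices])
    t_end = float(times[-1]) if len(times) > 1 else 1.0

    if config is None:
        config = SequenceConfig(y_down=False)
    cx, cy = camera.frame_center
    ppu = camera.pixels_per_unit
    mags = np.asarray(camera.magnification(times, t_end), dtype=float)
    rolls = np.asarray(camera.roll_deg(times, t_end), dtype=float)

    frames: List[DigitizedFrame] = []
    truncated = False
    for j, idx in enumerate(indices):
        left = by_frame[idx]["left"].points
        right = by_frame[idx]["right"].points
        outline = np.vstack([left[::-1], right[1:]])
        outline = _resample_polyline(outline, camera.n_digitized)
        s_right = cumulative_arclength(right)
        marker_body, _ = _interp_at_s(right, s_right, camera.marker_arclength_offset)

        th = np.radians(rolls[j])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m = mags[j]

        def project(p):
            return np.array([cx, cy]) + m * ppu * (np.atleast_2d(p) @ rot.T)

        pix = project(outline) + rng.normal(0.0, camera.noise_sd, (len(outline), 2))
        marker = project(marker_body)[0] + rng.normal(0.0, camera.noise_sd, 2)
        ref_x = cx + (camera.reference_x0 - cx) * float(camera.zoom(times[j], t_end))
        if not (0.0 <= ref_x <= camera.frame_width):
            truncated = True
        ref = np.array([ref_x, camera.reference_y]) + rng.normal(0.0, camera.noise_sd, 2)
        frames.append(
            DigitizedFrame(
                frame_index=idx,
                time=float(times[j]),
                points=pix,
                reference_xy=ref,
                marker_xy=marker,
            )
        )
    if truncated:
        import logging

        logging.getLogger(__name__).warning("reference point left the configured frame width")

    T = spec.period
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    contracted = []
    t_cont = spec.contraction_s + spec.cruise_s
    k = 0
    while k * T + t_cont <= times[-1] + 1e-9:
        contracted.append(int(round((k * T + t_cont) / dt)) + indices[0])
        k += 1
    config = config.replace(
        contracted_frames=tuple(contracted),
        apex_offset=camera.marker_arclength_offset * ppu,
        apex_offset_sign=-1,
        frame_center_x=cx,
        y_down=False,
        relaxed_frame=indices[0],
    )
    truth = SegmentTimeSeries(
        times=times,
        lengths=np.array([spec.lengths_at(t) for t in times]),
        angles=np.array([spec.angles_at(t) for t in times]),
    )
    return SyntheticScene(
        times=times,
        frames=frames,
        true_halves=list(true_halves),
        truth=truth,
        true_magnification=mags,
        true_roll_deg=rolls,
        phases=spec.phase_segmentation(),
        spec=spec,
        camera=camera,
        config=config,
        reference_truncated=truncated,
    )


def _interp_at_s(pts: np.ndarray, s: np.ndarray, target: float) -> Tuple[np.ndarray, int]:
    target = float(np.clip(target, 0.0, s[-1]))
    k = min(int(np.searchsorted(s, target, side="right") - 1), len(pts) - 2)
    seg = s[k + 1] - s[k]
    u = 0.0 if seg == 0.0 else (target - s[k]) / seg
    return pts[k] + u * (pts[k + 1] - pts[k]), k


def make_scene(
    spec: Optional[SwimmerSpec] = None,
    camera: Optional[CameraSpec] = None,
    n_cycles: int = 2,
    dt: float = 0.2,
    seed: int = 0,
) -> SyntheticScene:
    """Convenience: generate truth for ``n_cycles`` and apply the camera."""
    spec = spec or SwimmerSpec()
    camera = camera or CameraSpec()
    times = np.arange(0.0, n_cycles * spec.period + dt / 2.0, dt)
    halves, _ = generate_true_profiles(spec, times)
    return apply_camera(halves, camera, spec, seed=seed)


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_report(
    scene: SyntheticScene,
    halves: Sequence[HalfProfile],
    scales: ScaleSeries,
    body_frames: Sequence[BodyFrame],
) -> Dict[str, float]:
    """Score a pipeline run against the scene's ground truth.

    Returns recovery errors for the scale series, the roll angle, the
    contracted-instant arclengths, the two-cycle margin-trajectory
    overlay, the anatomical segment-angle channels and the phase
    durations.  All positional quantities are in normalized half-
    arclength units; angles in degrees; durations in seconds.
    """
    report: Dict[str, float] = {}
    required = 1.0 / scene.true_magnification
    est = scales.s_total
    report["scale_rms_pct"] = 100.0 * float(
        np.sqrt(np.mean((est / required - 1.0) ** 2))
    )
    est_roll = np.degrees([bf.theta for bf in body_frames])
    err_roll = est_roll - scene.true_roll_deg
    report["roll_rms_deg"] = float(np.sqrt(np.mean(err_roll**2)))
    report["roll_max_deg"] = float(np.max(np.abs(err_roll)))

    totals: Dict[int, float] = {}
    for h in halves:
        totals[h.frame_index] = totals.get(h.frame_index, 0.0) + h.arclength
    contracted_L = np.array([totals[f] for f in scene.config.contracted_frames])
    report["contracted_arclength_cv_pct"] = 100.0 * float(
        np.std(contracted_L) / np.mean(contracted_L)
    )

    T = scene.spec.period
    dtm = float(np.median(np.diff(scene.times)))
    per_cycle = int(round(T / dtm))
    margins: Dict[str, Dict[int, np.ndarray]] = {"left": {}, "right": {}}
    for h in halves:
        margins[h.side][h.frame_index] = h.points[-1]
    d = []
    first = scene.frames[0].frame_index
    for side in ("left", "right"):
        for j in range(per_cycle):
            a = margins[side].get(first + j)
            b = margins[side].get(first + j + per_cycle)
            if a is not None and b is not None:
                d.append(np.hypot(*(a - b)))
    if d:
        report["margin_overlay_pct"] = 100.0 * float(np.mean(d))

    rights = [h for h in halves if h.side == "right"]
    model = evaluate_model(rights, scene.spec.node_fractions)
    series = segment_kinematics(model)
    ang_err = series.angles - scene.truth.angles
    report["angle_rms_deg"] = float(np.sqrt(np.mean(ang_err**2)))
    len_err = series.lengths - scene.truth.lengths
    report["length_rms"] = float(np.sqrt(np.mean(len_err**2)))

    drive = series.angles[:, 1]  # circular-muscle channel
    one_cycle = series.times < T - dtm / 2.0
    ph = detect_phases(series.times[one_cycle], drive[one_cycle], period=T)
    truth_ph = scene.phases
    for name, k in (("contraction", 0), ("cruise", 1), ("relaxation", 2)):
        report[f"{name}_error_s"] = abs(ph.durations[k] - truth_ph.durations[k])
    return report


def run_pipeline(scene: SyntheticScene):
    """Correct a scene's frames with its own configuration."""
    return correct_sequence(scene.frames, scene.config)
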
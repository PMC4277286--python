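"""Derived biomechanics: node looping, margin excursion, subumbrella volume.

The subumbrella water volume is approximated by revolving the body-frame
exumbrella profile about the axial axis, between the profile and the
horizontal line through its minimum y.  The revolution integral is
evaluated as the boundary line integral V = | pi * closed-integral of
x^2 dy |, which stays valid when the profile is multi-valued in y (the
margin can travel above the apex during deep relaxation, where a disk
stack would break).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .correction import polyline_arclength
from .kinematics import PhaseSegmentation
from .types import HalfProfile, ValidationError

__all__ = [
    "TrajectoryLoop",
    "VolumeSeries",
    "node_trajectories",
    "margin_excursion",
    "subumbrella_volume",
    "volume_series",
]


@dataclass
class TrajectoryLoop:
    """Closed trajectory of one node over a cycle and its hysteresis loop."""

    node_fraction: float  # % of half arclength
    path: np.ndarray  # (n_frames, 2), implicitly closed
    area: float  # signed shoelace area of the closed path
    orientation: Optional[str] = None  # 'outer-on-contraction' | 'inner-on-contraction'


@dataclass
class VolumeSeries:
    """Subumbrella volume and bell width over time (normalized units)."""

    times: np.ndarray
    volume: np.ndarray  # normalized length^3
    diameter: np.ndarray  # 2 * |margin x|
    radius: np.ndarray  # |margin x|
    y_min: np.ndarray


def _shoelace(path: np.ndarray) -> float:
    x, y = path[:, 0], path[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def node_trajectories(
    model,
    phases: Optional[PhaseSegmentation] = None,
    area_tol: float = 1e-12,
) -> List[TrajectoryLoop]:
    """Per-node closed trajectories with signed loop areas.

    The loop area quantifies hysteresis between the contraction and
    relaxation paths of each node; zero area means the node retraces
    itself.  When a phase segmentation is supplied, the orientation is
    labelled by comparing each node's mean distance from the apex during
    contraction against relaxation ('outer-on-contraction' when the
    contraction path lies outside).
    """
    nodes = np.asarray(model.node_positions, dtype=float)
    times = np.asarray(model.times, dtype=float)
    if len(nodes) < 3:
        raise ValidationError("need >= 3 frames for a trajectory loop")
    loops: List[TrajectoryLoop] = []
    fractions = np.asarray(model.node_fractions, dtype=float)
    for k, frac in enumerate(fractions):
        path = nodes[:, k, :]
        area = _shoelace(path)
        orientation = None
        if phases is not None and abs(area) > area_tol:
            r = np.hypot(path[:, 0], path[:, 1])
            t_rel = np.mod(times - times[0], phases.period)
            in_contraction = t_rel < (phases.contraction[1] - phases.contraction[0])
            in_relaxation = t_rel >= (phases.relaxation[0] - phases.contraction[0])
            if in_contraction.any() and in_relaxation.any():
                orientation = (
                    "outer-on-contraction"
                    if r[in_contraction].mean() > r[in_relaxation].mean()
                    else "inner-on-contraction"
                )
        loops.append(
            TrajectoryLoop(node_fraction=float(frac), path=path, area=area, orientation=orientation)
        )
    return loops


def margin_excursion(
    profiles: Sequence[HalfProfile],
    relaxed_times: Sequence[float],
    contracted_times: Sequence[float],
    atol: float = 1e-9,
) -> Tuple[float, float]:
    """Mean absolute margin displacement between relaxed and contracted bells.

    For each relaxed/contracted instant pair and each side, the margin
    (last profile point) displacement is taken per axis; the absolute
    values are averaged over sides and cycle pairs, giving
    (delta_x, delta_y) in normalized units.
    """
    if not relaxed_times or not contracted_times:
        raise ValidationError("need at least one relaxed and one contracted instant")
    by_time_side: Dict[Tuple[float, str], HalfProfile] = {}
    for p in profiles:
        by_time_side[(round(p.time, 9), p.side)] = p

    def margin(t: float, side: str) -> np.ndarray:
        key = (round(t, 9), side)
        if key not in by_time_side:
            raise ValidationError(f"no {side} profile at t = {t}")
        return by_time_side[key].points[-1]

    dx, dy = [], []
    for t_r, t_c in zip(relaxed_times, contracted_times):
        for side in ("left", "right"):
            m_r = margin(t_r, side)
            m_c = margin(t_c, side)
            dx.append(abs(m_r[0] - m_c[0]))
            dy.append(abs(m_r[1] - m_c[1]))
    return float(np.mean(dx)), float(np.mean(dy))


def subumbrella_volume(half: HalfProfile, axis_tol: float = 1e-3) -> float:
    """Solid-of-revolution volume enclosed below the exumbrella profile.

    The region bounded by the profile, the rotation (apex) axis and the
    horizontal line y = y_min is revolved about the axis:
    V = | pi * closed-integral x^2 dy | over the closed boundary.  The
    closing edges along the axis and along y = y_min contribute nothing,
    so only the profile and the margin drop to y_min enter.  The profile
    must stay on one side of the axis to within ``axis_tol`` of its
    arclength.
    """
    pts = np.asarray(half.points, dtype=float)
    L = polyline_arclength(pts)
    x = pts[:, 0].copy()
    sign = np.sign(np.mean(x)) or 1.0
    x = x * sign
    if np.min(x) < -axis_tol * L:
        raise ValidationError("profile crosses the rotation axis beyond tolerance")
    y = pts[:, 1]
    y_min = float(np.min(y))

    def edge(x1, y1, x2, y2):
        return (y2 - y1) * (x1 * x1 + x1 * x2 + x2 * x2) / 3.0

    total = np.sum(edge(x[:-1], y[:-1], x[1:], y[1:]))
    total += edge(x[-1], y[-1], x[-1], y_min)  # margin drop to the y_min line
    return float(abs(np.pi * total))


def volume_series(profiles: Sequence[HalfProfile]) -> VolumeSeries:
    """Subumbrella volume and bell width over time.

    Left and right half volumes are averaged per frame; the diameter is
    twice the margin |x| of the analyzed halves (also averaged).
    """
    by_time: Dict[float, List[HalfProfile]] = {}
    for p in profiles:
        by_time.setdefault(round(p.time, 9), []).append(p)
    times = np.array(sorted(by_time))
    vol = np.empty(len(times))
    rad = np.empty(len(times))
    ymin = np.empty(len(times))
    for j, t in enumerate(times):
        group = by_time[t]
        vol[j] = float(np.mean([subumbrella_volume(p) for p in group]))
        rad[j] = float(np.mean([abs(p.points[-1, 0]) for p in group]))
        ymin[j] = float(np.min([p.points[:, 1].min() for p in group]))
    return VolumeSeries(times=times, volume=vol, diameter=2.0 * rad, radius=rad, y_min=ymin)
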
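"""Scale, rotation and sampling correction of digitized bell outlines.

The pipeline turns raw margin-to-margin outline digitizations of a
freely swimming jellyfish, filmed hand-held in open water, into
apex-rooted half profiles in the animal's body frame at a constant
scale:

1. reference-point magnification correction (the background landmark
   tracks the camera's approach; distances from the frame center scale
   with magnification),
2. arclength linear-fit correction (the bell is assumed to return to
   the same exumbrella length at every full contraction; a linear fit
   through the contracted-instant arclengths removes the residual drift
   of the animal relative to the camera),
3. apex location from a near-apex marker plus a fixed arclength offset,
   and splitting into left/right half profiles,
4. body-roll estimation from a least-squares line through the
   low-deformation region around the apex, and rotation into the body
   frame,
5. zero-phase Butterworth smoothing of the polar radius about the apex,
6. cubic-spline resampling to a fixed number of points uniform in
   arclength, and normalization by the relaxed half arclength.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .types import (
    BodyFrame,
    DigitizedFrame,
    HalfProfile,
    ScaleSeries,
    SequenceConfig,
    ValidationError,
)

__all__ = [
    "polyline_arclength",
    "cumulative_arclength",
    "reference_scale",
    "apply_scale",
    "arclength_lf_scale",
    "locate_apex",
    "body_angle",
    "to_body_frame",
    "smooth_half_profile",
    "resample_half_profile",
    "correct_sequence",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# arclength primitives


def polyline_arclength(points) -> float:
    """Total chord-sum arclength of an ordered point list.

    A single point has zero length; an empty list is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValidationError("cannot compute arclength of an empty point list")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected (N, 2) points, got shape {pts.shape}")
    if len(pts) == 1:
        return 0.0
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def cumulative_arclength(points) -> np.ndarray:
    """Cumulative chord-sum arclength, starting at 0 for the first point."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


# ---------------------------------------------------------------------------
# magnification


def reference_scale(
    frames: Sequence[DigitizedFrame],
    frame_center_x: float,
    eps: float = 1e-6,
) -> ScaleSeries:
    """Magnification correction from the background reference point.

    As the camera approaches, the reference landmark moves away from the
    frame center in proportion to the magnification.  With the animal
    kept centered, s_ref(j) = |x_r(1) - x_c| / |x_r(j) - x_c| restores
    frame-1 scale when frame-j coordinates are multiplied by it about
    the frame center.  s_ref(first frame) = 1 by construction.
    """
    d = []
    for fr in frames:
        if fr.reference_xy is None:
            raise ValidationError(f"frame {fr.frame_index}: missing reference point")
        dist = abs(fr.reference_xy[0] - frame_center_x)
        if dist < eps:
            raise ValidationError(
                f"frame {fr.frame_index}: reference point at the frame center; "
                "magnification scale is undefined"
            )
        d.append(dist)
    d = np.asarray(d)
    s_ref = d[0] / d
    idx = np.array([fr.frame_index for fr in frames])
    return ScaleSeries(idx, s_ref, np.ones_like(s_ref))


def apply_scale(
    frames: Sequence[DigitizedFrame],
    scales: np.ndarray,
    center: Tuple[float, float],
) -> List[DigitizedFrame]:
    """Scale each frame's points (and marker) about ``center``.

    The scaling center only shifts the result rigidly, and the later
    apex-rooting removes any translation, so the y-component of the
    center is immaterial; the x-component matches the reference model.
    """
    c = np.asarray(center, dtype=float)
    out = []
    for fr, s in zip(frames, scales):
        marker = None if fr.marker_xy is None else c + s * (fr.marker_xy - c)
        ref = None if fr.reference_xy is None else c + s * (fr.reference_xy - c)
        out.append(
            DigitizedFrame(
                frame_index=fr.frame_index,
                time=fr.time,
                points=c + s * (fr.points - c),
                reference_xy=ref,
                marker_xy=marker,
            )
        )
    return out


def arclength_lf_scale(
    frames: Sequence[DigitizedFrame],
    contracted_frames: Sequence[int],
) -> ScaleSeries:
    """Residual-drift correction from contracted-instant arclengths.

    Straight swimming is cyclical, so the exumbrella returns to the same
    length at every full contraction.  A least-squares line
    L(t) = alpha + beta t through the contracted-instant arclengths of
    the (already reference-corrected) outlines captures the remaining
    linear scale drift; s_lf(j) = L_fit(t_1) / L_fit(t_j) removes it.
    """
    contracted = sorted(set(int(f) for f in contracted_frames))
    if len(contracted) < 2:
        raise ValidationError("need >= 2 contracted frames for the linear-fit scale")
    by_index = {fr.frame_index: fr for fr in frames}
    missing = [f for f in contracted if f not in by_index]
    if missing:
        raise ValidationError(f"contracted frames {missing} not present in sequence")
    t_c = np.array([by_index[f].time for f in contracted])
    L_c = np.array([polyline_arclength(by_index[f].points) for f in contracted])
    beta, alpha = np.polyfit(t_c, L_c, 1)
    times = np.array([fr.time for fr in frames])
    L_fit = alpha + beta * times
    if np.any(L_fit <= 0):
        raise ValidationError("linear fit implies non-positive arclength in sequence")
    s_lf = L_fit[0] / L_fit
    idx = np.array([fr.frame_index for fr in frames])
    return ScaleSeries(idx, np.ones_like(s_lf), s_lf)


# ---------------------------------------------------------------------------
# apex location and profile splitting


def _project_on_polyline(points: np.ndarray, p: np.ndarray) -> Tuple[float, float]:
    """Arclength position and distance of the closest point on a polyline."""
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.hypot(*(proj - p).T)
    k = int(np.argmin(dist))
    s = cumulative_arclength(points)
    seg_len = np.hypot(*ab[k])
    return float(s[k] + t[k] * seg_len), float(dist[k])


def _point_at_arclength(points: np.ndarray, s_target: float) -> Tuple[np.ndarray, int]:
    """Point at arclength position ``s_target`` and index of the segment it lies on."""
    s = cumulative_arclength(points)
    s_target = float(np.clip(s_target, 0.0, s[-1]))
    k = int(np.searchsorted(s, s_target, side="right") - 1)
    k = min(k, len(points) - 2)
    seg = s[k + 1] - s[k]
    u = 0.0 if seg == 0.0 else (s_target - s[k]) / seg
    return points[k] + u * (points[k + 1] - points[k]), k


def locate_apex(
    frame: DigitizedFrame,
    marker_xy: Optional[np.ndarray] = None,
    apex_offset: float = 0.0,
    offset_sign: int = 1,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate the bell apex and split the outline into two half profiles.

    The apex is the outline point at the arclength position of the
    marker's closest outline point, shifted by ``apex_offset`` along the
    outline (direction from ``offset_sign``).  Returns
    ``(apex_xy, half_a, half_b)`` where both halves are rooted at the
    apex (the apex is inserted as their first vertex) and ordered apex
    to margin; ``half_a`` covers the low-point-index side.
    """
    pts = frame.points
    marker = frame.marker_xy if marker_xy is None else np.asarray(marker_xy, float)
    if marker is None:
        raise ValidationError(f"frame {frame.frame_index}: no marker available")
    L = polyline_arclength(pts)
    s_marker, dist = _project_on_polyline(pts, marker)
    tol = max(2.0 * abs(apex_offset), 0.05 * L)
    if dist > tol:
        raise ValidationError(
            f"frame {frame.frame_index}: marker {dist:.3g} from outline, "
            f"tolerance {tol:.3g}"
        )
    s_apex = s_marker + offset_sign * apex_offset
    if not (0.0 < s_apex < L):
        raise ValidationError(
            f"frame {frame.frame_index}: apex arclength {s_apex:.3g} outside outline (0, {L:.3g})"
        )
    apex, k = _point_at_arclength(pts, s_apex)
    before = pts[: k + 1]
    after = pts[k + 1 :]
    if np.allclose(apex, pts[k]):
        before = pts[:k]
    if len(after) and np.allclose(apex, after[0]):
        after = after[1:]
    half_a = np.vstack([apex, before[::-1]])
    half_b = np.vstack([apex, after])
    if len(half_a) < 3 or len(half_b) < 3:
        raise ValidationError(
            f"frame {frame.frame_index}: apex too close to an outline end to split"
        )
    return apex, half_a, half_b


# ---------------------------------------------------------------------------
# body rotation


def body_angle(
    half_a: np.ndarray,
    half_b: np.ndarray,
    apex_xy,
    top_fraction: float = 0.24,
) -> BodyFrame:
    """Roll angle from a least-squares line through the near-apex region.

    The bell deforms least near the apex, so points within
    ``top_fraction`` of each half's arclength from the apex trace the
    body's horizontal.  The ordinary least-squares slope m through those
    points (about their mean) gives theta = arctan(m).
    """
    sel = []
    for half in (half_a, half_b):
        s = cumulative_arclength(half)
        sel.append(half[s <= top_fraction * s[-1]])
    pts = np.vstack(sel)
    if len(pts) < 2:
        raise ValidationError("fewer than 2 points in the top-region fit window")
    x = pts[:, 0]
    y = pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx < 1e-12 * max(1.0, float(np.sum((y - y.mean()) ** 2))):
        raise ValidationError("top-region points are vertically collinear; slope undefined")
    m = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    c = float(y.mean() - m * x.mean())
    return BodyFrame(
        theta=float(np.arctan(m)),
        apex_xy=np.asarray(apex_xy, dtype=float),
        slope=m,
        intercept=c,
        n_points=len(pts),
    )


def to_body_frame(points, frame: BodyFrame) -> np.ndarray:
    """Translate the apex to the origin and rotate by -theta.

    Active rotation convention: with theta = 90 deg, the point (1, 0)
    relative to the apex maps to (0, -1).  The map is an isometry.
    """
    p = np.asarray(points, dtype=float) - frame.apex_xy
    c, s = np.cos(frame.theta), np.sin(frame.theta)
    rot = np.array([[c, s], [-s, c]])
    return p @ rot.T


# ---------------------------------------------------------------------------
# smoothing and resampling


def smooth_half_profile(half: HalfProfile, cutoff_fraction: float = 0.20) -> HalfProfile:
    """Zero-phase Butterworth smoothing of the polar radius about the apex.

    The profile is converted to polar coordinates about the apex (the
    bell's curvature makes Cartesian filtering along x ill-posed, and
    during deep relaxation the margin can travel over the apex, so the
    radius is filtered against the sample index rather than the
    geometric angle).  A second-order Butterworth low-pass at
    ``cutoff_fraction`` of the Nyquist frequency is applied
    forward-backward so the margin is not shifted in arclength; both
    endpoints are retained exactly.
    """
    n = half.n
    if n < 9:
        raise ValidationError(f"need >= 9 points to filter, got {n}")
    apex = half.points[0]
    rel = half.points[1:] - apex  # the apex itself has r = 0 and stays fixed
    r = np.hypot(rel[:, 0], rel[:, 1])
    alpha = np.arctan2(rel[:, 1], rel[:, 0])
    b, a = butter(2, cutoff_fraction)
    padlen = min(3 * max(len(a), len(b)), len(r) - 2)
    r_f = filtfilt(b, a, r, padlen=padlen)
    pts = np.vstack(
        [apex, apex + np.column_stack([r_f * np.cos(alpha), r_f * np.sin(alpha)])]
    )
    pts[-1] = half.points[-1]
    return HalfProfile(time=half.time, side=half.side, points=pts, frame_index=half.frame_index)


def resample_half_profile(half: HalfProfile, n: int = 51) -> HalfProfile:
    """Resample to ``n`` points at uniform fractions of cumulative arclength.

    A cubic spline parameterized by cumulative chord arclength is fitted
    to each coordinate and evaluated at arclength fractions k/(n-1).
    Endpoints are preserved exactly.  Uniform resampling assumes the
    exumbrella deforms equally along its arclength, so a fixed sample
    index addresses the same material point over time.
    """
    if n < 3:
        raise ValidationError("resample_n must be >= 3")
    pts = half.points
    if len(pts) < 4:
        raise ValidationError("need >= 4 points for cubic-spline resampling")
    s = cumulative_arclength(pts)
    keep = np.concatenate([[True], np.diff(s) > 0])
    s, pts = s[keep], pts[keep]
    if len(pts) < 4:
        raise ValidationError("too few distinct points for cubic-spline resampling")
    cs_x = CubicSpline(s, pts[:, 0])
    cs_y = CubicSpline(s, pts[:, 1])
    targets = np.linspace(0.0, s[-1], n)
    out = np.column_stack([cs_x(targets), cs_y(targets)])
    out[0] = half.points[0]
    out[-1] = half.points[-1]
    return HalfProfile(time=half.time, side=half.side, points=out, frame_index=half.frame_index)


# ---------------------------------------------------------------------------
# full pipeline


def _scale_series_identity(frames: Sequence[DigitizedFrame]) -> ScaleSeries:
    idx = np.array([fr.frame_index for fr in frames])
    ones = np.ones(len(frames))
    return ScaleSeries(idx, ones.copy(), ones.copy())


def correct_sequence(
    frames: Sequence[DigitizedFrame],
    config: SequenceConfig,
) -> Tuple[List[HalfProfile], ScaleSeries, List[BodyFrame]]:
    """Run the full correction pipeline on a digitized sequence.

    Returns the corrected, smoothed, resampled and normalized half
    profiles (left and right per frame), the combined scale series and
    the per-frame body frames.  If the reference track or the frame
    center is missing, the reference scale degrades to 1 with a logged
    warning and only the arclength linear fit corrects magnification.
    """
    if not frames:
        raise ValidationError("empty sequence")

    have_ref = config.frame_center_x is not None and all(
        fr.reference_xy is not None for fr in frames
    )
    if have_ref:
        ref_series = reference_scale(frames, config.frame_center_x)
    else:
        log.warning("missing reference track or frame center; using s_ref = 1")
        ref_series = _scale_series_identity(frames)
    center = (config.frame_center_x if config.frame_center_x is not None else 0.0, 0.0)
    scaled = apply_scale(frames, ref_series.s_ref, center)

    if len(config.contracted_frames) >= 2:
        lf_series = arclength_lf_scale(scaled, config.contracted_frames)
    else:
        log.warning("fewer than 2 contracted frames; skipping linear-fit scale")
        lf_series = _scale_series_identity(frames)
    scaled = apply_scale(scaled, lf_series.s_lf, center)

    scales = ScaleSeries(ref_series.frame_index, ref_series.s_ref, lf_series.s_lf)

    body_frames: List[BodyFrame] = []
    halves: List[HalfProfile] = []
    for fr in scaled:
        try:
            apex, half_a, half_b = locate_apex(
                fr, apex_offset=config.apex_offset, offset_sign=config.apex_offset_sign
            )
            bf = body_angle(half_a, half_b, apex, config.top_fraction)
            ha = to_body_frame(half_a, bf)
            hb = to_body_frame(half_b, bf)
        except ValidationError as err:
            raise ValidationError(f"frame {fr.frame_index}: {err}") from err
        body_frames.append(bf)
        side_a = "left" if ha[1:, 0].mean() < 0 else "right"
        side_b = "right" if side_a == "left" else "left"
        for side, pts in ((side_a, ha), (side_b, hb)):
            half = HalfProfile(time=fr.time, side=side, points=pts, frame_index=fr.frame_index)
            half = smooth_half_profile(half, config.filter_cutoff_fraction)
            half = resample_half_profile(half, config.resample_n)
            halves.append(half)

    # normalize by the relaxed half arclength of cycle 1 (mean of sides)
    if config.relaxed_frame is not None:
        relaxed_idx = config.relaxed_frame
    else:
        totals = {}
        for h in halves:
            totals[h.frame_index] = totals.get(h.frame_index, 0.0) + h.arclength
        relaxed_idx = max(totals, key=totals.get)
    relaxed = [h for h in halves if h.frame_index == relaxed_idx]
    if not relaxed:
        raise ValidationError(f"relaxed frame {relaxed_idx} not found in sequence")
    norm = float(np.mean([h.arclength for h in relaxed]))
    if norm <= 0:
        raise ValidationError("non-positive normalization arclength")
    for h in halves:
        h.points = h.points / norm
    return halves, scales, body_frames
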
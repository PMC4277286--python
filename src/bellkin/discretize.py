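"""Strategic discretization of the exumbrella into nodes and segments.

Three node-placement strategies are provided:

* curvature — discrete signed curvature from the circumcircle of
  consecutive point triples; candidate nodes sit where the derivative
  of the across-frame mean curvature with respect to arclength crosses
  zero (the locations of strongest shape variation along the bell),
* anatomical — fixed landmarks of the swimming apparatus (coronal
  joint / circular muscles, radial muscles, flap root, margin),
* optimization — the node set minimizing the area discrepancy between
  the chord model and the profiles, found exactly on a percentage grid.

The model/profile discrepancy for one profile is the summed absolute
area enclosed between each chord and its profile arc, divided by the
profile arclength, so the error is dimensionless for normalized
profiles; the sequence error E is the sum over all profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .correction import cumulative_arclength, polyline_arclength
from .types import HalfProfile, ValidationError

__all__ = [
    "CurvatureProfile",
    "DiscreteBellModel",
    "circumcircle_curvature",
    "profile_curvature",
    "curvature_nodes",
    "anatomical_nodes",
    "ANATOMICAL_FRACTIONS",
    "ANATOMICAL_SEGMENT_LABELS",
    "model_from_fractions",
    "profile_model_error",
    "total_error",
    "evaluate_model",
    "optimize_nodes",
    "optimize_from_candidates",
]

# Landmark fractions (% of half arclength from the apex) of the
# Cyanea capillata swimming apparatus: the passive central disk ends at
# the coronal joint and circular muscles (40%), the radial muscles span
# 64-88%, and the muscle-free flap runs from 88% to the margin.
ANATOMICAL_FRACTIONS = (0.0, 40.0, 64.0, 88.0, 100.0)
ANATOMICAL_SEGMENT_LABELS = (
    "central disk",
    "circular muscles",
    "radial muscles",
    "flap",
)


@dataclass
class CurvatureProfile:
    """Per-point curvature statistics along resampled half profiles."""

    fractions: np.ndarray  # % of arclength, per point
    kappa: np.ndarray  # (n_frames, n_points), NaN at endpoints
    mean: np.ndarray  # across-frame mean curvature
    variance: np.ndarray  # across-frame sample variance (ddof=1)
    dkappa_ds: np.ndarray  # derivative of the mean curvature vs arclength


@dataclass
class DiscreteBellModel:
    """Chord model of the bell over a profile sequence."""

    node_fractions: np.ndarray  # %, strictly increasing, 0 .. 100
    times: np.ndarray
    node_positions: np.ndarray  # (n_frames, n_nodes, 2)
    segment_lengths: np.ndarray  # (n_frames, n_segments)
    segment_angles: np.ndarray  # degrees, (n_frames, n_segments)
    frame_errors: np.ndarray  # E_j per profile
    total_error: float
    sides: Optional[List[str]] = None

    def __post_init__(self):
        f = np.asarray(self.node_fractions, dtype=float)
        if f[0] != 0.0 or f[-1] != 100.0 or np.any(np.diff(f) <= 0):
            raise ValidationError("node fractions must increase strictly from 0 to 100")
        self.node_fractions = f

    @property
    def n_segments(self) -> int:
        return len(self.node_fractions) - 1


# ---------------------------------------------------------------------------
# curvature


def circumcircle_curvature(p1, p2, p3) -> float:
    """Signed discrete curvature from the circumcircle of three points.

    The unsigned curvature is the reciprocal circumradius,
    |kappa| = 4 A / (f g h) with A the triangle area and f, g, h the
    side lengths; the sign is the turn direction of the triple
    (positive for a counter-clockwise turn).  Collinear points give 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p2 - p1
    v = p3 - p2
    w = p3 - p1
    f, g, h = np.hypot(*u), np.hypot(*v), np.hypot(*w)
    if f == 0.0 or g == 0.0 or h == 0.0:
        raise ValidationError("coincident points have no circumcircle")
    cross = u[0] * v[1] - u[1] * v[0]
    return float(2.0 * cross / (f * g * h))


def profile_curvature(half: HalfProfile) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise signed curvature and its arclength derivative.

    Returns ``(fractions_pct, kappa, dkappa_ds)``; curvature is NaN at
    the two endpoints and the derivative additionally at their
    neighbours (central differences over cumulative arclength).
    """
    pts = half.points
    n = len(pts)
    if n < 3:
        raise ValidationError("need >= 3 points for curvature")
    s = cumulative_arclength(pts)
    kappa = np.full(n, np.nan)
    for i in range(1, n - 1):
        kappa[i] = circumcircle_curvature(pts[i - 1], pts[i], pts[i + 1])
    dk = np.full(n, np.nan)
    for i in range(2, n - 2):
        dk[i] = (kappa[i + 1] - kappa[i - 1]) / (s[i + 1] - s[i - 1])
    fractions = 100.0 * s / s[-1]
    return fractions, kappa, dk


def curvature_nodes(
    profiles: Sequence[HalfProfile],
    noise_floor: float = 1e-3,
) -> Tuple[List[float], CurvatureProfile]:
    """Candidate node fractions from across-frame mean curvature extrema.

    Curvature is averaged across frames per sample index; candidates are
    the arclength fractions where the central-difference derivative of
    the mean curvature crosses zero (linear interpolation between
    samples).  Crossings where both flanking derivative samples fall
    below ``noise_floor`` times the derivative peak are treated as
    numerical noise and skipped.  The across-frame sample variance per
    point is attached as the deformation-over-time indicator.
    """
    if len(profiles) < 2:
        raise ValidationError("need >= 2 profiles for curvature averaging")
    n = profiles[0].n
    if any(p.n != n for p in profiles):
        raise ValidationError("profiles must share a common resampling")
    kappa = np.vstack([profile_curvature(p)[1] for p in profiles])
    mean = kappa.mean(axis=0)
    variance = kappa.var(axis=0, ddof=1)
    s_mean = np.mean([cumulative_arclength(p.points) for p in profiles], axis=0)
    fractions = 100.0 * s_mean / s_mean[-1]
    dk = np.full(n, np.nan)
    for i in range(2, n - 2):
        dk[i] = (mean[i + 1] - mean[i - 1]) / (s_mean[i + 1] - s_mean[i - 1])
    valid = np.where(~np.isnan(dk))[0]
    candidates: List[float] = []
    # a derivative peak far below the curvature scale itself is numerical
    # noise on a constant-curvature arc, not a shape feature
    dk_scale = np.nanmax(np.abs(mean)) / s_mean[-1]
    if valid.size and np.nanmax(np.abs(dk)) > 1e-6 * dk_scale:
        peak = np.nanmax(np.abs(dk))
        thresh = noise_floor * peak if peak > 0 else 0.0
        for i in valid[:-1]:
            a, b = dk[i], dk[i + 1]
            if np.isnan(b):
                continue
            if a == 0.0 and abs(a) >= thresh:
                candidates.append(float(fractions[i]))
            elif a * b < 0.0:
                if abs(a) < thresh and abs(b) < thresh:
                    continue  # isolated noise flip
                u = a / (a - b)
                candidates.append(float(fractions[i] + u * (fractions[i + 1] - fractions[i])))
    report = CurvatureProfile(
        fractions=fractions, kappa=kappa, mean=mean, variance=variance, dkappa_ds=dk
    )
    return candidates, report


def anatomical_nodes() -> Tuple[List[float], List[str]]:
    """Fixed anatomical node fractions and the segment labels they bound."""
    return list(ANATOMICAL_FRACTIONS), list(ANATOMICAL_SEGMENT_LABELS)


# ---------------------------------------------------------------------------
# chord models and the area error


def model_from_fractions(half: HalfProfile, fractions: Sequence[float]) -> np.ndarray:
    """Node positions at arclength fractions (%) on the profile polyline."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0.0) or np.any(f > 100.0):
        raise ValidationError("node fractions must lie in [0, 100]")
    s = cumulative_arclength(half.points)
    targets = f / 100.0 * s[-1]
    x = np.interp(targets, s, half.points[:, 0])
    y = np.interp(targets, s, half.points[:, 1])
    return np.column_stack([x, y])


def _segment_area(pts: np.ndarray, s: np.ndarray, cs: np.ndarray, sa: float, sb: float) -> float:
    """|area| between the profile arc from sa to sb and its chord.

    ``cs`` holds prefix sums of cross(p_k, p_k+1) along the polyline so
    interior spans cost O(1); fractional end segments are handled by
    interpolated points.
    """
    if sb <= sa:
        return 0.0
    ka = min(int(np.searchsorted(s, sa, side="right") - 1), len(pts) - 2)
    kb = min(int(np.searchsorted(s, sb, side="right") - 1), len(pts) - 2)
    ua = 0.0 if s[ka + 1] == s[ka] else (sa - s[ka]) / (s[ka + 1] - s[ka])
    ub = 0.0 if s[kb + 1] == s[kb] else (sb - s[kb]) / (s[kb + 1] - s[kb])
    qa = pts[ka] + ua * (pts[ka + 1] - pts[ka])
    qb = pts[kb] + ub * (pts[kb + 1] - pts[kb])
    if ka == kb:
        return 0.0  # arc is a straight chord
    def cross(p, q):
        return p[0] * q[1] - p[1] * q[0]
    total = cross(qa, pts[ka + 1]) + (cs[kb] - cs[ka + 1]) + cross(pts[kb], qb) + cross(qb, qa)
    return 0.5 * abs(total)


def _prefix_cross(pts: np.ndarray) -> np.ndarray:
    c = pts[:-1, 0] * pts[1:, 1] - pts[:-1, 1] * pts[1:, 0]
    return np.concatenate([[0.0], np.cumsum(c)])


def profile_model_error(half: HalfProfile, fractions: Sequence[float]) -> float:
    """Dimensionless discrepancy E_j between one profile and a chord model.

    Sum over segments of the absolute area enclosed by the profile arc
    and its chord, divided by the profile's total arclength.
    """
    pts = half.points
    s = cumulative_arclength(pts)
    cs = _prefix_cross(pts)
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0.0) or np.any(f > 100.0):
        raise ValidationError("node fractions must lie in [0, 100]")
    targets = np.sort(f) / 100.0 * s[-1]
    area = 0.0
    for sa, sb in zip(targets[:-1], targets[1:]):
        area += _segment_area(pts, s, cs, sa, sb)
    return area / s[-1]


def total_error(profiles: Sequence[HalfProfile], fractions: Sequence[float]) -> float:
    """Sequence error E: sum of E_j over all profiles (both halves)."""
    return float(sum(profile_model_error(p, fractions) for p in profiles))


def evaluate_model(
    profiles: Sequence[HalfProfile], fractions: Sequence[float]
) -> DiscreteBellModel:
    """Build the chord model with node tracks, segment geometry and errors."""
    from .kinematics import chain_lengths_angles  # local import; kinematics is leaf-free

    fr = np.asarray(fractions, dtype=float)
    times = np.array([p.time for p in profiles])
    nodes = np.stack([model_from_fractions(p, fr) for p in profiles])
    lengths = np.empty((len(profiles), len(fr) - 1))
    angles = np.empty_like(lengths)
    for j in range(len(profiles)):
        lengths[j], angles[j] = chain_lengths_angles(nodes[j])
    errors = np.array([profile_model_error(p, fr) for p in profiles])
    return DiscreteBellModel(
        node_fractions=fr,
        times=times,
        node_positions=nodes,
        segment_lengths=lengths,
        segment_angles=angles,
        frame_errors=errors,
        total_error=float(errors.sum()),
        sides=[p.side for p in profiles],
    )


# ---------------------------------------------------------------------------
# node-location optimization


def _pairwise_cost(profiles: Sequence[HalfProfile], grid: np.ndarray) -> np.ndarray:
    """M[i, j] = sum over profiles of area(grid_i, grid_j) / L_p for i < j."""
    G = len(grid)
    M = np.zeros((G, G))
    for p in profiles:
        pts = p.points
        s = cumulative_arclength(pts)
        cs = _prefix_cross(pts)
        L = s[-1]
        targets = grid / 100.0 * L
        for i in range(G - 1):
            for j in range(i + 1, G):
                M[i, j] += _segment_area(pts, s, cs, targets[i], targets[j]) / L
    return M


def optimize_nodes(
    profiles: Sequence[HalfProfile],
    n_segments: int,
    grid_step: float = 2.0,
) -> DiscreteBellModel:
    """Minimum-error node placement on a percentage grid.

    Endpoints are fixed at 0 and 100%; the interior nodes minimizing the
    sequence error E over the grid are found exactly (E is additive over
    segments, so the search is a fixed-edge-count shortest path solved
    by dynamic programming, equivalent to exhaustive enumeration).  Ties
    break to the lexicographically smallest fraction tuple.
    """
    if n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    if not profiles:
        raise ValidationError("no profiles given")
    n_steps = int(round(100.0 / grid_step))
    if abs(n_steps * grid_step - 100.0) > 1e-9:
        raise ValidationError("grid_step must divide 100")
    grid = np.linspace(0.0, 100.0, n_steps + 1)
    if len(grid) - 2 < n_segments - 1:
        raise ValidationError(
            f"grid of {len(grid) - 2} interior points cannot host {n_segments - 1} interior nodes"
        )
    M = _pairwise_cost(profiles, grid)
    G = len(grid)
    # dp[j] = (cost, path) of the best path 0 -> j with the current edge count
    dp: List[Optional[Tuple[float, Tuple[int, ...]]]] = [None] * G
    dp[0] = (0.0, (0,))
    for _ in range(n_segments):
        nxt: List[Optional[Tuple[float, Tuple[int, ...]]]] = [None] * G
        for j in range(1, G):
            best = None
            for i in range(j):
                if dp[i] is None:
                    continue
                cand = (dp[i][0] + M[i, j], dp[i][1] + (j,))
                if best is None or cand < best:
                    best = cand
            nxt[j] = best
        dp = nxt
    if dp[G - 1] is None:
        raise ValidationError("no feasible node placement on this grid")
    cost, path = dp[G - 1]
    return evaluate_model(profiles, grid[list(path)])


def optimize_from_candidates(
    profiles: Sequence[HalfProfile],
    candidates: Sequence[float],
    n_segments: int,
) -> DiscreteBellModel:
    """Best node subset of candidate fractions by exhaustive enumeration.

    Endpoints stay fixed at 0 and 100%; every combination of
    ``n_segments - 1`` interior candidates is evaluated and the
    minimum-E model returned (lexicographic tie-break).
    """
    cand = sorted(float(c) for c in candidates if 0.0 < c < 100.0)
    k = n_segments - 1
    if len(cand) < k:
        raise ValidationError(
            f"{len(cand)} interior candidates cannot fill {k} interior nodes"
        )
    best = None
    for combo in itertools.combinations(cand, k):
        fracs = (0.0,) + combo + (100.0,)
        e = total_error(profiles, fracs)
        key = (e, fracs)
        if best is None or key < best:
            best = key
    return evaluate_model(profiles, best[1])
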
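"""Shared domain containers for the bell-kinematics pipeline.

All in-memory coordinates use a y-up camera convention (image rows are
flipped on ingest when the source is image-derived).  Half profiles are
rooted at the bell apex and, after full correction, live in the body
frame with coordinates normalized by the relaxed half exumbrella
arclength of the first swimming cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BellkinError",
    "FormatError",
    "ValidationError",
    "SequenceConfig",
    "DigitizedFrame",
    "HalfProfile",
    "ScaleSeries",
    "BodyFrame",
]


class BellkinError(Exception):
    """Base class for all package errors."""


class FormatError(BellkinError):
    """An on-disk artifact does not match the expected layout."""


class ValidationError(BellkinError):
    """Data violates a documented invariant."""


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"expected an (N, 2) point array, got shape {arr.shape}")
    return arr


@dataclass
class SequenceConfig:
    """Acquisition and processing parameters for one digitized sequence.

    Parameters
    ----------
    fps : float
        Video frame rate of the source footage (frames / s).
    stride : int
        Digitization stride: one outline was digitized every ``stride``
        video frames, so consecutive digitized frames are
        ``stride / fps`` seconds apart.
    contracted_frames : sequence of int
        Digitized frame indices at which the bell is fully contracted
        (the instants used for the arclength linear-fit scale).
    apex_offset : float
        Arclength offset (pixels, frame-1 scale) from the tracked
        near-apex body marker to the true apex, measured once on the
        first frame.
    apex_offset_sign : int
        Direction of the offset along the outline (+1 toward larger
        point index, -1 toward smaller).
    top_fraction : float
        Fraction of each half's arclength around the apex used for the
        body-rotation linear fit.
    resample_n : int
        Number of uniformly spaced arclength samples per half profile.
    filter_cutoff_fraction : float
        Butterworth low-pass cutoff as a fraction of the Nyquist
        frequency of the per-point sampling.
    y_down : bool
        True when input pixel rows increase downward (image-derived
        data); rows are flipped to y-up on ingest.
    frame_center_x : float, optional
        x of the image center (width / 2), required for the
        reference-point magnification correction.
    relaxed_frame : int, optional
        Digitized frame index of the fully relaxed bell in cycle 1 used
        for arclength normalization; defaults to the frame of maximum
        total arclength.
    """

    fps: float = 25.0
    stride: int = 5
    contracted_frames: tuple = ()
    apex_offset: float = 0.0
    apex_offset_sign: int = 1
    top_fraction: float = 0.24
    resample_n: int = 51
    filter_cutoff_fraction: float = 0.20
    y_down: bool = True
    frame_center_x: Optional[float] = None
    relaxed_frame: Optional[int] = None

    def __post_init__(self):
        self.contracted_frames = tuple(int(f) for f in self.contracted_frames)
        if not (0.0 < self.top_fraction < 0.5):
            raise ValidationError("top_fraction must lie in (0, 0.5)")
        if self.resample_n < 3:
            raise ValidationError("resample_n must be >= 3")
        if not (0.0 < self.filter_cutoff_fraction < 1.0):
            raise ValidationError("filter_cutoff_fraction must lie in (0, 1)")
        if self.fps <= 0 or self.stride <= 0:
            raise ValidationError("fps and stride must be positive")
        if self.apex_offset_sign not in (-1, 1):
            raise ValidationError("apex_offset_sign must be +1 or -1")

    @property
    def dt(self) -> float:
        """Seconds between consecutive digitized frames."""
        return self.stride / self.fps

    def replace(self, **kw) -> "SequenceConfig":
        return replace(self, **kw)


@dataclass
class DigitizedFrame:
    """One digitized outline (margin to margin) plus optional tracks."""

    frame_index: int
    time: float
    points: np.ndarray
    reference_xy: Optional[np.ndarray] = None
    marker_xy: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = _as_points(self.points)
        if len(self.points) < 5:
            raise ValidationError(
                f"frame {self.frame_index}: outline needs >= 5 points, got {len(self.points)}"
            )
        dup = np.all(np.diff(self.points, axis=0) == 0.0, axis=1)
        if np.any(dup):
            raise ValidationError(
                f"frame {self.frame_index}: duplicate consecutive outline points"
            )
        for name in ("reference_xy", "marker_xy"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).reshape(2))


@dataclass
class HalfProfile:
    """Apex-rooted half outline at one time sample.

    ``points[0]`` is the apex; ``points[-1]`` the bell margin.  After
    resampling, the ``resample_n`` points sit at uniform fractions of
    the cumulative arclength, indexed ``b = 0 .. n-1``.
    """

    time: float
    side: str
    points: np.ndarray
    frame_index: Optional[int] = None

    def __post_init__(self):
        self.points = _as_points(self.points)
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def arclength(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class ScaleSeries:
    """Per-frame multiplicative scale corrections.

    ``s_ref`` removes camera magnification measured from the background
    reference point; ``s_lf`` removes the residual linear drift measured
    from the contracted-instant arclengths.  Both equal 1 on frame 1 and
    multiply frame coordinates (about the frame center) to restore the
    frame-1 scale.
    """

    frame_index: np.ndarray
    s_ref: np.ndarray
    s_lf: np.ndarray

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.s_ref = np.asarray(self.s_ref, dtype=float)
        self.s_lf = np.asarray(self.s_lf, dtype=float)
        if not (len(self.frame_index) == len(self.s_ref) == len(self.s_lf)):
            raise ValidationError("scale series length mismatch")
        if np.any(self.s_ref <= 0) or np.any(self.s_lf <= 0):
            raise ValidationError("scales must be positive")

    @property
    def s_total(self) -> np.ndarray:
        return self.s_ref * self.s_lf


@dataclass
class BodyFrame:
    """Rigid camera-to-body transform for one frame.

    theta is the roll angle about the optical axis, from the linear fit
    through the near-apex top region; apex_xy is the rotation origin.
    """

    theta: float
    apex_xy: np.ndarray
    slope: float
    intercept: float
    n_points: int

    def __post_init__(self):
        self.apex_xy = np.asarray(self.apex_xy, dtype=float).reshape(2)
        if abs(self.theta) >= np.pi / 2:
            raise ValidationError("|theta| must be < pi/2")
        if self.n_points < 2:
            raise ValidationError("body-frame fit needs >= 2 points")
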
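"""On-disk artifacts: digitized points, tracks, profiles, models, config.

All tabular artifacts are comma-delimited UTF-8 with a header row and
full-precision floats, so round trips are lossless well below 1e-9.
Fourier coefficient files and node models are JSON; sequence
configuration is YAML.

Image-derived inputs usually have pixel rows increasing downward; the
reader flips them to the package's y-up convention when
``config.y_down`` is true, and the writers invert the same flag so
read(write(x)) is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinematics import FourierChannel, FourierKinematicModel
from .types import (
    DigitizedFrame,
    FormatError,
    HalfProfile,
    SequenceConfig,
    ValidationError,
)

__all__ = [
    "read_digitized_sequence",
    "write_digitized_sequence",
    "read_half_profiles",
    "write_half_profiles",
    "read_fourier_model",
    "write_fourier_model",
    "read_node_model",
    "write_node_model",
    "load_config",
    "save_config",
]

_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_digitized_sequence(
    points_path,
    tracks_path: Optional[object],
    config: SequenceConfig,
) -> List[DigitizedFrame]:
    """Read digitized outline points and optional reference/marker tracks.

    ``points_path`` needs columns (frame, point_idx, x, y);
    ``tracks_path`` (frame, kind, x, y) with kind in {reference, marker}.
    Frames are sorted by index, points by point_idx within each frame
    (never reordered beyond that, never dropped), and times follow
    t = (frame - first_frame) * stride / fps.
    """
    pts = pd.read_csv(points_path)
    _require_columns(pts, ("frame", "point_idx", "x", "y"), points_path)
    tracks = None
    if tracks_path is not None and Path(tracks_path).exists():
        tracks = pd.read_csv(tracks_path)
        _require_columns(tracks, ("frame", "kind", "x", "y"), tracks_path)

    ysign = -1.0 if config.y_down else 1.0
    frames: List[DigitizedFrame] = []
    frame_ids = sorted(pts["frame"].unique())
    first = int(frame_ids[0])
    for fid in frame_ids:
        sub = pts[pts["frame"] == fid].sort_values("point_idx", kind="stable")
        xy = np.column_stack([sub["x"].to_numpy(float), ysign * sub["y"].to_numpy(float)])
        ref = marker = None
        if tracks is not None:
            tsub = tracks[tracks["frame"] == fid]
            for kind in ("reference", "marker"):
                row = tsub[tsub["kind"] == kind]
                if len(row):
                    v = np.array([row["x"].iloc[0], ysign * row["y"].iloc[0]], dtype=float)
                    if kind == "reference":
                        ref = v
                    else:
                        marker = v
        if len(xy) < 5:
            raise ValidationError(f"frame {fid}: outline needs >= 5 points, got {len(xy)}")
        frames.append(
            DigitizedFrame(
                frame_index=int(fid),
                time=(int(fid) - first) * config.stride / config.fps,
                points=xy,
                reference_xy=ref,
                marker_xy=marker,
            )
        )
    return frames


def write_digitized_sequence(
    frames: Sequence[DigitizedFrame],
    points_path,
    tracks_path=None,
    y_down: bool = True,
):
    """Write frames (and tracks) in the layout the reader consumes."""
    ysign = -1.0 if y_down else 1.0
    rows = []
    for fr in frames:
        for i, (x, y) in enumerate(fr.points):
            rows.append((fr.frame_index, i, x, ysign * y))
    pd.DataFrame(rows, columns=["frame", "point_idx", "x", "y"]).to_csv(
        points_path, index=False, float_format=_FLOAT_FMT
    )
    if tracks_path is not None:
        trows = []
        for fr in frames:
            if fr.reference_xy is not None:
                trows.append((fr.frame_index, "reference", fr.reference_xy[0], ysign * fr.reference_xy[1]))
            if fr.marker_xy is not None:
                trows.append((fr.frame_index, "marker", fr.marker_xy[0], ysign * fr.marker_xy[1]))
        pd.DataFrame(trows, columns=["frame", "kind", "x", "y"]).to_csv(
            tracks_path, index=False, float_format=_FLOAT_FMT
        )
    return points_path


def write_half_profiles(profiles: Sequence[HalfProfile], path):
    """Write half profiles as (time, frame, side, b, x_n, y_n) rows."""
    ns = {p.n for p in profiles}
    if len(ns) > 1:
        raise ValidationError(f"heterogeneous point counts {sorted(ns)} in one file")
    rows = []
    for p in profiles:
        for b, (x, y) in enumerate(p.points):
            rows.append((p.time, -1 if p.frame_index is None else p.frame_index, p.side, b, x, y))
    pd.DataFrame(rows, columns=["time", "frame", "side", "b", "x_n", "y_n"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_half_profiles(path) -> List[HalfProfile]:
    df = pd.read_csv(path)
    _require_columns(df, ("time", "frame", "side", "b", "x_n", "y_n"), path)
    out: List[HalfProfile] = []
    for (t, fr, side), sub in df.groupby(["time", "frame", "side"], sort=True):
        sub = sub.sort_values("b", kind="stable")
        out.append(
            HalfProfile(
                time=float(t),
                side=str(side),
                points=np.column_stack([sub["x_n"].to_numpy(float), sub["y_n"].to_numpy(float)]),
                frame_index=None if int(fr) < 0 else int(fr),
            )
        )
    out.sort(key=lambda p: (p.time, p.side))
    return out


def write_fourier_model(model: FourierKinematicModel, path):
    """Write per-channel Fourier coefficient blocks as JSON."""
    payload = {
        "period": model.T,
        "order": model.order,
        "channels": {
            name: {
                "a0": ch.a0,
                "a": list(ch.a),
                "b": list(ch.b),
                "residual_rms": ch.residual_rms,
            }
            for name, ch in model.channels.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return path


def read_fourier_model(path) -> FourierKinematicModel:
    payload = json.loads(Path(path).read_text())
    try:
        channels = {
            name: FourierChannel(
                a0=float(ch["a0"]),
                a=np.asarray(ch["a"], float),
                b=np.asarray(ch["b"], float),
                T=float(payload["period"]),
                residual_rms=float(ch.get("residual_rms", 0.0)),
            )
            for name, ch in payload["channels"].items()
        }
        return FourierKinematicModel(
            channels=channels, T=float(payload["period"]), order=int(payload["order"])
        )
    except KeyError as err:
        raise FormatError(f"{path}: missing key {err}") from err


def write_node_model(model, path):
    """Write a discrete bell model's fractions and summary error as JSON."""
    payload = {
        "node_fractions": list(map(float, model.node_fractions)),
        "total_error": float(model.total_error),
        "times": list(map(float, model.times)),
        "frame_errors": list(map(float, model.frame_errors)),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return path


def read_node_model(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if "node_fractions" not in payload:
        raise FormatError(f"{path}: not a node-model file")
    return payload


def load_config(path) -> SequenceConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in SequenceConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return SequenceConfig(**data)


def save_config(config: SequenceConfig, path):
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
    return path
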
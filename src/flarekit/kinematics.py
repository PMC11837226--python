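"""Keypoint cleaning and kinematic feature extraction.

Input is a wide pose-tracker table (three columns per body part: x, y,
likelihood).  Cleaning drops low-confidence samples and single-frame jumps
and fills them by linear interpolation; features are computed in image
coordinates (origin top-left, y down) and scaled by ``px_per_cm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_FRAME_RATE, FeatureSeries

DEFAULT_CONF_THRESH = 0.8
DEFAULT_JUMP_THRESH = 15.0   # px
DEFAULT_SMOOTH_WINDOW = 11   # frames

MIDLINE_PARTS = ("spine1", "spine2", "spine3")


@dataclass
class KeypointTable:
    """Frames x keypoints table with per-keypoint (x, y, confidence)."""

    data: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE
    view: str = "top"
    px_per_cm: float = 1.0

    def __post_init__(self):
        if self.frame_rate <= 0 or self.px_per_cm <= 0:
            raise ValueError("frame_rate and px_per_cm must be positive")
        if self.view not in ("top", "side"):
            raise ValueError("view must be 'top' or 'side'")

    @property
    def bodyparts(self) -> list[str]:
        return [c[:-2] for c in self.data.columns if c.endswith("_x")]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, part: str) -> np.ndarray:
        return self.data[[f"{part}_x", f"{part}_y"]].to_numpy(dtype=float)

    def confidence(self, part: str) -> np.ndarray:
        return self.data[f"{part}_likelihood"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float = DEFAULT_FRAME_RATE,
                 view: str = "top", px_per_cm: float = 1.0) -> "KeypointTable":
        """Read a wide keypoint CSV; a multi-row pose-tracker header
        (scorer / bodyparts / coords rows) is collapsed to flat names."""
        path = Path(path)
        head = pd.read_csv(path, nrows=4, header=None)
        first = str(head.iloc[0, 0]).lower()
        if first in ("scorer", "bodyparts"):
            # DLC-style: rows for scorer (optional), bodyparts, coords
            skip = 0
            rows = [str(v).lower() for v in head.iloc[:, 0]]
            bp_row = rows.index("bodyparts")
            coord_row = rows.index("coords")
            raw = pd.read_csv(path, header=list(range(coord_row + 1)),
                              index_col=0, skiprows=skip)
            parts = raw.columns.get_level_values(bp_row)
            coords = raw.columns.get_level_values(coord_row)
            cols = [f"{p}_{'likelihood' if c == 'likelihood' else c}"
                    for p, c in zip(parts, coords)]
            data = pd.DataFrame(raw.to_numpy(dtype=float), columns=cols)
        else:
            data = pd.read_csv(path)
        return cls(data=data.reset_index(drop=True), frame_rate=frame_rate,
                   view=view, px_per_cm=px_per_cm)


def clean_keypoints(table: KeypointTable,
                    conf_thresh: float = DEFAULT_CONF_THRESH,
                    jump_thresh: float = DEFAULT_JUMP_THRESH) -> KeypointTable:
    """Drop low-confidence and jumping samples; fill by linear interpolation.

    A sample is dropped when its confidence is below ``conf_thresh`` or when
    its displacement from the previous *retained* sample exceeds
    ``jump_thresh`` pixels (comparing to the retained rather than the raw
    predecessor prevents one outlier from masking subsequent good points).
    Interior gaps are linearly interpolated; leading/trailing gaps take the
    nearest valid value.  Imputed samples get confidence 1.0, which makes
    the operation idempotent.
    """
    if table.n_frames == 0:
        raise ValueError("empty keypoint table")
    out = table.data.copy()
    n = table.n_frames
    idx = np.arange(n)
    for part in table.bodyparts:
        xy = table.xy(part)
        conf = table.confidence(part)
        keep = np.zeros(n, dtype=bool)
        last = None
        for t in range(n):
            if conf[t] < conf_thresh:
                continue
            if last is not None and np.hypot(*(xy[t] - last)) > jump_thresh:
                continue
            keep[t] = True
            last = xy[t]
        if not keep.any():
            raise ValueError(f"keypoint {part!r} has no valid samples")
        valid = idx[keep]
        for j, col in enumerate((f"{part}_x", f"{part}_y")):
            # np.interp clamps at the edges -> nearest-value fill there
            out[col] = np.interp(idx, valid, xy[keep, j])
        newconf = conf.copy()
        newconf[~keep] = 1.0
        out[f"{part}_likelihood"] = newconf
    return replace(table, data=out)


@dataclass
class TailGeometry:
    tail_angle: float        # deg, between tail line and body line, [0, 90]
    tail_deviation: float    # cm, perpendicular distance of tail tip to body line
    contour_head: np.ndarray
    contour_tail: np.ndarray


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Least-squares line direction through a point cloud (principal axis)."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    if np.allclose(cov, 0.0):
        warnings.warn("degenerate contour neighborhood; zero-angle result")
        return np.array([1.0, 0.0])
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def tail_geometry(contour: np.ndarray, head_kp, tail_kp,
                  px_per_cm: float = 1.0, n_fit: int = 100) -> TailGeometry:
    """Head/tail contour anchoring and tail line-fit geometry.

    The contour points nearest the supplied head and tail markers become the
    contour head/tail; lines are least-squares fit to the ``n_fit`` contour
    points centered on each anchor (wrapping around the closed polygon).
    The tail angle is the angle between the two lines; the deviation is the
    perpendicular distance of the contour tail from the body (head) line.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) polygon")
    m = len(contour)
    head_kp = np.asarray(head_kp, dtype=float)
    tail_kp = np.asarray(tail_kp, dtype=float)
    i_head = int(np.argmin(np.linalg.norm(contour - head_kp, axis=1)))
    i_tail = int(np.argmin(np.linalg.norm(contour - tail_kp, axis=1)))

    half = n_fit // 2

    def neighborhood(i):
        offs = np.arange(-half, half) % m
        return contour[(i + offs) % m]

    v_body = _fit_direction(neighborhood(i_head))
    v_tail = _fit_direction(neighborhood(i_tail))

    cosang = abs(float(np.dot(v_body, v_tail)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    rel = contour[i_tail] - contour[i_head]
    deviation = abs(float(rel[0] * v_body[1] - rel[1] * v_body[0])) / px_per_cm
    return TailGeometry(tail_angle=angle, tail_deviation=deviation,
                        contour_head=contour[i_head],
                        contour_tail=contour[i_tail])


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle in degrees between stacks of 2-D vectors."""
    dot = (u * v).sum(axis=-1)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip(dot / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def compute_features(table: KeypointTable,
                     contours=None,
                     stimulus_normal=(1.0, 0.0),
                     stimulus_x: float | None = None,
                     side_table: KeypointTable | None = None,
                     tank_floor_y: float | None = None) -> FeatureSeries:
    """Extract per-frame behavioral feature channels from cleaned keypoints.

    ``stimulus_normal`` is the image-plane unit vector pointing toward the
    stimulus side; orientation is the unsigned angle in [0, 180] between the
    body axis (centroid -> nose) and that normal.  Elevation and z-channels
    require ``side_table`` (with a ``nose`` or ``head`` part) plus
    ``tank_floor_y``; they are omitted, not zero-filled, when absent.
    """
    if table.px_per_cm <= 0:
        raise ValueError("px_per_cm must be set on the keypoint table")
    scale = table.px_per_cm
    fps = table.frame_rate
    n = table.n_frames
    parts = table.bodyparts

    nose = table.xy("nose")
    mid_parts = [p for p in MIDLINE_PARTS if p in parts] or \
        [p for p in parts if "operculum" not in p and p != "nose"]
    centroid = np.mean([table.xy(p) for p in mid_parts], axis=0)

    axis = nose - centroid
    normal = np.asarray(stimulus_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    orientation = _angle_between(axis, np.broadcast_to(normal, axis.shape))

    heading = np.degrees(np.arctan2(axis[:, 1], axis[:, 0]))
    turning = np.zeros(n)
    if n > 1:
        d = np.diff(heading)
        turning[1:] = (d + 180.0) % 360.0 - 180.0

    speed = np.zeros(n)
    if n > 1:
        speed[1:] = np.linalg.norm(np.diff(centroid, axis=0), axis=1) * fps / scale

    data = {
        "orientation": orientation,
        "speed": speed,
        "turning_angle": turning,
        "head_x": nose[:, 0] / scale,
        "head_y": nose[:, 1] / scale,
        "centroid_x": centroid[:, 0] / scale,
        "centroid_y": centroid[:, 1] / scale,
    }
    units = {"orientation": "deg", "speed": "cm/s", "turning_angle": "deg/frame",
             "head_x": "cm", "head_y": "cm", "centroid_x": "cm",
             "centroid_y": "cm"}

    if "tail" in parts:
        tail = table.xy("tail")
        data["tail_x"] = tail[:, 0] / scale
        data["tail_y"] = tail[:, 1] / scale
        units["tail_x"] = units["tail_y"] = "cm"

    if "left_operculum" in parts and "right_operculum" in parts:
        left = table.xy("left_operculum") - nose
        right = table.xy("right_operculum") - nose
        data["operculum_angle"] = _angle_between(left, right)
        back = -axis
        data["left_operculum_angle"] = _angle_between(left, back)
        data["right_operculum_angle"] = _angle_between(right, back)
        # perpendicular distance of the tips from the body-axis line
        ax_unit = axis / np.maximum(np.linalg.norm(axis, axis=1, keepdims=True),
                                    1e-12)
        def perp(v):
            return np.abs(v[:, 0] * ax_unit[:, 1] - v[:, 1] * ax_unit[:, 0])
        data["operculum_midline_distance"] = (perp(left) + perp(right)) / 2 / scale
        units.update({"operculum_angle": "deg", "left_operculum_angle": "deg",
                      "right_operculum_angle": "deg",
                      "operculum_midline_distance": "cm"})

    if contours is not None:
        tail_kp = table.xy("tail") if "tail" in parts else centroid
        angles = np.empty(n)
        devs = np.empty(n)
        for i in range(n):
            g = tail_geometry(contours[i], nose[i], tail_kp[i], px_per_cm=scale)
            angles[i] = g.tail_angle
            devs[i] = g.tail_deviation
        data["tail_angle"] = angles
        data["tail_deviation"] = devs
        units.update({"tail_angle": "deg", "tail_deviation": "cm"})

    if stimulus_x is not None:
        data["distance_to_stimulus"] = np.abs(stimulus_x - nose[:, 0]) / scale
        units["distance_to_stimulus"] = "cm"

    absent = []
    if side_table is not None and tank_floor_y is not None:
        sparts = side_table.bodyparts
        head_part = "nose" if "nose" in sparts else "head"
        if head_part not in sparts:
            raise ValueError("side view table needs a 'nose' or 'head' keypoint")
        shead = side_table.xy(head_part)
        m = min(n, side_table.n_frames)
        elev = np.full(n, np.nan)
        elev[:m] = (tank_floor_y - shead[:m, 1]) / side_table.px_per_cm
        data["elevation"] = elev
        data["head_z"] = elev
        data["centroid_z"] = elev
        units.update({"elevation": "cm", "head_z": "cm", "centroid_z": "cm"})
    else:
        absent = ["elevation", "head_z", "centroid_z"]

    fs = FeatureSeries(data=pd.DataFrame(data), frame_rate=fps, units=units)
    fs.meta["absent_channels"] = absent
    return fs


def median_smooth(series: FeatureSeries,
                  window_frames: int = DEFAULT_SMOOTH_WINDOW) -> FeatureSeries:
    """Centered sliding-median smoothing of every channel.

    Windows shrink at the record edges.  The window's temporal span
    (``window_frames / frame_rate`` seconds) is recorded in the metadata.
    """
    if window_frames % 2 == 0 or window_frames < 1:
        raise ValueError("window_frames must be a positive odd integer")
    smoothed = series.data.rolling(window_frames, center=True,
                                   min_periods=1).median()
    meta = dict(series.meta)
    meta["smoothing_window_frames"] = window_frames
    meta["smoothing_window_s"] = window_frames / series.frame_rate
    return FeatureSeries(data=smoothed, frame_rate=series.frame_rate,
                         units=dict(series.units), meta=meta)
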
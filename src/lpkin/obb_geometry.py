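"""From oriented-bounding-box detections to a calibrated bar trajectory.

A landmine press is filmed side-on; an object detector emits, per video
frame, one oriented bounding box (OBB) around the whole bar, or one small
box around each bar end ("moving" and "fixed" classes).  This module
reduces those boxes to two points per frame — the moving (pressed) end and
the fixed (pivot) end — then converts pixels to metres using the known real
bar length, producing a trajectory in a y-up frame with its origin at the
pivot.

Geometry of the single-box path: the bar's principal axis is the longer
side of its OBB, and the two bar ends are approximated by the midpoints of
the two opposing longer sides.  End classification uses the biomechanical
constraint that the anchored end sits lower in the image (larger image-y,
since image coordinates grow downward).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OBBDetection",
    "AxisEndpoints",
    "EndTrack",
    "CalibratedTrajectory",
    "read_obb_detections",
    "axis_midpoints",
    "classify_ends",
    "build_end_tracks",
    "calibrate",
    "DEFAULT_CLASS_MAP",
]

ClassLabel = Literal["bar", "moving_marker", "fixed_marker"]

#: Default mapping from integer detector class ids to semantic labels.
DEFAULT_CLASS_MAP: dict[int, str] = {0: "bar", 1: "moving_marker", 2: "fixed_marker"}

_VALID_LABELS = {"bar", "moving_marker", "fixed_marker"}


def _shoelace_area(corners: np.ndarray) -> float:
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_cross(p: np.ndarray, q: np.ndarray, r: np.ndarray, s: np.ndarray) -> bool:
    """Proper intersection test for open segments pq and rs."""

    def orient(a, b, c):
        u, v = b - a, c - a
        return np.sign(u[0] * v[1] - u[1] * v[0])

    return (orient(p, q, r) * orient(p, q, s) < 0
            and orient(r, s, p) * orient(r, s, q) < 0)


def _ensure_simple(corners: np.ndarray) -> np.ndarray:
    """Re-order corners into a simple (non-self-crossing) quadrilateral.

    Input corners are expected consecutive around the rectangle; if the
    polygon has crossing edges (a "bowtie" ordering) the last two corners
    are swapped, which fixes the common mis-orderings.
    """
    for perm in ((0, 1, 2, 3), (0, 1, 3, 2), (0, 2, 1, 3)):
        c = corners[list(perm)]
        if not (_segments_cross(c[0], c[1], c[2], c[3])
                or _segments_cross(c[1], c[2], c[3], c[0])):
            if perm != (0, 1, 2, 3):
                logger.warning("re-ordered self-crossing OBB corners %s", perm)
            return c
    return corners


@dataclass(frozen=True)
class OBBDetection:
    """One oriented box in one frame, corners in pixel coordinates.

    Corners are stored consecutively around the rectangle (adjacent list
    entries share an edge); self-crossing orderings are repaired on
    construction and zero-area boxes rejected.
    """

    frame_index: int
    class_label: str
    corners: np.ndarray  # shape (4, 2), pixels
    confidence: float | None = None

    def __post_init__(self) -> None:
        corners = np.asarray(self.corners, dtype=float)
        if corners.shape != (4, 2):
            raise ValidationError(
                f"frame {self.frame_index}: expected 4 corner points, got "
                f"array of shape {corners.shape}"
            )
        if self.class_label not in _VALID_LABELS:
            raise ValidationError(
                f"frame {self.frame_index}: unknown class {self.class_label!r}"
            )
        if self.frame_index < 0:
            raise ValidationError("frame_index must be >= 0")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"confidence must be in [0, 1], got {self.confidence}"
            )
        corners = _ensure_simple(corners)
        if abs(_shoelace_area(corners)) <= 0.0:
            raise ValidationError(
                f"frame {self.frame_index}: zero-area box"
            )
        corners.setflags(write=False)
        object.__setattr__(self, "corners", corners)

    @property
    def center(self) -> np.ndarray:
        return self.corners.mean(axis=0)


@dataclass(frozen=True)
class AxisEndpoints:
    """Midpoints of the two short sides of an OBB, i.e. the bar-end estimates."""

    M1: np.ndarray
    M2: np.ndarray
    L1: float
    L2: float


@dataclass
class EndTrack:
    """Per-frame moving/fixed pixel points for one contiguous block of frames."""

    frame_indices: np.ndarray   # strictly increasing ints
    moving_px: np.ndarray       # (n, 2)
    fixed_px: np.ndarray        # (n, 2)
    fps: float
    image_height: float
    gap_mask: np.ndarray        # True where the frame was interpolated

    def __post_init__(self) -> None:
        n = len(self.frame_indices)
        if not (len(self.moving_px) == len(self.fixed_px) == len(self.gap_mask) == n):
            raise ValidationError("EndTrack arrays must share one length")
        if n >= 2 and not np.all(np.diff(self.frame_indices) > 0):
            raise ValidationError("frame_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_indices)


@dataclass
class CalibratedTrajectory:
    """Moving-end trajectory in metres, y-up, origin at the pivot.

    ``scale_s`` is the single scalar pixel-to-metre factor obtained from the
    known real bar length; ``scale_s * L_pixel_mean == L_real`` by
    construction.
    """

    t: np.ndarray          # seconds
    moving_m: np.ndarray   # (n, 2) metres, pivot at origin, y up
    pivot_m: np.ndarray    # (2,), always (0, 0)
    scale_s: float         # m / pixel
    L_pixel_mean: float    # pixels
    L_real: float          # metres
    fps: float
    gap_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# parsing

_LINE_RE = re.compile(r"\S+")


def _parse_yolo_line(line: str, path: Path, lineno: int,
                     width: float, height: float,
                     class_map: dict[int, str]) -> tuple[str, np.ndarray, float | None]:
    tokens = line.split()
    if len(tokens) not in (9, 10):
        raise ParseError(
            f"{path}:{lineno}: expected 'class x1 y1 ... x4 y4 [conf]' "
            f"(9 or 10 fields), got {len(tokens)}"
        )
    try:
        cls_id = int(tokens[0])
        values = [float(tok) for tok in tokens[1:]]
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    coords = np.array(values[:8], dtype=float)
    conf = values[8] if len(values) == 9 else None
    if coords.min() < 0.0 or coords.max() > 1.0:
        raise ParseError(
            f"{path}:{lineno}: normalized coordinates outside [0, 1]"
        )
    if cls_id not in class_map:
        raise ParseError(f"{path}:{lineno}: unmapped class id {cls_id}")
    corners = coords.reshape(4, 2) * np.array([width, height])
    return class_map[cls_id], corners, conf


def _frame_index_from_name(path: Path) -> int:
    m = re.search(r"(\d+)$", path.stem)
    if m is None:
        raise ParseError(f"{path}: no trailing frame index in filename")
    return int(m.group(1))


def read_obb_detections(
    source: str | Path,
    dialect: Literal["yolo_obb_txt", "long_csv"] = "yolo_obb_txt",
    image_size: tuple[float, float] | None = None,
    class_map: dict[int, str] | None = None,
) -> list[OBBDetection]:
    """Read OBB detections from label files or a long-format CSV.

    ``yolo_obb_txt``: *source* is a directory of one text file per frame,
    each line ``class x1 y1 x2 y2 x3 y3 x4 y4 [conf]`` with coordinates
    normalized to ``image_size = (width, height)``; the frame index is the
    trailing integer of the filename.  ``long_csv``: *source* is a CSV with
    header ``frame,class,x1,y1,...,x4,y4[,conf]`` already in pixels; the
    class column may hold integer ids (mapped through *class_map*) or the
    labels themselves.
    """
    source = Path(source)
    class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    detections: list[OBBDetection] = []

    if dialect == "yolo_obb_txt":
        if image_size is None:
            raise ParseError("yolo_obb_txt dialect requires image_size=(W, H)")
        width, height = image_size
        for path in sorted(source.glob("*.txt")):
            frame = _frame_index_from_name(path)
            for lineno, line in enumerate(path.read_text().splitlines(), start=1):
                if not line.strip():
                    continue
                label, corners, conf = _parse_yolo_line(
                    line, path, lineno, width, height, class_map
                )
                detections.append(OBBDetection(frame, label, corners, conf))
    elif dialect == "long_csv":
        try:
            table = pd.read_csv(source)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{source}: {exc}") from None
        needed = ["frame", "class"] + [f"{ax}{i}" for i in range(1, 5) for ax in "xy"]
        missing = [c for c in needed if c not in table.columns]
        if missing:
            raise ParseError(f"{source}: missing columns {missing}")
        for row_idx, row in table.iterrows():
            raw_cls = row["class"]
            if isinstance(raw_cls, str) and raw_cls in _VALID_LABELS:
                label = raw_cls
            else:
                try:
                    label = class_map[int(raw_cls)]
                except (KeyError, ValueError):
                    raise ParseError(
                        f"{source}: row {row_idx}: unknown class {raw_cls!r}"
                    ) from None
            corners = np.array(
                [[row[f"x{i}"], row[f"y{i}"]] for i in range(1, 5)], dtype=float
            )
            conf = float(row["conf"]) if "conf" in table.columns and pd.notna(
                row.get("conf")) else None
            try:
                detections.append(
                    OBBDetection(int(row["frame"]), label, corners, conf)
                )
            except ValidationError as exc:
                raise ParseError(f"{source}: row {row_idx}: {exc}") from None
    else:
        raise ParseError(f"unknown dialect {dialect!r}")

    detections.sort(key=lambda d: d.frame_index)
    return detections


# ---------------------------------------------------------------------------
# geometry

def axis_midpoints(box: OBBDetection) -> AxisEndpoints:
    """Bar-end estimates: midpoints of the two opposing longer sides.

    With corners P1..P4 consecutive, the adjacent side lengths are
    ``L1 = |P1-P2|`` and ``L2 = |P2-P3|``; the longer one is the bar's
    principal axis.  If ``L1 > L2`` the endpoints are ``(P1+P4)/2`` and
    ``(P2+P3)/2``, otherwise ``(P1+P2)/2`` and ``(P3+P4)/2`` (ties take the
    second branch).
    """
    p1, p2, p3, p4 = box.corners
    L1 = float(np.linalg.norm(p1 - p2))
    L2 = float(np.linalg.norm(p2 - p3))
    if L1 == 0.0 or L2 == 0.0:
        raise DegenerateGeometryError(
            f"frame {box.frame_index}: degenerate box with a zero-length side"
        )
    if L1 > L2:
        m1, m2 = (p1 + p4) / 2.0, (p2 + p3) / 2.0
    else:
        m1, m2 = (p1 + p2) / 2.0, (p3 + p4) / 2.0
    return AxisEndpoints(M1=m1, M2=m2, L1=L1, L2=L2)


def classify_ends(endpoints: AxisEndpoints) -> tuple[np.ndarray, np.ndarray]:
    """Split axis endpoints into (moving, fixed) by image height.

    Image coordinates grow downward, so the moving (pressed) end has the
    smaller image-y; an exact tie labels ``M2`` as moving.
    """
    if endpoints.M1[1] < endpoints.M2[1]:
        return endpoints.M1, endpoints.M2
    return endpoints.M2, endpoints.M1


def _frame_points(
    boxes: Sequence[OBBDetection],
) -> tuple[np.ndarray, np.ndarray] | None:
    """Reduce one frame's boxes to (moving_px, fixed_px), or None if unusable.

    Preference order: a pair of per-end marker boxes (centers used
    directly), else a whole-bar box (principal-axis midpoints).  The
    height rule is applied to marker centers as a consistency check;
    disagreement with the class labels logs a warning and trusts the rule.
    """
    markers = {b.class_label: b for b in boxes
               if b.class_label in ("moving_marker", "fixed_marker")}
    if len(markers) == 2:
        moving_c = markers["moving_marker"].center
        fixed_c = markers["fixed_marker"].center
        if moving_c[1] >= fixed_c[1]:
            logger.warning(
                "frame %d: class labels disagree with the height rule; "
                "re-classifying by image height",
                boxes[0].frame_index,
            )
            moving_c, fixed_c = (moving_c, fixed_c) if moving_c[1] < fixed_c[1] \
                else (fixed_c, moving_c)
        return moving_c, fixed_c
    bars = [b for b in boxes if b.class_label == "bar"]
    if bars:
        box = max(bars, key=lambda b: b.confidence if b.confidence is not None else 1.0)
        try:
            return classify_ends(axis_midpoints(box))
        except DegenerateGeometryError:
            logger.warning("frame %d: degenerate bar box skipped", box.frame_index)
            return None
    return None


def build_end_tracks(
    detections: Iterable[OBBDetection],
    fps: float,
    image_height: float,
    max_gap: int = 5,
) -> list[EndTrack]:
    """Assemble per-frame end points into contiguous tracks.

    Frames missing a usable detection create gaps: gaps of at most
    ``max_gap`` frames are filled by linear interpolation (flagged in
    ``gap_mask``); longer gaps split the recording into separate tracks,
    each analysed independently downstream.  Blocks with fewer than two
    frames are dropped; if nothing usable remains an
    :class:`InsufficientDataError` is raised.
    """
    by_frame: dict[int, list[OBBDetection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame_index, []).append(det)

    frames, moving, fixed = [], [], []
    for frame in sorted(by_frame):
        points = _frame_points(by_frame[frame])
        if points is not None:
            frames.append(frame)
            moving.append(points[0])
            fixed.append(points[1])
    if len(frames) < 2:
        raise InsufficientDataError(
            f"only {len(frames)} usable frames; need at least 2"
        )

    frames_arr = np.array(frames)
    moving_arr = np.array(moving)
    fixed_arr = np.array(fixed)

    # split into blocks wherever the frame gap exceeds max_gap
    split_at = np.where(np.diff(frames_arr) > max_gap + 1)[0] + 1
    tracks: list[EndTrack] = []
    for block in np.split(np.arange(len(frames_arr)), split_at):
        if len(block) < 2:
            continue
        f = frames_arr[block]
        dense = np.arange(f[0], f[-1] + 1)
        mov = np.column_stack([np.interp(dense, f, moving_arr[block, j])
                               for j in range(2)])
        fix = np.column_stack([np.interp(dense, f, fixed_arr[block, j])
                               for j in range(2)])
        mask = ~np.isin(dense, f)
        if mask.any():
            logger.warning(
                "interpolated %d dropped frame(s) in block %d-%d",
                int(mask.sum()), int(f[0]), int(f[-1]),
            )
        tracks.append(EndTrack(dense, mov, fix, fps, image_height, mask))
    if not tracks:
        raise InsufficientDataError(
            "no contiguous block with >= 2 frames after gap splitting"
        )
    return tracks


def calibrate(track: EndTrack, L_real: float) -> CalibratedTrajectory:
    """Convert a pixel track to metres in a y-up frame with origin at the pivot.

    The mean per-frame pixel distance between the two ends estimates the
    bar's pixel length; the scale factor is ``s = L_real / L_pixel``.  The
    pivot is the per-axis median of the fixed-end detections (robust to
    detector jitter), and the y axis is flipped so upward pressing gives
    increasing angle and positive velocity.
    """
    if L_real <= 0:
        raise ValidationError(f"L_real must be positive, got {L_real}")
    if len(track) == 0:
        raise InsufficientDataError("empty track")
    lengths = np.linalg.norm(track.moving_px - track.fixed_px, axis=1)
    L_pixel = float(lengths.mean())
    if L_pixel <= 0.0:
        raise DegenerateGeometryError("zero mean pixel bar length")
    s = L_real / L_pixel
    pivot_px = np.median(track.fixed_px, axis=0)
    x_m = s * (track.moving_px[:, 0] - pivot_px[0])
    y_m = s * (pivot_px[1] - track.moving_px[:, 1])   # flip: image y grows down
    t = track.frame_indices / track.fps
    return CalibratedTrajectory(
        t=np.asarray(t, dtype=float),
        moving_m=np.column_stack([x_m, y_m]),
        pivot_m=np.zeros(2),
        scale_s=s,
        L_pixel_mean=L_pixel,
        L_real=float(L_real),
        fps=track.fps,
        gap_mask=track.gap_mask.copy(),
    )
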
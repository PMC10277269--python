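"""Homography calibration and the "robot in reach of target" decision.

A one-time calibration estimates the 3×3 planar homography H between an
external (world / motion-capture) plane and the ultrasound image plane
from point correspondences, using the direct linear transformation (DLT)
with Hartley similarity normalization. Once calibrated, candidate needle
trajectories — one straight line per mechanically available holder angle
— are mapped into the image frame, and a detected target box is declared
*in reach* if some trajectory passes within a tolerance of its center at
a depth the needle can cover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Annotation
from .errors import (
    DegenerateConfigurationError,
    ProjectionError,
    UnderdeterminedError,
)

__all__ = [
    "Homography",
    "PointPair",
    "HolderGeometry",
    "RigidTransform2D",
    "ReachDecision",
    "estimate_homography",
    "project",
    "predict_tip_trajectories",
    "in_reach",
    "reprojection_rmse",
    "read_pairs_csv",
    "write_pairs_csv",
]


@dataclass
class PointPair:
    """A world-plane / image-plane point correspondence."""

    world: tuple[float, float]  # (X, Y) mm in the external plane
    image: tuple[float, float]  # (u, v) px or mm in the US frame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.world + self.image)):
            raise ValueError("coordinates must be finite")


@dataclass
class Homography:
    """A 3×3 projective map, defined up to scale.

    Normalized so the bottom-right entry is 1 whenever it is nonzero.
    """

    matrix: np.ndarray
    frame_from: str = "world"
    frame_to: str = "image"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(m)) < 1e-14 * max(np.abs(m).max(), 1.0) ** 3:
            raise DegenerateConfigurationError("homography must be invertible")
        if abs(m[2, 2]) > 1e-12:
            m = m / m[2, 2]
        self.matrix = m

    def inverse(self) -> "Homography":
        return Homography(
            np.linalg.inv(self.matrix), self.frame_to, self.frame_from
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix": self.matrix.tolist(),
                    "frame_from": self.frame_from,
                    "frame_to": self.frame_to,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Homography":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["matrix"]), d["frame_from"], d["frame_to"])


@dataclass
class RigidTransform2D:
    """Rotation (degrees) plus translation in the plane."""

    angle_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def apply(self, p: np.ndarray) -> np.ndarray:
        a = np.radians(self.angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return p @ rot.T + np.asarray(self.translation)


@dataclass
class HolderGeometry:
    """Mechanical options of the needle holder.

    The holder offers a discrete set of in-plane insertion angles; the
    needle pivot sits at a fixed rigid offset from the US frame origin.
    """

    available_angles_deg: tuple[float, ...] = (40.0, 45.0, 50.0, 55.0, 60.0)
    needle_length_mm: float = 200.0
    mount_offset: RigidTransform2D = field(default_factory=RigidTransform2D)

    def __post_init__(self) -> None:
        if not all(0 < a < 90 for a in self.available_angles_deg):
            raise ValueError("holder angles must lie in (0, 90) degrees")
        if self.needle_length_mm <= 0:
            raise ValueError("needle length must be positive")


@dataclass
class ReachDecision:
    reachable: bool
    best_angle_deg: float
    depth_mm: float
    miss_distance: float


def _normalization(points: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid to origin, mean distance sqrt(2)."""
    c = points.mean(axis=0)
    d = np.linalg.norm(points - c, axis=1).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    return np.array(
        [[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]]
    )


def estimate_homography(pairs: list[PointPair]) -> Homography:
    """DLT homography from >= 4 world/image correspondences.

    Both point sets are similarity-normalized before building the 2n×9
    design matrix; the solution is the right singular vector of the
    smallest singular value, denormalized afterwards. Noiseless pairs
    generated by a true homography are recovered to ~1e-8 relative
    error; near-degenerate (collinear) configurations raise.
    """
    if len(pairs) < 4:
        raise UnderdeterminedError(
            f"need at least 4 point pairs, got {len(pairs)}"
        )
    world = np.asarray([p.world for p in pairs], dtype=float)
    image = np.asarray([p.image for p in pairs], dtype=float)
    t_w = _normalization(world)
    t_i = _normalization(image)
    wh = np.column_stack([world, np.ones(len(world))]) @ t_w.T
    ih = np.column_stack([image, np.ones(len(image))]) @ t_i.T

    rows = []
    for (X, Y, W), (u, v, w) in zip(wh, ih):
        rows.append([0, 0, 0, -w * X, -w * Y, -w * W, v * X, v * Y, v * W])
        rows.append([w * X, w * Y, w * W, 0, 0, 0, -u * X, -u * Y, -u * W])
    a = np.asarray(rows)
    _, s, vt = np.linalg.svd(a)
    # with >= 4 generic pairs the nullspace is 1D; a (near-)2D nullspace
    # signals a degenerate point configuration
    if s[-2] < 1e-9 * s[0]:
        raise DegenerateConfigurationError(
            "point configuration is degenerate (collinear or coincident)"
        )
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_i) @ h_norm @ t_w
    return Homography(h, "world", "image")


def project(h: Homography, p) -> np.ndarray:
    """Apply the homography to one 2D point (homogeneous multiply)."""
    v = h.matrix @ np.array([p[0], p[1], 1.0])
    if abs(v[2]) < 1e-12 * max(1.0, np.abs(v[:2]).max()):
        raise ProjectionError(f"point {tuple(p)} maps to infinity")
    return v[:2] / v[2]


def project_many(h: Homography, pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ h.matrix.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ProjectionError("a point maps to infinity")
    return hom[:, :2] / w[:, None]


def predict_tip_trajectories(
    h: Homography,
    holder: HolderGeometry,
    robot_pose: RigidTransform2D | None = None,
    n_samples: int = 100,
    image_bounds: tuple[float, float, float, float] | None = None,
) -> dict[float, dict]:
    """Candidate needle-tip trajectories in the image frame.

    For each available holder angle, sample the straight world-frame
    line from the pivot over the needle length and map it through the
    homography. Returns per angle a dict with the projected ``points``
    (n, 2), the world-frame ``depth_mm`` of each sample along the
    needle, and an ``outside`` flag when ``image_bounds``
    (x0, y0, x1, y1) are given and no sample falls inside; flagged
    trajectories are kept, not dropped.
    """
    pose = robot_pose or RigidTransform2D()
    pivot = pose.apply(holder.mount_offset.apply(np.zeros((1, 2))))[0]
    depths = np.linspace(0.0, holder.needle_length_mm, n_samples)
    out: dict[float, dict] = {}
    for angle in holder.available_angles_deg:
        a = np.radians(angle)
        d_local = np.array([np.cos(a), np.sin(a)])
        rot = np.radians(pose.angle_deg)
        rotm = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        d_world = rotm @ d_local
        world_pts = pivot[None, :] + depths[:, None] * d_world[None, :]
        img_pts = project_many(h, world_pts)
        outside = False
        if image_bounds is not None:
            x0, y0, x1, y1 = image_bounds
            inside = (
                (img_pts[:, 0] >= x0)
                & (img_pts[:, 0] <= x1)
                & (img_pts[:, 1] >= y0)
                & (img_pts[:, 1] <= y1)
            )
            outside = not bool(inside.any())
        out[angle] = {
            "points": img_pts,
            "depth_mm": depths,
            "outside": outside,
        }
    return out


def in_reach(
    target_bbox: Annotation,
    trajectories: dict[float, dict],
    tolerance: float,
) -> ReachDecision:
    """Decide whether some holder angle brings the needle tip to the target.

    The target point is the bounding-box center. Reachable iff a
    trajectory sample within the needle length passes within
    ``tolerance`` (same units as the trajectory points) of it; the best
    angle minimizes the miss distance, ties broken toward the smaller
    angle.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not trajectories:
        raise ValueError("trajectory set must be nonempty")
    x, y, w, hgt = target_bbox.bbox
    center = np.array([x + w / 2.0, y + hgt / 2.0])
    best_angle, best_miss, best_depth = None, np.inf, np.nan
    for angle in sorted(trajectories):
        traj = trajectories[angle]
        d = np.linalg.norm(traj["points"] - center, axis=1)
        i = int(np.argmin(d))
        if d[i] < best_miss - 1e-12:
            best_angle, best_miss = angle, float(d[i])
            best_depth = float(traj["depth_mm"][i])
    return ReachDecision(
        reachable=bool(best_miss <= tolerance),
        best_angle_deg=float(best_angle),
        depth_mm=best_depth,
        miss_distance=best_miss,
    )


def reprojection_rmse(h: Homography, pairs: list[PointPair]) -> float:
    """RMSE of world-frame residuals after mapping image points back
    through the inverse homography (units of the world frame, mm)."""
    if not pairs:
        raise ValueError("pairs must be nonempty")
    world = np.asarray([p.world for p in pairs], dtype=float)
    image = np.asarray([p.image for p in pairs], dtype=float)
    back = project_many(h.inverse(), image)
    return float(np.sqrt(np.mean(np.sum((back - world) ** 2, axis=1))))


def write_pairs_csv(pairs: list[PointPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "world_x_mm": p.world[0],
                "world_y_mm": p.world[1],
                "img_u": p.image[0],
                "img_v": p.image[1],
            }
            for p in pairs
        ]
    ).to_csv(path, index=False)


def read_pairs_csv(path: str | Path) -> list[PointPair]:
    df = pd.read_csv(path)
    return [
        PointPair((r.world_x_mm, r.world_y_mm), (r.img_u, r.img_v))
        for r in df.itertuples()
    ]
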
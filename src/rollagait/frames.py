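"""2-D rigid transforms and the rollator's static frame graph.

The rollator carries several sensors, each with its own coordinate frame.
All frames are expressed as static poses relative to ``base_footprint``,
the point on the ground midway between the rear wheels.  Convention:
x points in the rollator's forward direction of travel, y to its left,
angles counter-clockwise.  The walking user is behind the frame, at x < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform2D",
    "FrameGraph",
    "FrameLookupError",
    "default_frame_graph",
    "transform_points",
    "BASE_FRAME",
]

BASE_FRAME = "base_footprint"


class FrameLookupError(KeyError):
    """Raised when a requested frame is not in the graph."""


@dataclass(frozen=True)
class RigidTransform2D:
    """Planar rigid motion: rotation by ``theta`` followed by translation."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 2) array (or a single (2,) point)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        c, s = math.cos(self.theta), math.sin(self.theta)
        out = np.empty_like(pts)
        out[:, 0] = c * pts[:, 0] - s * pts[:, 1] + self.x
        out[:, 1] = s * pts[:, 0] + c * pts[:, 1] + self.y
        return out[0] if single else out

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return self o other (``other`` applied first)."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        return RigidTransform2D(
            x=c * other.x - s * other.y + self.x,
            y=s * other.x + c * other.y + self.y,
            theta=self.theta + other.theta,
        )

    def inverse(self) -> "RigidTransform2D":
        c, s = math.cos(self.theta), math.sin(self.theta)
        return RigidTransform2D(
            x=-(c * self.x + s * self.y),
            y=-(-s * self.x + c * self.y),
            theta=-self.theta,
        )

    @staticmethod
    def identity() -> "RigidTransform2D":
        return RigidTransform2D()


class FrameGraph:
    """Static frames, each stored as its pose in ``base_footprint``.

    ``pose_in_base[f]`` maps points expressed in frame ``f`` to base
    coordinates.  ``base_footprint`` itself is always the identity.
    """

    def __init__(self, poses: dict[str, RigidTransform2D] | None = None):
        self._poses: dict[str, RigidTransform2D] = {
            BASE_FRAME: RigidTransform2D.identity()
        }
        if poses:
            for name, tf in poses.items():
                self._poses[name] = tf
        # base_footprint must stay the identity even if the caller passed one
        self._poses[BASE_FRAME] = RigidTransform2D.identity()

    @property
    def frames(self) -> list[str]:
        return list(self._poses)

    def pose(self, frame: str) -> RigidTransform2D:
        try:
            return self._poses[frame]
        except KeyError:
            raise FrameLookupError(f"unknown frame {frame!r}") from None

    def transform(self, from_frame: str, to_frame: str) -> RigidTransform2D:
        """Transform taking points in ``from_frame`` to ``to_frame``."""
        return self.pose(to_frame).inverse().compose(self.pose(from_frame))

    def to_dict(self) -> dict:
        return {
            name: {"xy": [tf.x, tf.y], "theta": tf.theta}
            for name, tf in self._poses.items()
        }

    @staticmethod
    def from_dict(d: dict) -> "FrameGraph":
        return FrameGraph(
            {
                name: RigidTransform2D(spec["xy"][0], spec["xy"][1], spec["theta"])
                for name, spec in d.items()
            }
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, FrameGraph) and self._poses == other._poses


def transform_points(
    points: np.ndarray, from_frame: str, to_frame: str, graph: FrameGraph
) -> np.ndarray:
    """Re-express (n, 2) points from one frame in another.

    Rigid, so pairwise distances are preserved.  Unknown frames raise
    :class:`FrameLookupError`.
    """
    return graph.transform(from_frame, to_frame).apply(points)


def default_frame_graph() -> FrameGraph:
    """Nominal sensor placement for a standard rollator frame.

    Laser under the lower front pole, handles above and behind the rear
    axle, wheels on the rear axle (0.55 m apart).  All positions are
    overridable through the session's ``frames.json``.
    """
    return FrameGraph(
        {
            "laser": RigidTransform2D(0.30, 0.0, 0.0),
            "left_handle": RigidTransform2D(-0.20, 0.25, 0.0),
            "right_handle": RigidTransform2D(-0.20, -0.25, 0.0),
            "left_wheel": RigidTransform2D(0.0, 0.275, 0.0),
            "right_wheel": RigidTransform2D(0.0, -0.275, 0.0),
        }
    )
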
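"""Ellipse geometry helpers shared by the generator and the preprocessor.

Conventions (fixed for reproducibility): pixel coordinates are 0-based with
x along columns (rightward) and y along rows (downward); angles are in
degrees measured from the +x axis toward +y, restricted to (-90, 90] for the
undirected major axis.  Axis lengths are *full* axis lengths, defined from
second-order central moments of the solid region so that a filled ellipse
with semi-axes (a, b) yields major = 2a and minor = 2b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BodyEllipse:
    """Fitted body-column ellipse, optionally with head/foot polarity.

    ``head_end`` is a unit vector along the major axis pointing toward the
    tentacle/mouth end, or ``None`` before polarity is resolved.
    """

    centroid: tuple[float, float]       # (x, y)
    major_axis: float
    minor_axis: float
    orientation: float                  # degrees, (-90, 90]
    head_end: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")
        if not (-90.0 < self.orientation <= 90.0):
            raise ValueError("orientation must lie in (-90, 90] degrees")

    @property
    def axis_vector(self) -> np.ndarray:
        t = np.deg2rad(self.orientation)
        return np.array([np.cos(t), np.sin(t)])

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Major-axis endpoints, (x, y) each."""
        c = np.asarray(self.centroid, float)
        half = 0.5 * self.major_axis * self.axis_vector
        return c + half, c - half


def wrap_angle_deg(angle: float) -> float:
    """Map an axis angle to the canonical (-90, 90] degree interval."""
    a = (angle + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def ellipse_from_moments(mask: np.ndarray) -> BodyEllipse:
    """Moment-based ellipse fit to a binary region.

    Uses the eigen-decomposition of the second-order central moment matrix;
    full axis lengths are 4 sqrt(eigenvalue), the solid-ellipse relation.
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array(
        [[np.mean(dx * dx), np.mean(dx * dy)], [np.mean(dx * dy), np.mean(dy * dy)]]
    )
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor = 4.0 * np.sqrt(max(evals[0], 1e-12))
    major = 4.0 * np.sqrt(max(evals[1], 1e-12))
    vx, vy = evecs[:, 1]
    angle = wrap_angle_deg(np.rad2deg(np.arctan2(vy, vx)))
    return BodyEllipse((cx, cy), float(major), float(minor), float(angle))


def angle_difference_deg(a: float, b: float) -> float:
    """Smallest absolute difference between two undirected axis angles."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
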
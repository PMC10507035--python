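"""Small rigid-body geometry helpers shared by fixtures and selection."""

from __future__ import annotations

import numpy as np

__all__ = ["rotation_x", "rotation_z", "tilt_twist_matrix", "principal_axis"]


def rotation_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def tilt_twist_matrix(tilt_deg: float, twist_deg: float) -> np.ndarray:
    """Twist about the molecular z axis, then tilt about the lab x axis.

    With this order a pure twist (tilt = 0) is an azimuthal rotation,
    under which azimuthally averaged spectra are invariant, while the
    twist selects which face of the molecule meets the interface once
    tilted.
    """
    return rotation_x(np.deg2rad(tilt_deg)) @ rotation_z(np.deg2rad(twist_deg))


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant axis (unit vector) of a point cloud via SVD; sign fixed so
    the axis points from the first toward the last point."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)
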
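"""Axial-angle helpers.

Fiber orientations are undirected (axial) quantities on [0, 180) degrees.
All differences are taken modulo 180 and folded to [0, 90].
"""

from __future__ import annotations

import numpy as np


def wrap_axial(deg: np.ndarray | float) -> np.ndarray | float:
    """Map an angle in degrees onto the axial interval [0, 180)."""
    return np.mod(deg, 180.0)


def axial_difference(a_deg, b_deg):
    """Acute difference between two axial angles, in [0, 90] degrees."""
    d = np.abs(np.mod(np.asarray(a_deg, dtype=float) - b_deg, 180.0))
    return np.minimum(d, 180.0 - d)


def axial_mean_resultant_length(deg: np.ndarray) -> float:
    """Mean resultant length of axial data (angles doubled before averaging).

    1 for perfectly aligned orientations, ~0 for isotropic ones.
    """
    theta = 2.0 * np.deg2rad(np.asarray(deg, dtype=float))
    return float(np.hypot(np.mean(np.cos(theta)), np.mean(np.sin(theta))))


def principal_axis_deg(points: np.ndarray) -> float:
    """Principal-axis orientation of a 2-D point cloud, in [0, 180).

    Points are (row, col); the returned angle is measured from the +col
    axis toward +row, matching image conventions used throughout.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    # 2x2 scatter eigenvector via the closed form for symmetric matrices
    srr = np.sum(centered[:, 0] ** 2)
    scc = np.sum(centered[:, 1] ** 2)
    src = np.sum(centered[:, 0] * centered[:, 1])
    angle = 0.5 * np.arctan2(2.0 * src, scc - srr)
    return float(wrap_axial(np.rad2deg(angle)))
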
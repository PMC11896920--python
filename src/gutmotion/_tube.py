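"""Tube-coordinate frame around a centerline.

Maps arbitrary world points to (arc length ``s``, radial distance ``r``)
coordinates of the nearest point on a densely resampled centerline.
Shared by the phantom generator (to paint and advect the lumen), the
registration ROI (distance-to-polyline test) and the ground-truth
deformation oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import resample_centerline


class TubeFrame:
    """Dense polyline with fast nearest-point projection."""

    def __init__(self, points: np.ndarray, step: float = 0.25):
        cl = resample_centerline(points, step)
        self.points = cl.points
        self.arcs = cl.arc_lengths
        self.tangents = cl.tangents
        self.length = cl.length
        self._tree = cKDTree(self.points)

    def project(self, x: np.ndarray):
        """Project world points onto the polyline.

        Returns ``(s, r, foot, idx)``: arc length of the projection
        (clipped to [0, length]), radial distance, foot point, and the
        index of the nearest dense vertex (whose tangent approximates
        the local tangent).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _, idx = self._tree.query(x)
        p = self.points[idx]
        t = self.tangents[idx]
        ds = np.einsum("ij,ij->i", x - p, t)
        s = np.clip(self.arcs[idx] + ds, 0.0, self.length)
        foot = p + (s - self.arcs[idx])[:, None] * t
        r = np.linalg.norm(x - foot, axis=1)
        return s, r, foot, idx

    def distance(self, x: np.ndarray) -> np.ndarray:
        """Distance from world points to the polyline (mm)."""
        return self.project(x)[1]

    def point_at(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        return np.column_stack([np.interp(s, self.arcs, self.points[:, k]) for k in range(3)])

    def tangent_at(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        t = np.column_stack([np.interp(s, self.arcs, self.tangents[:, k]) for k in range(3)])
        return t / np.linalg.norm(t, axis=1, keepdims=True)
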
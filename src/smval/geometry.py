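"""Axon skeleton geometry container shared by the generator and morphometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AxonGeometry:
    """One myelinated axon as an ordered 3d centerline with per-point
    cross-sectional area and myelin sheath thickness.

    ``points`` are micrometers; ``area`` is the cross-sectional area A(z) in
    um^2 of the slice perpendicular to the skeleton; ``myelin_thickness`` is
    the sheath thickness in um (outer radius = inner radius + thickness).
    """

    points: np.ndarray                 # (n, 3) um
    area: np.ndarray                   # (n,) um^2
    myelin_thickness: np.ndarray       # (n,) um
    main_direction: np.ndarray | None = field(default=None)
    axon_id: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.myelin_thickness = np.asarray(self.myelin_thickness, dtype=float)
        n = len(self.points)
        if n < 2:
            raise ValueError("axon needs at least 2 centerline points")
        if len(self.area) != n or len(self.myelin_thickness) != n:
            raise ValueError("area/myelin arrays must match the point count")
        if np.any(self.area <= 0):
            raise ValueError("all cross-sectional areas must be > 0")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive centerline points must be distinct")

    # -- derived geometry ---------------------------------------------------

    def segments(self) -> np.ndarray:
        return np.diff(self.points, axis=0)

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segments(), axis=1)

    def tangents(self) -> np.ndarray:
        """Unit tangent per segment."""
        seg = self.segments()
        return seg / np.linalg.norm(seg, axis=1, keepdims=True)

    def arc_length(self) -> float:
        """Geodesic length along the centerline (um)."""
        return float(self.segment_lengths().sum())

    def euclidean_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def segment_areas(self) -> np.ndarray:
        """Mid-segment cross-sectional areas."""
        return 0.5 * (self.area[:-1] + self.area[1:])

    def intra_volume(self) -> float:
        """Intra-axonal volume: integral of A along the centerline (um^3)."""
        return float(np.sum(self.segment_areas() * self.segment_lengths()))

    def myelin_volume(self) -> float:
        """Myelin annulus volume along the centerline (um^3)."""
        r_in = np.sqrt(self.area / np.pi)
        r_out = r_in + self.myelin_thickness
        ann = np.pi * (r_out**2 - r_in**2)
        ann_mid = 0.5 * (ann[:-1] + ann[1:])
        return float(np.sum(ann_mid * self.segment_lengths()))

    def diameters(self) -> np.ndarray:
        """Equivalent-circle diameter 2r = 2*sqrt(A/pi) per point (um)."""
        return 2.0 * np.sqrt(self.area / np.pi)


def rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ direction = z-hat (Rodrigues)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(d, z)
    c = float(d @ z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def weighted_mean_direction(tangents: np.ndarray,
                            weights: np.ndarray) -> np.ndarray:
    """Length-weighted mean tangent of an ordered centerline, normalized.

    For per-segment tangents weighted by segment length this is the
    end-to-end (secant) direction of the axon.  Tangents are taken as
    ordered (consistently signed); no antipodal canonicalization is applied
    beyond fixing the overall sign to the +z hemisphere.
    """
    t = np.asarray(tangents, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = (t * w[:, None]).sum(axis=0)
    nrm = np.linalg.norm(m)
    if nrm == 0:
        raise ValueError("degenerate tangent set")
    m = m / nrm
    if m[2] < 0 or (m[2] == 0 and m[1] < 0):
        m = -m
    return m


def principal_direction(tangents: np.ndarray,
                        weights: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the length-weighted tangent outer-product
    sum; the population main axis."""
    t = np.asarray(tangents, dtype=float)
    w = np.asarray(weights, dtype=float)
    T = (t.T * w) @ t
    _, vecs = np.linalg.eigh(T)
    v = vecs[:, -1]
    if v[2] < 0 or (v[2] == 0 and v[1] < 0):
        v = -v
    return v
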
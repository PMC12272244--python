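"""Triangulated unit sphere used for orientation histograms.

The fiber-orientation histogram lives on a subdivided icosahedron.  Each face
is one bin; the bin direction is the normalized face centroid and the bin
solid angle is the face area rescaled so that the whole mesh covers exactly
4*pi.  Antipodal symmetry is imposed by averaging each bin with the bin
nearest to its antipode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SphereMesh:
    """Icosphere bin structure for spherical histograms."""

    centers: np.ndarray        # (n_bins, 3) unit bin directions
    solid_angles: np.ndarray   # (n_bins,) bin solid angles, sum = 4*pi
    antipode: np.ndarray       # (n_bins,) index of the antipodal bin
    _tree: cKDTree = field(repr=False, compare=False, default=None)

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def assign(self, directions: np.ndarray) -> np.ndarray:
        """Index of the bin whose center is nearest to each unit direction."""
        directions = np.atleast_2d(directions)
        _, idx = self._tree.query(directions)
        return idx


@lru_cache(maxsize=4)
def icosphere_mesh(subdivisions: int = 4) -> SphereMesh:
    """Build the face-bin structure of a subdivided icosahedron.

    ``subdivisions=4`` gives 2562 vertices / 5120 faces, the default working
    resolution for orientation histograms.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    centers = mesh.triangles_center
    centers = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    areas = mesh.area_faces.copy()
    solid = areas * (4.0 * np.pi / areas.sum())
    tree = cKDTree(centers)
    _, antipode = tree.query(-centers)
    return SphereMesh(centers=centers, solid_angles=solid, antipode=antipode,
                      _tree=tree)


@dataclass
class SphericalHistogram:
    """Orientation density on the icosphere bins.

    ``density`` is the FOD value P per bin in the dOmega/(4*pi) convention:
    sum(density * solid_angle) / (4*pi) == 1 for a normalized histogram.
    """

    mesh: SphereMesh
    density: np.ndarray

    @property
    def mass(self) -> float:
        return float(np.sum(self.density * self.mesh.solid_angles) / (4 * np.pi))

    def normalize(self) -> "SphericalHistogram":
        m = self.mass
        if m <= 0:
            raise ValueError("histogram has no mass")
        return SphericalHistogram(self.mesh, self.density / m)

    def symmetrize(self) -> "SphericalHistogram":
        d = 0.5 * (self.density + self.density[self.mesh.antipode])
        return SphericalHistogram(self.mesh, d)


def histogram_from_directions(
    directions: np.ndarray,
    weights: np.ndarray | None = None,
    subdivisions: int = 4,
) -> SphericalHistogram:
    """Bin unit vectors into a normalized, antipodally symmetric histogram.

    Parameters
    ----------
    directions : (n, 3) unit vectors (sign is irrelevant).
    weights : optional per-vector weights (e.g. segment lengths).
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.size == 0:
        raise ValueError("no directions to histogram")
    mesh = icosphere_mesh(subdivisions)
    idx = mesh.assign(directions)
    if weights is None:
        weights = np.ones(len(directions))
    counts = np.bincount(idx, weights=weights, minlength=mesh.n_bins)
    density = counts / mesh.solid_angles
    hist = SphericalHistogram(mesh, density).symmetrize()
    return hist.normalize()


def uniform_hemisphere(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Quasi-uniform directions on the half-sphere by electrostatic repulsion.

    Antipodal (charge-pair) repulsion on random initial points; used to build
    acquisition direction sets.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # canonical hemisphere: z >= 0 (tie-break on y, x)
    flip = (pts[:, 2] < 0) | ((pts[:, 2] == 0) & (pts[:, 1] < 0))
    pts[flip] *= -1
    return pts
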
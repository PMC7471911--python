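"""Greedy sphere packing of a watertight mesh.

The bone volume is represented by non-overlapping spheres ("sphere packing"):
contact queries against a rotating hemispherical tool then reduce to
sphere-sphere tests, which is what makes a 1 kHz haptic loop feasible.
Non-overlap matters beyond speed — the aggregate surface normal is only a
reasonable approximation when no geometric feature is counted twice.

The packer is greedy largest-first: candidate centers are sampled on a
jittered grid inside the mesh, each candidate's admissible radius is the
minimum of the radius cap, its distance to the mesh surface and its clearance
from already placed spheres, and the largest admissible sphere is placed
repeatedly until nothing of at least ``min_radius`` fits.  Densities start
uniform; calibration reshapes them later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import ParameterError, ValidationError
from .meshquery import MeshQuery

#: slack allowed by the pairwise non-overlap invariant [mm]
OVERLAP_TOLERANCE = 1e-6

#: uniform density every packing starts from (the calibration reference)
REFERENCE_DENSITY = 1.0


@dataclass
class SpherePacking:
    """Non-overlapping spheres (center, radius, density) filling a mesh."""

    centers: np.ndarray  # (n, 3) mm
    radii: np.ndarray  # (n,) mm
    densities: np.ndarray  # (n,) dimensionless >= 0
    min_radius: float = 0.0
    reference_density: float = REFERENCE_DENSITY
    mesh: Optional[trimesh.Trimesh] = None
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.densities = np.asarray(self.densities, dtype=float).reshape(-1)
        if not (len(self.centers) == len(self.radii) == len(self.densities)):
            raise ValidationError("centers, radii and densities must align")
        if np.any(self.radii < 0) or np.any(self.densities < 0):
            raise ValidationError("radii and densities must be non-negative")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.centers) if len(self) else cKDTree(np.zeros((1, 3)))
        return self._tree

    def total_volume(self) -> float:
        """Sum of sphere volumes [mm^3]."""
        return float(np.sum(4.0 / 3.0 * np.pi * self.radii ** 3))

    def copy(self) -> "SpherePacking":
        return SpherePacking(self.centers.copy(), self.radii.copy(),
                             self.densities.copy(), self.min_radius,
                             self.reference_density, self.mesh)

    def with_spheres(self, centers, radii, densities) -> "SpherePacking":
        return SpherePacking(centers, radii, densities, self.min_radius,
                             self.reference_density, self.mesh)

    def overlap_violations(self, tolerance: float = OVERLAP_TOLERANCE) -> int:
        """Number of sphere pairs violating non-overlap (exhaustive sweep)."""
        n = len(self)
        if n < 2:
            return 0
        violations = 0
        pairs = self.tree.query_pairs(2.0 * float(self.radii.max()), output_type="ndarray")
        for i, j in pairs:
            gap = np.linalg.norm(self.centers[i] - self.centers[j]) - self.radii[i] - self.radii[j]
            if gap < -tolerance:
                violations += 1
        return violations


def pack_mesh(mesh: trimesh.Trimesh, min_radius: float, max_radius: float,
              seed: int = 0, grid_jitter: float = 0.3) -> SpherePacking:
    """Fill a watertight mesh with non-overlapping spheres, largest first.

    Candidates come from a regular grid of pitch ``min_radius`` (aligned on
    the bounding-box center so symmetric optima are representable) plus a
    jittered copy of that grid.  Every placed sphere's radius uses the exact
    point-to-surface distance, so spheres never protrude through the mesh.

    Raises if the mesh is open or if not even one sphere of ``min_radius``
    fits (``min_radius`` above the mesh inradius).
    """
    if not (0.0 < min_radius <= max_radius):
        raise ParameterError("need 0 < min_radius <= max_radius")
    if not mesh.is_watertight:
        raise ValidationError("mesh must be watertight")
    rng = np.random.default_rng(seed)
    query = MeshQuery(mesh)

    lo, hi = mesh.bounds
    center = 0.5 * (lo + hi)
    pitch = float(min_radius)
    half_counts = np.ceil((hi - lo) / (2.0 * pitch)).astype(int)
    axes = [center[k] + pitch * np.arange(-half_counts[k], half_counts[k] + 1)
            for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    jittered = grid + rng.uniform(-grid_jitter, grid_jitter, grid.shape) * pitch
    candidates = np.vstack([grid, jittered])

    # cheap conservative prefilter: distance to surface samples is an upper
    # bound on the true surface distance, so it can only over-admit
    n_samples = max(20_000, 8 * len(mesh.faces))
    surface_pts = trimesh.sample.sample_surface(mesh, n_samples, seed=int(seed))[0]
    surf_tree = cKDTree(surface_pts)
    upper = np.minimum(surf_tree.query(candidates)[0], max_radius)
    keep = upper >= min_radius
    candidates, upper = candidates[keep], upper[keep]
    if len(candidates) == 0:
        raise ParameterError("min_radius exceeds the mesh inradius: empty packing")

    inside = query.contains(candidates)
    candidates = candidates[inside]
    upper = upper[inside]
    if len(candidates) == 0:
        raise ParameterError("min_radius exceeds the mesh inradius: empty packing")

    # 'avail' is an upper bound on the admissible radius; it is replaced by
    # the exact surface distance lazily, the first time a candidate wins.
    # Placements only affect candidates within r + max_radius, so updates go
    # through a KD-tree neighborhood instead of the full candidate set.
    avail = upper.copy()
    exact = np.zeros(len(candidates), dtype=bool)
    cand_tree = cKDTree(candidates)
    centers, radii = [], []
    while True:
        i = int(np.argmax(avail))
        best = avail[i]
        if best < min_radius - 1e-9:
            break
        if not exact[i]:
            true_dist = float(query.surface_distance(candidates[i:i + 1])[0])
            avail[i] = min(avail[i], true_dist)
            exact[i] = True
            continue  # re-rank with the exact value
        c, r = candidates[i], float(best)
        centers.append(c)
        radii.append(r)
        near = cand_tree.query_ball_point(c, r + max_radius)
        near = np.asarray(near, dtype=int)
        gap = np.linalg.norm(candidates[near] - c, axis=1) - r
        avail[near] = np.minimum(avail[near], gap)

    if not centers:
        raise ParameterError("min_radius exceeds the mesh inradius: empty packing")
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    return SpherePacking(centers=centers, radii=radii,
                         densities=np.full(len(radii), REFERENCE_DENSITY),
                         min_radius=min_radius, mesh=mesh)
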
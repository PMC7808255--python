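"""Solvent-accessible surface area and solvent-accessible volume.

Surface area uses the Shrake–Rupley numerical scheme: quasi-uniform test
points on each atom's solvent-expanded sphere, counting the fraction not
occluded by any neighbour. Volume is the region enclosed by the
solvent-accessible surface, measured on a regular grid: voxels whose centre
lies within ``r_vdw + probe`` of any atom, plus interior voxels a solvent
flood fill from the box boundary cannot reach.

Both computations follow the heavy-atom convention: hydrogens and waters
are dropped, metals kept, and the pinned van-der-Waals radii of
:mod:`tyrcav.structure_io` are used throughout. Because every downstream
statistic consumes *differences* of these metrics between paired
structures, the absolute calibration of the estimators matters less than
their determinism, which is exact here (no random number generation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "SurfaceReport",
    "VolumeReport",
    "sasa",
    "accessible_volume",
    "sphere_points",
    "occupancy_grid",
]


@dataclass(frozen=True, slots=True)
class SurfaceReport:
    """Shrake–Rupley surface area result."""

    total_area: float
    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int


@dataclass(frozen=True, slots=True)
class VolumeReport:
    """Grid estimate of the volume enclosed by the accessible surface."""

    total_volume: float
    grid_spacing: float
    probe_radius: float


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic construction — no RNG — so areas are bit-reproducible.
    """
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SurfaceReport:
    """Solvent-accessible surface area by the Shrake–Rupley method.

    Parameters
    ----------
    structure:
        Input structure; hydrogens and waters are ignored.
    probe_radius:
        Solvent probe radius in Å (water ≈ 1.4 Å).
    n_sphere_points:
        Test points per atom; 960 keeps the discretisation error on
        protein-sized inputs under ~2% relative to a 4000-point run.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points <= 0:
        raise ValueError("n_sphere_points must be positive")
    heavy = structure.heavy_atoms()
    xyz = heavy.coordinates
    radii = heavy.radii + probe_radius
    n_atoms = len(heavy)

    unit = sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    areas = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = xyz[i] + radii[i] * unit
        # neighbours whose expanded sphere could occlude any test point
        nbrs = tree.query_ball_point(xyz[i], radii[i] + max_r)
        nbrs = [j for j in nbrs if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            exposed &= d2 >= radii[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return SurfaceReport(
        total_area=float(areas.sum()),
        per_atom_area=areas,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def occupancy_grid(
    xyz: np.ndarray,
    radii: np.ndarray,
    spacing: float,
    padding: float,
    extra_radius: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean grid of voxels whose centre lies within ``r_i + extra`` of atom i.

    Returns ``(grid, origin)`` where ``origin`` is the coordinate of voxel
    (0,0,0)'s centre. The grid covers the atom bounding box padded by
    ``padding`` on every side. Shared by the volume and cavity engines.
    """
    lo = xyz.min(axis=0) - padding
    hi = xyz.max(axis=0) + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > 150_000_000:
        raise ValueError(
            "voxel grid exceeds budget; increase grid spacing"
        )
    grid = np.zeros(shape, dtype=bool)
    eff = radii + extra_radius
    # per-atom local subgrid marking, vectorised over the subgrid
    for center, r in zip(xyz, eff):
        if r <= 0:
            continue
        imin = np.floor((center - r - lo) / spacing).astype(int)
        imax = np.ceil((center + r - lo) / spacing).astype(int)
        imin = np.maximum(imin, 0)
        imax = np.minimum(imax, shape - 1)
        if np.any(imin > imax):
            continue
        ax = [lo[k] + spacing * np.arange(imin[k], imax[k] + 1) for k in range(3)]
        dx2 = (ax[0] - center[0]) ** 2
        dy2 = (ax[1] - center[1]) ** 2
        dz2 = (ax[2] - center[2]) ** 2
        mask = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        sub = grid[imin[0]:imax[0] + 1, imin[1]:imax[1] + 1, imin[2]:imax[2] + 1]
        np.logical_or(sub, mask, out=sub)
    return grid, lo


_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary_connected(free: np.ndarray) -> np.ndarray:
    """Mask of free voxels 6-connected to the grid boundary."""
    labels, n = ndimage.label(free, structure=_FACE_CONNECTIVITY)
    if n == 0:
        return np.zeros_like(free)
    boundary_labels = set()
    for axis in range(3):
        for idx in (0, -1):
            face = np.take(labels, idx, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())
    if not boundary_labels:
        return np.zeros_like(free)
    return np.isin(labels, sorted(boundary_labels))


def accessible_volume(
    structure: Structure,
    probe_radius: float = 1.4,
    grid_spacing: float = 0.5,
) -> VolumeReport:
    """Volume enclosed by the solvent-accessible surface (Å³).

    Counts grid voxels within ``r_vdw + probe`` of any heavy atom plus any
    interior pocket a 6-connected flood fill from the grid boundary cannot
    reach; volume = voxel count × spacing³.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if not (0 < grid_spacing <= 2.0):
        raise ValueError("grid_spacing must be in (0, 2] Å")
    heavy = structure.heavy_atoms()
    xyz = heavy.coordinates
    radii = heavy.radii
    padding = radii.max() + probe_radius + 2 * grid_spacing
    occupied, _ = occupancy_grid(xyz, radii, grid_spacing, padding, probe_radius)
    outside = _boundary_connected(~occupied)
    enclosed = ~outside  # occupied voxels plus unreachable interior pockets
    volume = float(enclosed.sum()) * grid_spacing**3
    return VolumeReport(
        total_volume=volume, grid_spacing=grid_spacing, probe_radius=probe_radius
    )
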
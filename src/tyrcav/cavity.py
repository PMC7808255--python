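"""Interior cavity detection on a regular grid.

The detector honours the three scalar parameters the underlying channel
analysis uses — an exterior probe radius (bulk solvent size), an interior
clearance threshold (the smallest free radius a cavity voxel must have),
and a minimum burial depth — on a transparent voxel grid:

1. Voxel *clearance* is the distance from the voxel centre to the nearest
   atom surface (centre distance minus that atom's van-der-Waals radius).
2. The *exterior* is flood-filled (6-connectivity) from the grid boundary
   over voxels with clearance ≥ probe_radius, then expanded over connected
   voxels with clearance ≥ interior_threshold reachable from that set —
   so a pocket whose mouth admits the probe is exterior, not a cavity.
3. *Cavity voxels* are the remaining voxels with clearance ≥
   interior_threshold; connected components become cavities.
4. A component's *depth* is the largest distance from any of its voxels to
   the nearest exterior voxel centre; components shallower than
   ``min_depth`` are discarded.

Cavity volumes reported here are grid estimates; the pipeline's claims are
about differences and rank order between paired structures, and those are
stable to the discretisation (see the convergence tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import _FACE_CONNECTIVITY, _boundary_connected, occupancy_grid
from .structure_io import Structure

__all__ = [
    "CavityParameters",
    "Cavity",
    "CavitySet",
    "detect_cavities",
    "total_cavity_volume",
    "interface_cavity",
    "EGF_DOMAIN_RESIDUES",
    "INTERFACE_LINING_RESIDUES",
]

#: Default residue window of the EGF-like domain: the first 100 residues of
#: the mature intra-melanosomal tyrosinase domain, which starts at 19.
EGF_DOMAIN_RESIDUES: range = range(19, 119)

#: Large aromatic residues lining the hydrophobic pocket at the interface
#: between the EGF-like domain and the catalytic domain.
INTERFACE_LINING_RESIDUES: tuple[tuple[str, int], ...] = (
    ("F", 98),
    ("F", 105),
    ("F", 176),
    ("W", 210),
    ("F", 429),
    ("Y", 433),
    ("F", 438),
)


@dataclass(frozen=True, slots=True)
class CavityParameters:
    """Scalar parameters of the cavity detector.

    Defaults follow the channel-analysis convention used for tyrosinase
    cavity screening: probe 3.00 Å, interior threshold 1.25 Å, minimum
    depth 5.00 Å.
    """

    probe_radius: float = 3.00
    interior_threshold: float = 1.25
    min_depth: float = 5.00
    grid_spacing: float = 0.6
    voxel_budget: int = 150_000_000

    def __post_init__(self) -> None:
        if not (self.probe_radius > self.interior_threshold > 0):
            raise ValueError("require probe_radius > interior_threshold > 0")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")


@dataclass(frozen=True, slots=True)
class Cavity:
    volume: float
    voxel_count: int
    depth: float
    centroid: tuple[float, float, float]
    lining_residues: frozenset[tuple[str, int]]


@dataclass(frozen=True, slots=True)
class CavitySet:
    """Cavities of one structure, sorted by volume descending."""

    cavities: tuple[Cavity, ...]
    parameters: CavityParameters
    # diagnostic grids retained for property verification (not serialised)
    _grids: dict = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.cavities)


def detect_cavities(
    structure: Structure,
    params: CavityParameters | None = None,
    keep_grids: bool = False,
) -> CavitySet:
    """Detect interior cavities of a structure on a voxel grid.

    Raises
    ------
    ValueError
        If the grid would exceed the configured voxel budget (use a larger
        ``grid_spacing``) or the structure has fewer than 4 heavy atoms.
    """
    params = params or CavityParameters()
    heavy = structure.heavy_atoms()
    if len(heavy) < 4:
        raise ValueError("cavity detection needs at least 4 heavy atoms")
    xyz = heavy.coordinates
    radii = heavy.radii
    spacing = params.grid_spacing
    padding = radii.max() + params.probe_radius + 2 * spacing

    lo = xyz.min(axis=0) - padding
    hi = xyz.max(axis=0) + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > params.voxel_budget:
        raise ValueError(
            f"grid of {int(np.prod(shape))} voxels exceeds budget "
            f"{params.voxel_budget}; increase grid_spacing"
        )

    # clearance >= t  <=>  voxel centre outside every sphere r_i + t
    blocked_interior, origin = occupancy_grid(
        xyz, radii, spacing, padding, params.interior_threshold
    )
    blocked_probe, _ = occupancy_grid(
        xyz, radii, spacing, padding, params.probe_radius
    )
    open_interior = ~blocked_interior
    open_probe = ~blocked_probe  # subset of open_interior

    # exterior: boundary-reachable bulk solvent, expanded over any
    # interior-clearance voxels connected to it
    bulk = _boundary_connected(open_probe)
    labels, n_comp = ndimage.label(open_interior, structure=_FACE_CONNECTIVITY)
    exterior_ids = np.unique(labels[bulk]) if bulk.any() else np.array([], dtype=int)
    exterior_ids = exterior_ids[exterior_ids > 0]
    exterior = np.isin(labels, exterior_ids)

    ext_id_set = set(exterior_ids.tolist())
    cavity_ids = [cid for cid in range(1, n_comp + 1) if cid not in ext_id_set]

    cavities: list[Cavity] = []
    if cavity_ids:
        # distance from every voxel to the nearest exterior voxel centre
        depth_map = ndimage.distance_transform_edt(
            ~exterior, sampling=(spacing, spacing, spacing)
        )
        res_keys = [(a.chain_id, a.residue_number) for a in heavy.atoms]
        reach = radii + params.interior_threshold + spacing
        for cid in cavity_ids:
            mask = labels == cid
            count = int(mask.sum())
            idx = np.argwhere(mask)
            centers = origin + idx * spacing
            depth = float(depth_map[mask].max())
            if depth < params.min_depth:
                continue
            centroid = tuple(float(v) for v in centers.mean(axis=0))
            # lining residues: atoms close enough to touch a cavity voxel
            lining: set[tuple[str, int]] = set()
            tree = cKDTree(centers)
            for i, key in enumerate(res_keys):
                if key in lining:
                    continue
                if tree.query_ball_point(xyz[i], reach[i], return_length=True):
                    lining.add(key)
            cavities.append(
                Cavity(
                    volume=count * spacing**3,
                    voxel_count=count,
                    depth=depth,
                    centroid=centroid,
                    lining_residues=frozenset(lining),
                )
            )
    cavities.sort(key=lambda c: c.volume, reverse=True)
    grids = None
    if keep_grids:
        grids = {
            "open_interior": open_interior,
            "exterior": exterior,
            "labels": labels,
            "origin": origin,
        }
    return CavitySet(cavities=tuple(cavities), parameters=params, _grids=grids)


def total_cavity_volume(cavity_set: CavitySet, top_n: int = 3) -> float:
    """Sum of the ``top_n`` largest cavity volumes (Å³); 0 for an empty set.

    Summing the three largest cavities approximates the total cavity volume
    of the structure.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    return float(sum(c.volume for c in cavity_set.cavities[:top_n]))


def interface_cavity(
    cavity_set: CavitySet,
    domain_a: set[tuple[str, int]] | set[int],
    domain_b: set[tuple[str, int]] | set[int],
) -> Cavity | None:
    """Largest cavity lined by residues of *both* domains, or ``None``.

    Domains are disjoint residue sets, given either as ``(chain, resnum)``
    pairs or as bare residue numbers (matched against any chain). This is
    the observable used to monitor the pocket between the EGF-like domain
    and the catalytic tyrosinase domain.
    """

    def normalise(dom):
        nums = {d for d in dom if isinstance(d, int)}
        pairs = {d for d in dom if not isinstance(d, int)}
        return nums, pairs

    a_nums, a_pairs = normalise(domain_a)
    b_nums, b_pairs = normalise(domain_b)
    if (a_nums & b_nums) or (a_pairs & b_pairs):
        raise ValueError("domain residue sets must be disjoint")

    def touches(cavity: Cavity, nums, pairs) -> bool:
        for chain, resnum in cavity.lining_residues:
            if resnum in nums or (chain, resnum) in pairs:
                return True
        return False

    qualifying = [
        c
        for c in cavity_set.cavities
        if touches(c, a_nums, a_pairs) and touches(c, b_nums, b_pairs)
    ]
    if not qualifying:
        return None
    return max(qualifying, key=lambda c: c.volume)
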
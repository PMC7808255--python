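"""Synthetic structures and tables with analytically known ground truth.

Every stage of the pipeline is testable without external structure
downloads through three generators:

* :func:`make_hollow_shell` — a spherical shell of atoms enclosing an
  interior cavity of analytically known volume (optionally with a mouth
  opened through the wall), the workhorse fixture for the cavity and
  volume engines;
* :func:`make_two_domain_trajectory` — a rigid "cup and piston" pair of
  domains whose shared interface pocket opens by a controlled per-frame
  drift, emulating one protein domain drifting away from another over a
  simulation, optionally carrying a two-copper site with His-like
  nitrogen ligands;
* :func:`make_ddg_table` — (mutation, ΔΔG, ΔΔV_cav) tables with a set
  linear relation plus Gaussian noise on the cavity response, emulating
  stability-vs-cavity regression data.

All constructions are deterministic: atom placement uses the golden-spiral
lattice or regular grids (no RNG), and table noise is drawn from a
generator seeded by the spec, so regenerating with the same spec yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import sphere_points
from .structure_io import AtomRecord, Structure, Trajectory, vdw_radius

__all__ = [
    "ShellSpec",
    "TwoDomainSpec",
    "DdgTableSpec",
    "make_hollow_shell",
    "make_two_domain_trajectory",
    "make_ddg_table",
]

_INTERIOR_THRESHOLD = 1.25  # default cavity interior clearance (Å)


@dataclass(frozen=True, slots=True)
class ShellSpec:
    """Hollow spherical shell of atoms.

    ``mouth_aperture`` is the chord width (Å) of a cone of atoms removed
    around +z; 0 keeps the shell closed.
    """

    shell_radius: float = 12.0
    atom_spacing: float = 1.5
    element: str = "C"
    mouth_aperture: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shell_radius <= self.atom_spacing:
            raise ValueError("shell_radius must exceed atom_spacing")
        if self.mouth_aperture < 0:
            raise ValueError("mouth_aperture must be >= 0")


@dataclass(frozen=True, slots=True)
class TwoDomainSpec:
    """Two rigid domains enclosing a controllable interface pocket.

    Domain B (chain B) is an open rectangular cup: a bottom plate and four
    walls. Domain A (chain A) is a piston plate sliding inside the cup;
    the sealed pocket between the bottom plate and the piston underside is
    the interface cavity. A positive z-drift per frame lifts the piston
    and grows the pocket monotonically.
    """

    pocket_width: float = 14.0
    wall_height: float = 26.0
    interface_gap: float = 8.0
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 1.5)
    n_frames: int = 2
    atom_spacing: float = 1.5
    element: str = "C"
    metal_pair: tuple[float, int] | None = None  # (Cu–Cu distance Å, ligands per Cu)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.interface_gap < 0:
            raise ValueError("interface_gap must be >= 0")
        if self.pocket_width <= 2 * self.atom_spacing:
            raise ValueError("pocket_width too small for the lattice spacing")


@dataclass(frozen=True, slots=True)
class DdgTableSpec:
    """Linear ΔΔG → ΔΔV_cav relation with Gaussian noise on the response."""

    n_mutants: int = 8
    slope: float = 749.1
    intercept: float = 423.0
    noise_sd: float = 0.0
    ddg_range: tuple[float, float] = (-2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ddg_range[0] >= self.ddg_range[1]:
            raise ValueError("ddg_range must satisfy low < high")
        if self.n_mutants < 3:
            raise ValueError("need at least 3 mutants")


def _atom(serial, name, element, resname, chain, resnum, xyz, hetero=False):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        coordinates=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
        is_hetero=hetero,
    )


def make_hollow_shell(
    spec: ShellSpec,
    interior_threshold: float = _INTERIOR_THRESHOLD,
) -> tuple[Structure, float]:
    """Build a hollow shell and return it with its analytic cavity volume.

    Atoms are placed quasi-uniformly on the sphere by the golden-spiral
    lattice at (approximately) the requested spacing. The analytic cavity
    volume is (4/3)·π·(R − r_vdw − interior_threshold)³ — the ball a
    cavity detector with the given interior clearance should recover.

    Raises
    ------
    ValueError
        If the atom spacing is too coarse for the shell wall to seal
        against the interior-clearance flood fill (conservative bound:
        spacing < √3·(r_vdw + interior_threshold)).
    """
    r_atom = vdw_radius(spec.element)
    seal_limit = math.sqrt(3.0) * (r_atom + interior_threshold)
    if spec.atom_spacing >= seal_limit:
        raise ValueError(
            f"atom_spacing {spec.atom_spacing} cannot seal the shell; "
            f"needs < {seal_limit:.2f} Å"
        )
    n = max(4, math.ceil(4.0 * math.pi * spec.shell_radius**2 / spec.atom_spacing**2))
    pts = sphere_points(n) * spec.shell_radius
    if spec.mouth_aperture > 0:
        half = min(1.0, (spec.mouth_aperture / 2.0) / spec.shell_radius)
        cos_cut = math.cos(math.asin(half))
        keep = pts[:, 2] / spec.shell_radius < cos_cut
        pts = pts[keep]
    center = np.asarray(spec.center, dtype=float)
    atoms = [
        _atom(i + 1, spec.element, spec.element, "SPH", "S", i + 1, center + p)
        for i, p in enumerate(pts)
    ]
    structure = Structure(atoms, identifier=f"shell_r{spec.shell_radius:g}")
    inner = spec.shell_radius - r_atom - interior_threshold
    analytic = (4.0 / 3.0) * math.pi * max(inner, 0.0) ** 3
    return structure, analytic


def _grid_points_2d(width: float, spacing: float) -> np.ndarray:
    n = max(2, int(round(width / spacing)) + 1)
    ax = np.linspace(-width / 2.0, width / 2.0, n)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _build_cup(spec: TwoDomainSpec) -> list[np.ndarray]:
    """Bottom plate plus four walls (xyz rows)."""
    w, h, s = spec.pocket_width, spec.wall_height, spec.atom_spacing
    outer = w + 2 * s  # walls sit one lattice step outside the pocket
    pts = []
    base = _grid_points_2d(outer, s)
    pts.append(np.column_stack([base, np.zeros(len(base))]))
    nz = max(2, int(round(h / s)) + 1)
    zs = np.linspace(0.0, h, nz)
    edge = outer / 2.0
    nxy = max(2, int(round(outer / s)) + 1)
    line = np.linspace(-edge, edge, nxy)
    for z in zs[1:]:
        for sign in (-1.0, 1.0):
            pts.append(np.column_stack([line, np.full(nxy, sign * edge), np.full(nxy, z)]))
            pts.append(np.column_stack([np.full(nxy, sign * edge), line, np.full(nxy, z)]))
    return pts


def _build_piston(spec: TwoDomainSpec) -> np.ndarray:
    """Piston plate sliding inside the cup walls (xy at z = 0).

    The plate reaches to within 1 Å of the wall atom centres so the seam
    around its rim stays sealed against the interior-clearance flood fill
    and the pocket's top boundary is flat wall-to-wall.
    """
    outer = spec.pocket_width + 2 * spec.atom_spacing
    plate = _grid_points_2d(outer - 2.0, spec.atom_spacing)
    return np.column_stack([plate, np.zeros(len(plate))])


def _metal_site_atoms(spec: TwoDomainSpec, start_serial: int) -> list[AtomRecord]:
    distance, n_ligands = spec.metal_pair
    offset = np.array([spec.pocket_width + 12.0, 0.0, spec.wall_height / 2.0])
    cu_a = offset + np.array([0.0, 0.0, -distance / 2.0])
    cu_b = offset + np.array([0.0, 0.0, distance / 2.0])
    atoms = [
        _atom(start_serial, "CU", "CU", "CU", "B", 900, cu_a, hetero=True),
        _atom(start_serial + 1, "CU", "CU", "CU", "B", 901, cu_b, hetero=True),
    ]
    serial = start_serial + 2
    resnum = 910
    bond = 2.1  # Cu–N coordination distance
    for k, cu in enumerate((cu_a, cu_b)):
        axial = -1.0 if k == 0 else 1.0
        for j in range(n_ligands):
            theta = 2.0 * math.pi * j / max(n_ligands, 1)
            # ligands splay away from the partner copper
            direction = np.array(
                [math.cos(theta) * 0.8, math.sin(theta) * 0.8, axial * 0.6]
            )
            direction /= np.linalg.norm(direction)
            pos = cu + bond * direction
            name = "ND1" if j % 2 == 0 else "NE2"
            atoms.append(_atom(serial, name, "N", "HIS", "B", resnum, pos))
            serial += 1
            resnum += 1
    return atoms


def make_two_domain_trajectory(
    spec: TwoDomainSpec,
    interior_threshold: float = _INTERIOR_THRESHOLD,
    time_labels: list[float] | None = None,
) -> tuple[Trajectory, list[float]]:
    """Build the cup-and-piston frame set plus per-frame pocket estimates.

    Returns ``(trajectory, estimates)`` where ``estimates[f]`` is the
    analytic volume of the sealed pocket in frame ``f``: the cuboid
    between the wall/floor/piston atom planes minus one contact margin
    (atom radius + interior clearance) per face,

        (w + 2s − 2m)² · (g + f·dz − 2m),   m = r_vdw + interior_threshold,

    with wall atom planes at ±(w/2 + s) for lattice spacing s.

    Domain A (the piston, chain A) rigidly translates by the drift vector
    each frame; domain B (the cup and any metal site, chain B) is static.
    """
    r_atom = vdw_radius(spec.element)
    cup = np.vstack(_build_cup(spec))
    piston = _build_piston(spec)

    cup_atoms = [
        _atom(i + 1, spec.element, spec.element, "CUP", "B", 200 + i, p)
        for i, p in enumerate(cup)
    ]
    serial0 = len(cup_atoms) + 1
    piston_atoms_template = [
        (serial0 + i, 1 + i) for i in range(len(piston))
    ]
    metal_atoms: list[AtomRecord] = []
    if spec.metal_pair is not None:
        metal_atoms = _metal_site_atoms(spec, serial0 + len(piston))

    drift = np.asarray(spec.drift_per_frame, dtype=float)
    frames = []
    estimates = []
    margin = r_atom + interior_threshold
    for f in range(spec.n_frames):
        z_piston = spec.interface_gap + f * drift[2]
        shift = np.array([f * drift[0], f * drift[1], z_piston])
        piston_atoms = [
            _atom(serial, spec.element, spec.element, "PIS", "A", resnum, piston[i] + shift)
            for i, (serial, resnum) in enumerate(piston_atoms_template)
        ]
        label = float(time_labels[f]) if time_labels else float(f)
        frames.append(
            Structure(
                cup_atoms + piston_atoms + metal_atoms,
                identifier=f"twodomain_f{f}",
                frame_label=label,
            )
        )
        side = (spec.pocket_width + 2 * spec.atom_spacing) - 2 * margin
        height = z_piston - 2 * margin
        estimates.append(max(side, 0.0) ** 2 * max(height, 0.0))
    trajectory = Trajectory(frames=frames, time_labels=list(time_labels or []))
    return trajectory, estimates


def make_ddg_table(spec: DdgTableSpec) -> pd.DataFrame:
    """Mutation table with a known linear ΔΔG → ΔΔV_cav relation.

    ΔΔG values are drawn uniformly over ``ddg_range``; the cavity response
    is ``slope·ΔΔG + intercept`` plus Gaussian noise of SD ``noise_sd``
    (ΔΔG itself is treated as exact — in practice it comes from an energy
    calculation while the cavity volume is the noisy structural
    measurement). Fully reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    ddg = rng.uniform(spec.ddg_range[0], spec.ddg_range[1], size=spec.n_mutants)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=spec.n_mutants)
        if spec.noise_sd > 0
        else np.zeros(spec.n_mutants)
    )
    dd_vcav = spec.slope * ddg + spec.intercept + noise
    return pd.DataFrame(
        {
            "mutation": [f"M{i + 1:03d}" for i in range(spec.n_mutants)],
            "ddg": ddg,
            "dd_vcav": dd_vcav,
        }
    )
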
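"""Binuclear metal-site geometry: Cu–Cu separation and His coordination.

The tyrosinase active site holds two copper ions (a type-3 copper pair,
normally bridged by dioxygen) coordinated by six histidines, three per
copper through their side-chain nitrogens. These observables quantify the
site's integrity in a frame or across an exported frame series: the
metal-pair separation (2.7–2.8 Å in the intact oxy site, expanding when
the bridge is lost) and the number of coordinating ligand atoms per metal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Structure, Trajectory, select_atoms

__all__ = [
    "MetalSiteReport",
    "DistanceSeries",
    "metal_pair_distance",
    "coordination_count",
    "metal_site_report",
    "track_metal_distance",
    "coordination_lost",
    "DEFAULT_LIGAND_SELECTION",
    "DEFAULT_COORDINATION_CUTOFF",
    "LOSS_OF_COORDINATION_MAX_COUNT",
]

#: Default ligand atoms: histidine side-chain nitrogens.
DEFAULT_LIGAND_SELECTION = "atom_name in {ND1, NE2} and residue_name = HIS"

#: Cu–N coordination bonds run 1.9–2.2 Å; 3.0 Å allows thermal slack.
DEFAULT_COORDINATION_CUTOFF = 3.0

#: A metal holding at most this many ligand atoms counts as having lost
#: coordination (a metal held by a single contact is no longer fixed in
#: the site).
LOSS_OF_COORDINATION_MAX_COUNT = 1


@dataclass(frozen=True, slots=True)
class MetalSiteReport:
    """Geometry of a two-metal site in one frame."""

    metal_pair_distance: float
    per_metal_coordination: tuple[tuple[int, tuple[int, ...], int], ...]
    frame_label: float | None = None


@dataclass(frozen=True, slots=True)
class DistanceSeries:
    """Metal-pair separation per frame of an ordered frame set."""

    time_labels: tuple[float, ...]
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.time_labels) != len(self.distances):
            raise ValueError("time_labels and distances length mismatch")
        if any(b <= a for a, b in zip(self.time_labels, self.time_labels[1:])):
            raise ValueError("time labels must be strictly increasing")


def _metal_atoms(structure: Structure, element: str):
    sym = element.upper()
    return [a for a in structure.atoms if a.element.upper() == sym]


def metal_pair_distance(structure: Structure, element: str = "CU") -> float:
    """Euclidean separation (Å) of the structure's two atoms of ``element``.

    Raises
    ------
    ValueError
        If the structure does not contain exactly two such atoms.
    """
    metals = _metal_atoms(structure, element)
    if len(metals) != 2:
        raise ValueError(
            f"metal pair distance needs exactly 2 {element.upper()} atoms, "
            f"expected 2, found {len(metals)}"
        )
    a, b = metals
    return float(
        np.linalg.norm(np.asarray(a.coordinates) - np.asarray(b.coordinates))
    )


def coordination_count(
    structure: Structure,
    metal_serial: int,
    ligand_selection: str = DEFAULT_LIGAND_SELECTION,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
) -> tuple[int, list]:
    """Ligand atoms within ``cutoff`` of a metal centre, nearest first.

    Returns ``(count, atoms)`` where ``atoms`` are the coordinating
    :class:`AtomRecord` objects sorted by distance to the metal.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    metal = next((a for a in structure.atoms if a.serial == metal_serial), None)
    if metal is None:
        raise ValueError(f"no atom with serial {metal_serial}")
    ligands = select_atoms(structure, ligand_selection).atoms
    center = np.asarray(metal.coordinates)
    within = [
        (float(np.linalg.norm(np.asarray(a.coordinates) - center)), a)
        for a in ligands
        if a.serial != metal_serial
    ]
    within = [(d, a) for d, a in within if d <= cutoff]
    within.sort(key=lambda pair: pair[0])
    return len(within), [a for _, a in within]


def metal_site_report(
    structure: Structure,
    element: str = "CU",
    ligand_selection: str = DEFAULT_LIGAND_SELECTION,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
) -> MetalSiteReport:
    """Pair distance plus per-metal coordination for a two-metal site."""
    distance = metal_pair_distance(structure, element)
    per_metal = []
    for m in _metal_atoms(structure, element):
        count, atoms = coordination_count(
            structure, m.serial, ligand_selection, cutoff
        )
        per_metal.append((m.serial, tuple(a.serial for a in atoms), count))
    return MetalSiteReport(
        metal_pair_distance=distance,
        per_metal_coordination=tuple(per_metal),
        frame_label=structure.frame_label,
    )


def track_metal_distance(
    trajectory: Trajectory, element: str = "CU"
) -> DistanceSeries:
    """Metal-pair separation in every frame, paired with its time label."""
    distances = []
    for i, frame in enumerate(trajectory.frames):
        try:
            distances.append(metal_pair_distance(frame, element))
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return DistanceSeries(
        time_labels=tuple(float(t) for t in trajectory.time_labels),
        distances=tuple(distances),
    )


def coordination_lost(
    report: MetalSiteReport,
    max_count: int = LOSS_OF_COORDINATION_MAX_COUNT,
) -> bool:
    """True when any metal of the site retains ≤ ``max_count`` ligand atoms."""
    return any(count <= max_count for _, _, count in report.per_metal_coordination)
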
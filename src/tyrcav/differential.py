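"""Paired difference statistics between wild-type and mutant structures.

For each structural metric m (surface area SA, accessible volume V, cavity
volume V_cav) measured at two timepoints t0 and t1 of a simulation:

    Δm   = m(t1) − m(t0)                 (per structure)
    ΔΔm  = Δm(mutant) − Δm(wild type)    (mutant relative to wild type)

so ΔΔ quantifies how much more (or less) the mutant changed over the run
than the wild type did. These differences — not the absolute metric
values — are what the downstream correlation analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cavity import CavityParameters, detect_cavities, interface_cavity, total_cavity_volume
from .geometry import accessible_volume, sasa
from .structure_io import Structure

__all__ = [
    "StructureMetrics",
    "DeltaDeltaRecord",
    "delta",
    "delta_delta",
    "build_dd_table",
    "measure_structure",
]


@dataclass(frozen=True, slots=True)
class StructureMetrics:
    """One structure's geometric observables at one timepoint."""

    label: str
    timepoint: float
    sa: float
    volume: float
    cavity_top3: float
    interface_cavity: float


@dataclass(frozen=True, slots=True)
class DeltaDeltaRecord:
    mutation: str
    dd_sa: float
    dd_v: float
    dd_vcav: float


def _value_and_unit(x) -> tuple[float, str | None]:
    if isinstance(x, tuple) and len(x) == 2:
        return float(x[0]), str(x[1])
    return float(x), None


def delta(metric_t1, metric_t0) -> float:
    """Change of a metric over the run: value(t1) − value(t0).

    Values may be bare numbers or ``(value, unit)`` pairs; mixed units are
    rejected.
    """
    v1, u1 = _value_and_unit(metric_t1)
    v0, u0 = _value_and_unit(metric_t0)
    if u1 is not None and u0 is not None and u1 != u0:
        raise ValueError(f"unit mismatch: {u1!r} vs {u0!r}")
    return v1 - v0


def delta_delta(delta_mut, delta_wt) -> float:
    """Mutant change relative to the wild-type change: Δ_mut − Δ_wt."""
    v_m, u_m = _value_and_unit(delta_mut)
    v_w, u_w = _value_and_unit(delta_wt)
    if u_m is not None and u_w is not None and u_m != u_w:
        raise ValueError(f"unit mismatch: {u_m!r} vs {u_w!r}")
    return v_m - v_w


def measure_structure(
    structure: Structure,
    label: str,
    timepoint: float,
    cavity_params: CavityParameters | None = None,
    domain_a: set | None = None,
    domain_b: set | None = None,
    probe_radius: float = 1.4,
    grid_spacing: float = 0.5,
    n_sphere_points: int = 960,
) -> StructureMetrics:
    """Compute the full metric set (SA, V, top-3 V_cav, interface V_cav).

    ``domain_a``/``domain_b`` delimit the two regions whose shared pocket
    is reported as the interface cavity; when omitted the interface cavity
    is 0.
    """
    surface = sasa(structure, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    volume = accessible_volume(structure, probe_radius=probe_radius, grid_spacing=grid_spacing)
    cavities = detect_cavities(structure, cavity_params)
    iface = 0.0
    if domain_a and domain_b:
        cav = interface_cavity(cavities, domain_a, domain_b)
        iface = cav.volume if cav is not None else 0.0
    return StructureMetrics(
        label=label,
        timepoint=timepoint,
        sa=surface.total_area,
        volume=volume.total_volume,
        cavity_top3=total_cavity_volume(cavities),
        interface_cavity=iface,
    )


def _order_pair(pair: Sequence[StructureMetrics], who: str) -> tuple[StructureMetrics, StructureMetrics]:
    if len(pair) != 2:
        raise ValueError(f"{who}: need metrics at exactly two timepoints")
    a, b = sorted(pair, key=lambda m: m.timepoint)
    if a.timepoint == b.timepoint:
        raise ValueError(f"{who}: duplicate timepoint {a.timepoint}")
    return a, b


def build_dd_table(
    wt_metrics: Sequence[StructureMetrics],
    mutant_metrics: dict[str, Sequence[StructureMetrics]],
) -> list[DeltaDeltaRecord]:
    """ΔΔ records for every mutant against one wild-type reference.

    Every structure must supply both timepoints, and all structures must
    share the same two timepoint labels.
    """
    wt0, wt1 = _order_pair(wt_metrics, "wild type")
    timepoints = (wt0.timepoint, wt1.timepoint)
    d_wt = {
        "sa": delta(wt1.sa, wt0.sa),
        "v": delta(wt1.volume, wt0.volume),
        "vcav": delta(wt1.cavity_top3, wt0.cavity_top3),
    }
    records = []
    for name, pair in mutant_metrics.items():
        m0, m1 = _order_pair(pair, name)
        if (m0.timepoint, m1.timepoint) != timepoints:
            raise ValueError(
                f"{name}: timepoints {(m0.timepoint, m1.timepoint)} differ "
                f"from wild type {timepoints}"
            )
        records.append(
            DeltaDeltaRecord(
                mutation=name,
                dd_sa=delta_delta(delta(m1.sa, m0.sa), d_wt["sa"]),
                dd_v=delta_delta(delta(m1.volume, m0.volume), d_wt["v"]),
                dd_vcav=delta_delta(delta(m1.cavity_top3, m0.cavity_top3), d_wt["vcav"]),
            )
        )
    return records
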
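import math
from dataclasses import replace

import numpy as np
import pytest

from tyrcav import (
    Cavity,
    CavityParameters,
    CavitySet,
    ShellSpec,
    Structure,
    detect_cavities,
    interface_cavity,
    make_hollow_shell,
    total_cavity_volume,
)

from conftest import make_atom


def make_cavity(volume, lining, depth=6.0):
    return Cavity(
        volume=volume,
        voxel_count=int(volume / 0.6**3),
        depth=depth,
        centroid=(0.0, 0.0, 0.0),
        lining_residues=frozenset(lining),
    )


def cavity_set(cavities):
    ordered = tuple(sorted(cavities, key=lambda c: c.volume, reverse=True))
    return CavitySet(cavities=ordered, parameters=CavityParameters(), _grids=None)


class TestDetection:
    def test_solid_cluster_has_no_cavity(self, solid_cluster):
        assert len(detect_cavities(solid_cluster)) == 0

    def test_hollow_shell_volume_matches_analytic(self, closed_shell):
        shell, analytic = closed_shell
        cs = detect_cavities(shell)
        assert len(cs) == 1
        assert cs.cavities[0].volume == pytest.approx(analytic, rel=0.10)
        assert cs.cavities[0].depth >= 5.0
        assert cs.cavities[0].lining_residues

    def test_two_shells_ordered_largest_first(self):
        big, big_truth = make_hollow_shell(ShellSpec(shell_radius=12.0))
        small, small_truth = make_hollow_shell(
            ShellSpec(shell_radius=8.0, center=(40.0, 0.0, 0.0))
        )
        merged = Structure(
            big.atoms
            + [
                replace(a, serial=10_000 + i, chain_id="T")
                for i, a in enumerate(small.atoms)
            ]
        )
        cs = detect_cavities(merged)
        assert len(cs) == 2
        assert cs.cavities[0].volume > cs.cavities[1].volume
        assert cs.cavities[0].volume == pytest.approx(big_truth, rel=0.10)
        assert cs.cavities[1].volume == pytest.approx(small_truth, rel=0.10)

    def test_spacing_halving_convergence(self, closed_shell):
        shell, _ = closed_shell
        v_default = detect_cavities(
            shell, CavityParameters(grid_spacing=0.6)
        ).cavities[0].volume
        v_half = detect_cavities(
            shell, CavityParameters(grid_spacing=0.3)
        ).cavities[0].volume
        assert abs(v_default - v_half) / v_half < 0.10

    def test_open_mouth_destroys_cavity(self):
        """A mouth wider than the probe diameter opens the interior to bulk."""
        opened, _ = make_hollow_shell(ShellSpec(mouth_aperture=8.0))
        assert len(detect_cavities(opened)) == 0

    def test_cavity_voxels_satisfy_definition(self, closed_shell):
        """Every cavity voxel has interior clearance and is not boundary-reachable."""
        shell, _ = closed_shell
        cs = detect_cavities(shell, keep_grids=True)
        grids = cs._grids
        labels, exterior = grids["labels"], grids["exterior"]
        cavity_mask = (labels > 0) & ~exterior
        assert grids["open_interior"][cavity_mask].all()
        assert not (cavity_mask & exterior).any()
        # boundary faces of the grid are all exterior-or-blocked
        for axis in range(3):
            for idx in (0, -1):
                face_cavity = np.take(cavity_mask, idx, axis=axis)
                assert not face_cavity.any()

    def test_too_few_atoms_rejected(self):
        st = Structure([make_atom(1, (0, 0, 0)), make_atom(2, (5, 0, 0))])
        with pytest.raises(ValueError):
            detect_cavities(st)

    def test_voxel_budget_error_mentions_spacing(self, closed_shell):
        shell, _ = closed_shell
        params = CavityParameters(grid_spacing=0.3, voxel_budget=1000)
        with pytest.raises(ValueError, match="spacing"):
            detect_cavities(shell, params)


class TestParameters:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"probe_radius": 1.0, "interior_threshold": 1.25},  # probe <= interior
            {"interior_threshold": 0.0},
            {"min_depth": -1.0},
            {"grid_spacing": 0.0},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            CavityParameters(**kwargs)


class TestTotalVolume:
    def test_three_largest_summed(self):
        cs = cavity_set(
            [make_cavity(v, {("A", 1)}) for v in (1000.0, 400.0, 200.0, 50.0)]
        )
        assert total_cavity_volume(cs) == pytest.approx(1600.0)

    def test_fewer_than_top_n(self):
        cs = cavity_set([make_cavity(422.0, {("A", 1)})])
        assert total_cavity_volume(cs) == pytest.approx(422.0)

    def test_empty_set(self):
        assert total_cavity_volume(cavity_set([])) == 0.0

    def test_monotone_in_top_n(self):
        cs = cavity_set(
            [make_cavity(v, {("A", 1)}) for v in (900.0, 300.0, 100.0, 10.0)]
        )
        totals = [total_cavity_volume(cs, n) for n in range(1, 7)]
        assert totals == sorted(totals)
        assert totals[-1] == pytest.approx(sum(c.volume for c in cs.cavities))


class TestInterfaceCavity:
    DOM_A = {("A", i) for i in range(1, 10)}
    DOM_B = {("B", i) for i in range(100, 110)}

    def test_single_domain_lining_is_not_interface(self):
        cs = cavity_set([make_cavity(500.0, {("A", 1), ("A", 2)})])
        assert interface_cavity(cs, self.DOM_A, self.DOM_B) is None

    def test_largest_qualifying_returned(self):
        small = make_cavity(300.0, {("A", 1), ("B", 100)})
        large = make_cavity(800.0, {("A", 2), ("B", 101)})
        cs = cavity_set([small, large])
        assert interface_cavity(cs, self.DOM_A, self.DOM_B).volume == 800.0

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError):
            interface_cavity(cavity_set([]), {("A", 1)}, {("A", 1), ("B", 2)})

    def test_bare_residue_numbers_accepted(self):
        cs = cavity_set([make_cavity(500.0, {("A", 5), ("B", 105)})])
        assert interface_cavity(cs, set(range(1, 10)), set(range(100, 110))) is not None

    def test_engineered_interface_pocket_recovered(self):
        """Two-domain fixture: the sealed pocket is found within 10% of truth."""
        from tyrcav import TwoDomainSpec, make_two_domain_trajectory

        spec = TwoDomainSpec(interface_gap=10.0, n_frames=1)
        traj, estimates = make_two_domain_trajectory(spec)
        frame = traj.frames[0]
        dom_a = {(a.chain_id, a.residue_number) for a in frame.atoms if a.chain_id == "A"}
        dom_b = {(a.chain_id, a.residue_number) for a in frame.atoms if a.chain_id == "B"}
        cs = detect_cavities(frame, CavityParameters(grid_spacing=0.4))
        pocket = interface_cavity(cs, dom_a, dom_b)
        assert pocket is not None
        assert pocket.volume == pytest.approx(estimates[0], rel=0.10)
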
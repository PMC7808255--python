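import numpy as np
import pytest

from tyrcav import AtomRecord, ShellSpec, Structure, make_hollow_shell


def make_atom(serial, xyz, element="C", name=None, resname="LIG", chain="A",
              resnum=None, hetero=False, occupancy=1.0, alt_loc=""):
    return AtomRecord(
        serial=serial,
        name=name or element,
        element=element,
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum if resnum is not None else serial,
        coordinates=tuple(float(v) for v in xyz),
        occupancy=occupancy,
        alt_loc=alt_loc,
        is_hetero=hetero,
    )


def cluster_structure(xyz, element="C"):
    return Structure(
        [make_atom(i + 1, p, element=element) for i, p in enumerate(np.asarray(xyz))]
    )


@pytest.fixture(scope="session")
def closed_shell():
    """Default hollow shell plus its analytic interior cavity volume."""
    return make_hollow_shell(ShellSpec())


@pytest.fixture(scope="session")
def solid_cluster():
    """Dense block of carbon atoms with no interior gap."""
    ax = np.arange(0.0, 10.0, 1.6)
    pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
    return cluster_structure(pts)


@pytest.fixture
def copper_site():
    """Two Cu 2.75 Å apart, each coordinated by 3 His nitrogens at 2.1 Å."""
    atoms = []
    cu_positions = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 2.75])]
    for k, pos in enumerate(cu_positions):
        atoms.append(
            make_atom(k + 1, pos, element="CU", name="CU", resname="CU",
                      resnum=500 + k, hetero=True)
        )
    serial = 3
    for k, cu in enumerate(cu_positions):
        axial = -1.0 if k == 0 else 1.0
        for j in range(3):
            theta = 2 * np.pi * j / 3
            d = np.array([0.8 * np.cos(theta), 0.8 * np.sin(theta), 0.6 * axial])
            d /= np.linalg.norm(d)
            atoms.append(
                make_atom(serial, cu + 2.1 * d, element="N",
                          name="ND1" if j % 2 == 0 else "NE2",
                          resname="HIS", resnum=600 + serial)
            )
            serial += 1
    return Structure(atoms)
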
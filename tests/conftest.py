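import math

import numpy as np
import pytest

from hydrofold.model_io import AtomRecord, Frame, Topology, assign_symmetry_groups
from hydrofold.synthetic import GeneratorSpec, gen_two_state_toy, water_topology


def simple_atom(index, name="X", resname="XXX", resid=1, mol="protein", element="C",
                charge=0.0, eps=0.0, rmh=0.0, acceptor=False):
    return AtomRecord(
        atom_index=index, atom_name=name, residue_name=resname, residue_number=resid,
        molecule_class=mol, element=element, partial_charge=charge,
        lj_epsilon=eps, lj_rmin_half=rmh, is_acceptor=acceptor,
    )


def hbond_probe_topology():
    """Amide-like donor (N, HN, CB) and carbonyl-like acceptor (C, O)."""
    atoms = [
        simple_atom(0, "N", "ALA", 1, element="N", charge=-0.47, eps=0.2, rmh=1.85),
        simple_atom(1, "HN", "ALA", 1, element="H", charge=0.31, eps=0.046, rmh=0.2245),
        simple_atom(2, "CB", "ALA", 1, element="C", charge=0.16, eps=0.08, rmh=2.06),
        simple_atom(3, "C", "GLY", 2, element="C", charge=0.51, eps=0.11, rmh=2.0),
        simple_atom(4, "O", "GLY", 2, element="O", charge=-0.51, eps=0.12, rmh=1.7,
                    acceptor=True),
    ]
    bonds = [(0, 1), (0, 2), (3, 4)]
    return assign_symmetry_groups(Topology(atoms=atoms, bonds=bonds))


def hbond_probe_frame(d_heavy, angle_deg, box=(50.0, 50.0, 50.0)):
    """Place donor/acceptor at separation ``d_heavy`` with an exact
    donor-H-acceptor angle, solved by bisection on the hydrogen direction."""
    from scipy.optimize import brentq

    n = np.zeros(3)
    o = np.array([0.0, 0.0, d_heavy])

    def angle_at_h(alpha):
        h = np.array([math.sin(alpha), 0.0, math.cos(alpha)])  # 1.0 A from N
        v1 = n - h
        v2 = o - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(np.clip(c, -1, 1)))

    if abs(angle_deg - 180.0) < 1e-9:
        alpha = 0.0
    else:
        alpha = brentq(lambda a: angle_at_h(a) - angle_deg, 1e-6, math.pi / 2 - 1e-6)
    h = np.array([math.sin(alpha), 0.0, math.cos(alpha)])
    coords = np.array([
        n, h, n + [0.0, 1.2, -0.8],          # N, HN, CB
        o + [0.0, 0.0, 1.23], o,              # C, O
    ]) + np.asarray(box) / 2.0
    return Frame(coordinates=coords, box=box)


@pytest.fixture(scope="session")
def toy_two_state():
    """Small planted two-state system shared by slower tests."""
    return gen_two_state_toy(GeneratorSpec(
        seed=11, n_frames=6, recipe="two_state_toy", params={"n_replicates": 3}))
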
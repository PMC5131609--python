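"""Energy kernel: pair terms, switching, group sums, and decompositions."""

import itertools
import math

import numpy as np
import pytest

from hydrofold.model_io import Frame, Topology, TrajectoryError
from hydrofold.nonbonded import (
    BondedParameters,
    EnergyOptions,
    atom_energy_table,
    bonded_energy,
    component_breakdown,
    ensemble_total_energy,
    group_energy,
    pair_energy,
    state_energy_difference,
    total_nonbonded_energy,
)
from hydrofold.synthetic import GeneratorSpec, gen_uniform_water_box

from conftest import simple_atom

BOX = (50.0, 50.0, 50.0)


def two_atoms(q1=0.0, q2=0.0, eps1=0.0, eps2=0.0, rmh1=0.0, rmh2=0.0):
    atoms = [
        simple_atom(0, charge=q1, eps=eps1, rmh=rmh1),
        simple_atom(1, charge=q2, eps=eps2, rmh=rmh2),
    ]
    return Topology(atoms=atoms)


def frame_at(r, box=BOX):
    return Frame(coordinates=[[0, 0, 0], [r, 0, 0]], box=box)


def brute_pair_energy(ci, cj, box, qi, qj, epsi, epsj, rmhi, rmhj,
                      opts=EnergyOptions()):
    """Independent evaluation: 27-image minimum distance, explicit formulas."""
    best = math.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz]) * np.asarray(box)
        best = min(best, float(np.linalg.norm(np.asarray(cj) + shift - np.asarray(ci))))
    r = best
    e = opts.coulomb_constant * qi * qj / r
    eps = math.sqrt(epsi * epsj)
    rmin = rmhi + rmhj
    if eps > 0:
        ron, roff = opts.vdw_switch_on, opts.vdw_cutoff
        if r < roff:
            s = 1.0 if r <= ron else (
                (roff**2 - r**2) ** 2 * (roff**2 + 2 * r**2 - 3 * ron**2)
            ) / (roff**2 - ron**2) ** 3
            e += s * eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    return e


class TestPairEnergy:
    def test_zero_parameters_give_zero_at_any_distance(self):
        top = two_atoms()
        for r in (0.5, 3.0, 20.0):
            assert pair_energy(0, 1, frame_at(r), top) == 0.0

    def test_lj_minimum_is_minus_epsilon_at_rmin(self):
        top = two_atoms(eps1=0.2, eps2=0.2, rmh1=1.5, rmh2=1.5)
        assert pair_energy(0, 1, frame_at(3.0), top) == pytest.approx(-0.2, abs=1e-12)

    def test_unit_charges_at_one_angstrom_give_the_coulomb_constant(self):
        top = two_atoms(q1=1.0, q2=1.0)
        e = pair_energy(0, 1, frame_at(1.0), top)
        assert e == pytest.approx(332.0636, abs=1e-9)
        assert e == pytest.approx(brute_pair_energy([0, 0, 0], [1, 0, 0], BOX,
                                                    1, 1, 0, 0, 0, 0), abs=1e-9)

    def test_pair_symmetry_is_exact(self):
        top = two_atoms(q1=0.4, q2=-0.3, eps1=0.1, eps2=0.2, rmh1=1.7, rmh2=2.0)
        f = frame_at(2.7)
        assert pair_energy(0, 1, f, top) == pair_energy(1, 0, f, top)

    def test_excluded_pair_returns_zero(self):
        top = Topology(atoms=[simple_atom(0, charge=1.0), simple_atom(1, charge=1.0)],
                       bonds=[(0, 1)])
        assert pair_energy(0, 1, frame_at(1.0), top) == 0.0

    def test_overlapping_atoms_raise(self):
        top = two_atoms(q1=1.0, q2=1.0)
        with pytest.raises(ValueError, match="overlap"):
            pair_energy(0, 1, frame_at(0.0), top)

    def test_switching_is_continuous_and_zero_beyond_cutoff(self):
        top = two_atoms(eps1=0.3, eps2=0.3, rmh1=2.0, rmh2=2.0)
        rs = np.linspace(8.0, 12.0, 2001)
        es = np.array([pair_energy(0, 1, frame_at(r), top) for r in rs])
        assert np.all(es[rs >= 11.0] == 0.0)
        assert np.max(np.abs(np.diff(es))) < 1e-3  # no jumps on a fine sweep

    def test_minimum_image_wraps_the_pair_distance(self):
        top = two_atoms(q1=1.0, q2=1.0)
        f = Frame(coordinates=[[0, 0, 0], [49.0, 0, 0]], box=BOX)
        assert pair_energy(0, 1, f, top) == pytest.approx(332.0636, abs=1e-9)


class TestGroupEnergy:
    @pytest.fixture()
    def random_system(self):
        top, ens = gen_uniform_water_box(GeneratorSpec(
            seed=8, n_frames=1, box=(24.0, 24.0, 24.0), params={"n_waters": 12}))
        return top, ens.frames[0]

    def test_all_atoms_equals_total_nonbonded(self, random_system):
        top, frame = random_system
        assert group_energy(range(top.n_atoms), frame, top) == pytest.approx(
            total_nonbonded_energy(frame, top), rel=1e-12)

    def test_two_isolated_atoms_give_exactly_the_pair_energy(self):
        top = two_atoms(q1=0.5, q2=-0.5, eps1=0.1, eps2=0.1, rmh1=1.6, rmh2=1.6)
        f = frame_at(3.1)
        assert group_energy([0, 1], f, top) == pytest.approx(
            pair_energy(0, 1, f, top), rel=1e-12)

    def test_matches_brute_force_half_weight_sum(self, random_system):
        top, frame = random_system
        members = [0, 1, 2, 6, 7]
        expected = 0.0
        excl = top.excluded_pairs
        for i in members:
            a = top.atoms[i]
            for j in range(top.n_atoms):
                if j == i or (min(i, j), max(i, j)) in excl:
                    continue
                b = top.atoms[j]
                expected += 0.5 * brute_pair_energy(
                    frame.coordinates[i], frame.coordinates[j], frame.box,
                    a.partial_charge, b.partial_charge, a.lj_epsilon, b.lj_epsilon,
                    a.lj_rmin_half, b.lj_rmin_half)
        assert group_energy(members, frame, top) == pytest.approx(expected, rel=1e-9)

    def test_sum_of_single_atom_groups_conserves_total(self, random_system):
        top, frame = random_system
        total = total_nonbonded_energy(frame, top)
        per_atom = sum(group_energy([i], frame, top) for i in range(top.n_atoms))
        assert per_atom == pytest.approx(total, rel=1e-9)

    def test_lattice_translation_leaves_energy_unchanged(self, random_system):
        top, frame = random_system
        shifted = Frame(coordinates=frame.coordinates + np.array([24.0, -48.0, 24.0]),
                        box=frame.box)
        assert total_nonbonded_energy(shifted, top) == pytest.approx(
            total_nonbonded_energy(frame, top), rel=1e-9)

    def test_empty_group_is_an_error(self, random_system):
        top, frame = random_system
        with pytest.raises(ValueError):
            group_energy([], frame, top)


class TestBondedEnergy:
    def test_equilibrium_geometry_has_zero_energy(self):
        top = Topology(atoms=[simple_atom(i) for i in range(3)], bonds=[(0, 1), (1, 2)])
        params = BondedParameters(
            bonds=[(0, 1, 300.0, 1.5), (1, 2, 300.0, 1.5)],
            angles=[(0, 1, 2, 50.0, 90.0)],
        )
        f = Frame(coordinates=[[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0]], box=BOX)
        assert bonded_energy(f, top, params) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_is_harmonic_in_k_convention(self):
        top = Topology(atoms=[simple_atom(i) for i in range(2)], bonds=[(0, 1)])
        params = BondedParameters(bonds=[(0, 1, 300.0, 1.5)])
        f = Frame(coordinates=[[0, 0, 0], [1.7, 0, 0]], box=BOX)
        assert bonded_energy(f, top, params) == pytest.approx(300.0 * 0.2**2, abs=1e-9)

    def test_matches_term_by_term_brute_force(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 6, size=(4, 3))
        top = Topology(atoms=[simple_atom(i) for i in range(4)],
                       bonds=[(0, 1), (1, 2), (2, 3)])
        params = BondedParameters(
            bonds=[(0, 1, 250.0, 1.4), (1, 2, 200.0, 1.5)],
            angles=[(0, 1, 2, 40.0, 110.0)],
            dihedrals=[(0, 1, 2, 3, 1.2, 3, 0.0)],
            impropers=[(0, 1, 2, 3, 20.0, 0.0)],
        )
        f = Frame(coordinates=coords, box=BOX)

        def ang(a, b, c):
            v1, v2 = a - b, c - b
            return math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))

        def dih(p0, p1, p2, p3):
            b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
            b1n = b1 / np.linalg.norm(b1)
            v = b0 - np.dot(b0, b1n) * b1n
            w = b2 - np.dot(b2, b1n) * b1n
            return math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w))

        expected = (
            250.0 * (np.linalg.norm(coords[1] - coords[0]) - 1.4) ** 2
            + 200.0 * (np.linalg.norm(coords[2] - coords[1]) - 1.5) ** 2
            + 40.0 * (ang(coords[0], coords[1], coords[2]) - math.radians(110.0)) ** 2
            + 1.2 * (1 + math.cos(3 * dih(*coords)))
            + 20.0 * dih(*coords) ** 2
        )
        assert bonded_energy(f, top, params) == pytest.approx(expected, abs=1e-10)


class TestStateEnergies:
    def test_identical_ensembles_difference_is_zero(self):
        top, ens = gen_uniform_water_box(GeneratorSpec(
            seed=2, n_frames=3, box=(24.0, 24.0, 24.0), params={"n_waters": 8}))
        assert state_energy_difference(ens, ens, topology=top) == pytest.approx(0.0, abs=1e-12)

    def test_particle_inventory_mismatch_is_an_error(self):
        top1, ens1 = gen_uniform_water_box(GeneratorSpec(
            seed=2, n_frames=2, box=(24.0, 24.0, 24.0), params={"n_waters": 8}))
        top2, ens2 = gen_uniform_water_box(GeneratorSpec(
            seed=2, n_frames=2, box=(24.0, 24.0, 24.0), params={"n_waters": 9}))
        with pytest.raises(TrajectoryError, match="inventories"):
            state_energy_difference(ens2, ens1)


class TestDecompositions:
    def test_atom_table_conserves_and_partitions(self, toy_two_state):
        top, nat, ext = toy_two_state
        results, sums = atom_energy_table(nat[0], ext[0], top)
        assert len(results) == len(top.protein_indices)
        assert sums["polar"] + sums["nonpolar"] == pytest.approx(sums["all"], rel=1e-9)
        for r in results:
            assert r.delta_E_atom == pytest.approx(
                r.E_atom_native - r.E_atom_extended, abs=1e-12)

    def test_component_entries_sum_to_total(self, toy_two_state):
        top, nat, _ = toy_two_state
        comps = component_breakdown(nat[0], top)
        total = ensemble_total_energy(nat[0], top)
        assert sum(comps.values()) == pytest.approx(total, rel=1e-9)

    def test_pure_water_box_has_a_single_water_water_entry(self):
        top, ens = gen_uniform_water_box(GeneratorSpec(
            seed=6, n_frames=2, box=(24.0, 24.0, 24.0), params={"n_waters": 8}))
        comps = component_breakdown(ens, top)
        assert list(comps) == [("water-water", "nonbonded")]
        assert comps[("water-water", "nonbonded")] == pytest.approx(
            ensemble_total_energy(ens, top), rel=1e-12)

    def test_class_pair_sums_match_labeled_brute_force(self, toy_two_state):
        top, nat, _ = toy_two_state
        frame = nat[0].frames[0]
        comps = component_breakdown(
            type(nat[0])(state_label="native", replicate_id=0,
                         ensemble_kind="fixed_NVT", frames=[frame], topology=top),
            top)
        label = {"protein": "protein", "water": "water", "ion": "salt"}
        excl = top.excluded_pairs
        expected: dict = {}
        for i in range(top.n_atoms):
            for j in range(i + 1, top.n_atoms):
                if (i, j) in excl:
                    continue
                a, b = top.atoms[i], top.atoms[j]
                e = brute_pair_energy(
                    frame.coordinates[i], frame.coordinates[j], frame.box,
                    a.partial_charge, b.partial_charge, a.lj_epsilon, b.lj_epsilon,
                    a.lj_rmin_half, b.lj_rmin_half)
                ca, cb = sorted([label[a.molecule_class], label[b.molecule_class]],
                                key=["protein", "water", "salt"].index)
                key = (f"{ca}-{cb}", "nonbonded")
                expected[key] = expected.get(key, 0.0) + e
        for key, val in expected.items():
            assert comps[key] == pytest.approx(val, rel=1e-9, abs=1e-9)
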
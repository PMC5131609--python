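"""Metrics, KNN entropy estimator, bulk references, and hydration sites."""

import itertools
import math
import warnings

import numpy as np
import pytest

from hydrofold.ifst import (
    BulkReference,
    EstimatorConfig,
    GAS_CONSTANT_R,
    HydrationSite,
    WaterObservation,
    bulk_reference,
    cluster_hydration_sites,
    extract_water_observations,
    nearest_neighbor_distances,
    orientational_distance,
    site_energy,
    site_free_energy,
    site_ssw,
    ssw_knn,
    translational_distance,
    water_orientation_quaternion,
)
from hydrofold.model_io import Frame, Topology, TrajectoryEnsemble
from hydrofold.synthetic import (
    GeneratorSpec,
    build_rigid_water,
    gen_gaussian_sites,
    gen_uniform_water_box,
    random_unit_quaternions,
    water_topology,
)

from conftest import simple_atom


class TestOrientationalDistance:
    def test_identity_and_double_cover(self):
        q = np.array([0.5, 0.5, 0.5, 0.5])
        assert orientational_distance(q, q) == 0.0
        assert orientational_distance(q, -q) == 0.0

    def test_orthogonal_quaternions_are_pi_apart(self):
        assert orientational_distance([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(math.pi)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            q1, q2 = random_unit_quaternions(rng, 2)
            d12 = orientational_distance(q1, q2)
            assert d12 == pytest.approx(orientational_distance(q2, q1))
            assert 0.0 <= d12 <= math.pi + 1e-12

    def test_hydrogen_exchange_symmetry_collapses_the_flip(self):
        q1 = np.array([1.0, 0.0, 0.0, 0.0])
        q_flip = np.array([0.0, 0.0, 0.0, 1.0])  # rotation by pi about z
        assert orientational_distance(q1, q_flip) == pytest.approx(math.pi)
        assert orientational_distance(q1, q_flip, water_symmetry=True) == pytest.approx(0.0)

    def test_recovered_from_built_waters(self):
        rng = np.random.default_rng(3)
        q = random_unit_quaternions(rng, 1)[0]
        coords = build_rigid_water([1.0, 2.0, 3.0], q)
        q_back = water_orientation_quaternion(coords[0], coords[1], coords[2])
        assert orientational_distance(q, q_back) == pytest.approx(0.0, abs=1e-9)


class TestTranslationalDistance:
    def test_zero_and_wraparound(self):
        box = np.array([10.0, 10.0, 10.0])
        assert translational_distance([1, 1, 1], [1, 1, 1], box) == 0.0
        assert translational_distance([0, 0, 0], [9.0, 0, 0], box) == pytest.approx(1.0)

    def test_matches_27_image_enumeration(self):
        rng = np.random.default_rng(7)
        box = np.array([8.0, 11.0, 5.0])
        for _ in range(100):
            p1, p2 = rng.uniform(0, 1, size=(2, 3)) * box
            best = min(
                np.linalg.norm(p2 + np.array(s) * box - p1)
                for s in itertools.product((-1, 0, 1), repeat=3)
            )
            assert translational_distance(p1, p2, box) == pytest.approx(best, abs=1e-12)


def _random_observations(rng, n_frames, per_frame, box, volume=None):
    obs = []
    for fi in range(n_frames):
        for _ in range(per_frame):
            obs.append(WaterObservation(
                frame_index=fi,
                position=rng.uniform(0, 1, 3) * box,
                orientation=random_unit_quaternions(rng, 1)[0],
                frame_volume=volume or float(np.prod(box)),
            ))
    return obs


class TestNearestNeighborSearch:
    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(11)
        box = np.array([6.0, 6.0, 6.0])
        obs = _random_observations(rng, 150, 3, box)  # 450 observations
        cfg = EstimatorConfig()
        pos = np.stack([o.position for o in obs])
        quats = np.stack([o.orientation for o in obs])
        frames = np.array([o.frame_index for o in obs])
        fast = nearest_neighbor_distances(pos, quats, frames, box, cfg)
        for i in range(len(obs)):
            best = math.inf
            for j in range(len(obs)):
                if i == j or frames[i] == frames[j]:
                    continue
                d = math.sqrt(
                    translational_distance(pos[i], pos[j], box) ** 2
                    + orientational_distance(quats[i], quats[j]) ** 2
                )
                best = min(best, d)
            assert fast[i] == pytest.approx(best, abs=1e-12)

    def test_same_frame_exclusion_is_configurable(self):
        rng = np.random.default_rng(2)
        box = np.array([4.0, 4.0, 4.0])
        obs = _random_observations(rng, 5, 4, box)
        pos = np.stack([o.position for o in obs])
        quats = np.stack([o.orientation for o in obs])
        frames = np.array([o.frame_index for o in obs])
        d_excl = nearest_neighbor_distances(pos, quats, frames, box, EstimatorConfig())
        d_incl = nearest_neighbor_distances(
            pos, quats, frames, box, EstimatorConfig(exclude_same_frame_neighbors=False))
        assert np.all(d_incl <= d_excl + 1e-12)
        assert np.any(d_incl < d_excl)


class TestSswEstimator:
    def test_fewer_than_two_observations_is_an_error(self):
        rng = np.random.default_rng(0)
        obs = _random_observations(rng, 1, 1, np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError):
            ssw_knn(obs, np.array([2.0, 2.0, 2.0]))

    def test_identical_observations_are_degenerate(self):
        o = WaterObservation(0, [1, 1, 1], [1, 0, 0, 0], 8.0)
        dup = [WaterObservation(i, [1, 1, 1], [1, 0, 0, 0], 8.0) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ssw_knn(dup, np.array([2.0, 2.0, 2.0]))

    def test_duplicates_are_dropped_with_a_warning(self):
        rng = np.random.default_rng(4)
        box = np.array([2.0, 2.0, 2.0])
        obs = _random_observations(rng, 200, 1, box)
        obs.append(WaterObservation(200, obs[0].position, obs[0].orientation, 8.0))
        obs.append(WaterObservation(201, obs[0].position, obs[0].orientation, 8.0))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            ssw_knn(obs, box, total_frames=202)

    def test_tighter_confinement_never_increases_entropy(self):
        vals = []
        for sigma in (0.12, 0.25, 0.5):
            top, ens = gen_gaussian_sites(GeneratorSpec(
                seed=9, n_frames=1200, box=(20.0, 20.0, 20.0),
                recipe="gaussian_sites",
                params={"sigma": sigma, "orientation_law": "fixed"}))
            obs = extract_water_observations(ens, top)
            vals.append(ssw_knn(obs, ens.frames[0].box, total_frames=ens.n_frames))
        assert vals[0] < vals[1] < vals[2]


class TestBulkReference:
    def test_builtin_lookup_and_consistency(self):
        ref = bulk_reference("TIP3P", 0)
        assert ref.E_bulk == -9.8 and ref.minus_T_S_bulk == pytest.approx(
            ref.G_bulk - ref.E_bulk, abs=1e-9)

    def test_unknown_treatment_raises(self):
        with pytest.raises(KeyError):
            bulk_reference("SPC/E", 0)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            BulkReference("TIP3P", 0, -9.8, -5.0, 3.5)


def _static_water_system(n_other=0, charged=True):
    """One stationary water (plus optional charged neighbors), many frames."""
    solute = [
        simple_atom(i, "CL", "ION", 50 + i, mol="ion", element="C",
                    charge=-0.5 if charged else 0.0, eps=0.1, rmh=2.2)
        for i in range(n_other)
    ]
    top = water_topology(1, solute_atoms=solute)
    rng = np.random.default_rng(12)
    frames = []
    for _ in range(10):
        w = build_rigid_water([10.0, 10.0, 10.0], random_unit_quaternions(rng, 1)[0])
        solute_pos = np.array([[13.0 + 2.0 * i, 10.0, 10.0] for i in range(n_other)])
        coords = np.concatenate([solute_pos.reshape(n_other, 3), w])
        frames.append(Frame(coordinates=coords, box=(30.0, 30.0, 30.0)))
    ens = TrajectoryEnsemble(state_label="native", replicate_id=0,
                             ensemble_kind="fixed_NVT", frames=frames, topology=top)
    return top, ens


class TestSiteThermodynamics:
    def test_isolated_water_site_energy_is_zero(self):
        top, ens = _static_water_system(n_other=0)
        site = HydrationSite(center=np.array([10.0, 10.0, 10.0]), n_eff=1.0)
        bulk = bulk_reference("TIP3P", 0)
        e_site, de = site_energy(site, ens, top, bulk)
        assert e_site == pytest.approx(0.0, abs=1e-12)
        assert de == pytest.approx(-1.0 * bulk.E_bulk, abs=1e-12)

    def test_site_energy_matches_brute_force_pair_sum(self):
        from hydrofold.nonbonded import EnergyOptions, pair_energy

        top, ens = _static_water_system(n_other=2)
        site = HydrationSite(center=np.array([10.0, 10.0, 10.0]), n_eff=1.0)
        bulk = bulk_reference("TIP3P", 0)
        e_site, _ = site_energy(site, ens, top, bulk)
        opts = EnergyOptions()
        water_atoms = [2, 3, 4]
        expected = np.mean([
            sum(pair_energy(i, j, f, top, opts)
                for i in water_atoms for j in range(top.n_atoms) if j not in water_atoms)
            for f in ens.frames
        ])
        assert e_site == pytest.approx(expected, rel=1e-9)

    def test_never_occupied_site_is_an_error(self):
        top, ens = _static_water_system()
        site = HydrationSite(center=np.array([2.0, 2.0, 2.0]), n_eff=0.0)
        with pytest.raises(ValueError, match="never occupied"):
            site_energy(site, ens, top, bulk_reference("TIP3P", 0))

    def test_free_energy_accounting_identity(self):
        bulk = bulk_reference("TIP3P", 0)
        cfg = EstimatorConfig()
        site = HydrationSite(center=np.zeros(3), n_eff=0.9, occupancy=0.9,
                             delta_E_ifst=-2.5, S_sw=-0.01)
        site = site_free_energy(site, bulk, cfg)
        assert site.delta_G_ifst == pytest.approx(
            site.delta_E_ifst + site.minus_T_delta_S, abs=1e-12)

    def test_bulk_like_entropy_gives_zero_entropy_penalty(self):
        bulk = bulk_reference("TIP3P", 0)
        cfg = EstimatorConfig()
        s_bulk = -bulk.minus_T_S_bulk / cfg.temperature_T
        site = HydrationSite(center=np.zeros(3), n_eff=1.0, occupancy=1.0,
                             delta_E_ifst=0.0, S_sw=s_bulk)
        site = site_free_energy(site, bulk, cfg)
        assert site.minus_T_delta_S == pytest.approx(0.0, abs=1e-12)
        assert site.delta_G_ifst == pytest.approx(0.0, abs=1e-12)


class TestClustering:
    def test_uniform_bulk_yields_no_high_occupancy_sites(self):
        top, ens = gen_uniform_water_box(GeneratorSpec(
            seed=13, n_frames=40, box=(16.0, 16.0, 16.0), params={"n_waters": 30}))
        sites = cluster_hydration_sites(ens, top, surface_cutoff=None)
        assert sites == []

    def test_planted_locus_outside_the_surface_shell_is_filtered(self):
        centers = [[6.0, 10.0, 10.0], [16.0, 10.0, 10.0]]
        top, ens = gen_gaussian_sites(GeneratorSpec(
            seed=14, n_frames=200, box=(20.0, 20.0, 20.0),
            recipe="gaussian_sites",
            params={"sigma": 0.25, "centers": centers,
                    "protein_position": [7.0, 10.0, 10.0]}))
        near = cluster_hydration_sites(ens, top, surface_cutoff=4.1)
        assert len(near) == 1
        assert np.linalg.norm(near[0].center - centers[0]) < 0.2
        both = cluster_hydration_sites(ens, top, surface_cutoff=None)
        assert len(both) == 2

    def test_empty_water_set_is_an_error(self):
        top = Topology(atoms=[simple_atom(0)])
        frames = [Frame(coordinates=[[0.0, 0.0, 0.0]], box=(10.0, 10.0, 10.0))]
        ens = TrajectoryEnsemble(state_label="native", replicate_id=0,
                                 ensemble_kind="fixed_NVT", frames=frames, topology=top)
        with pytest.raises(ValueError, match="no water"):
            cluster_hydration_sites(ens, top)
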
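"""Seeded snapshot generators with known statistical structure.

These generators stand in for MD trajectories so that every pipeline stage
can be exercised against planted ground truth:

* ``uniform_box`` -- rigid waters uniform in position and orientation; the
  homogeneous zero point of the solute-water entropy estimator (S_sw = 0)
  and the Poisson reference for nearest-neighbor statistics.
* ``gaussian_sites`` -- one water per planted site per frame with isotropic
  Gaussian positional scatter; translational entropy has a closed form.
* ``two_state_toy`` -- a small multi-group solute rendered compact (planted
  hydrogen bond / non-polar contact / water bridge) and extended (the same
  groups solvent-separated), identical particle inventory in both states.
* ``bernoulli_contacts`` -- replicate ensembles in which a planted contact
  is in-criteria with probability p per frame, the oracle for the
  persistence filter.

No attempt is made at thermodynamically realistic water structure; the
point is exactly known geometry, occupancy, and presence statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import (
    AtomRecord,
    Frame,
    TIP3P_GEOMETRY,
    TIP4P2005_GEOMETRY,
    Topology,
    TrajectoryEnsemble,
    WaterGeometry,
    assign_symmetry_groups,
)

__all__ = [
    "GeneratorSpec",
    "build_rigid_water",
    "water_topology",
    "random_unit_quaternions",
    "gen_uniform_water_box",
    "gen_gaussian_sites",
    "gen_two_state_toy",
    "gen_bernoulli_contacts",
    "generate",
]

#: Non-bonded parameters for the bundled water models:
#: (name, element, charge e, epsilon kcal/mol, rmin/2 A, acceptor)
WATER_SITE_PARAMS = {
    "TIP3P": (
        ("O", "O", -0.834, 0.1521, 1.7682, True),
        ("H1", "H", 0.417, 0.0460, 0.2245, False),
        ("H2", "H", 0.417, 0.0460, 0.2245, False),
    ),
    "TIP4P-2005": (
        ("O", "O", 0.0, 0.1852, 1.7729, True),
        ("H1", "H", 0.5564, 0.0, 0.0, False),
        ("H2", "H", 0.5564, 0.0, 0.0, False),
        ("MW", "M", -1.1128, 0.0, 0.0, False),
    ),
}

#: Small bundled parameter set for toy solute groups (CHARMM-like classes):
#: carbonyl C/O, amide N/H with a stub carbon, and a methyl group.
TOY_PARAMS = {
    "C": dict(element="C", charge=0.51, epsilon=0.11, rmin_half=2.0, acceptor=False),
    "O": dict(element="O", charge=-0.51, epsilon=0.12, rmin_half=1.7, acceptor=True),
    "N": dict(element="N", charge=-0.30, epsilon=0.20, rmin_half=1.85, acceptor=False),
    "HN": dict(element="H", charge=0.33, epsilon=0.046, rmin_half=0.2245, acceptor=False),
    "CB": dict(element="C", charge=-0.03, epsilon=0.08, rmin_half=2.06, acceptor=False),
    # apolar probe group: zero partial charges so a planted non-polar contact
    # is purely dispersive (sign-stable against distant dipolar fields)
    "CG": dict(element="C", charge=0.0, epsilon=0.08, rmin_half=2.06, acceptor=False),
    "HG": dict(element="H", charge=0.0, epsilon=0.024, rmin_half=1.34, acceptor=False),
}


@dataclass
class GeneratorSpec:
    """A seeded generation request; identical specs yield identical ensembles."""

    seed: int = 0
    n_frames: int = 5000
    box: tuple[float, float, float] = (2.0, 2.0, 2.0)
    water_model: str = "TIP3P"
    recipe: str = "uniform_box"
    params: dict = field(default_factory=dict)


def _geometry(model: str) -> WaterGeometry:
    return TIP4P2005_GEOMETRY if model.upper().startswith("TIP4P") else TIP3P_GEOMETRY


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    return Rotation.from_quat(np.concatenate([q[1:], q[:1]])).as_matrix()


def _matrix_to_quat(rot: np.ndarray) -> np.ndarray:
    q_xyzw = Rotation.from_matrix(rot).as_quat()
    q = np.concatenate([[q_xyzw[3]], q_xyzw[:3]])
    return q if q[0] >= 0 else -q


def reference_water_coords(geometry: WaterGeometry) -> np.ndarray:
    """Site coordinates of the reference-oriented rigid water.

    Oxygen at the origin, H-O-H bisector along +z, molecular plane = xz,
    H1 at positive x; 4-site models place the charge site on the bisector.
    """
    half = math.radians(geometry.theta_HOH / 2.0)
    h1 = geometry.r_OH * np.array([math.sin(half), 0.0, math.cos(half)])
    h2 = geometry.r_OH * np.array([-math.sin(half), 0.0, math.cos(half)])
    coords = [np.zeros(3), h1, h2]
    if geometry.n_sites == 4:
        coords.append(geometry.r_OL * np.array([0.0, 0.0, 1.0]))
    return np.stack(coords)


def build_rigid_water(position: np.ndarray, orientation: np.ndarray,
                      geometry: WaterGeometry = TIP3P_GEOMETRY) -> np.ndarray:
    """Rigid water site coordinates at ``position`` rotated by ``orientation``.

    ``orientation`` is a unit quaternion (scalar-first) applied to the
    reference-oriented molecule.
    """
    q = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-9:
        raise ValueError("orientation must be a unit quaternion")
    ref = reference_water_coords(geometry)
    return ref @ _quat_to_matrix(q).T + np.asarray(position, dtype=float)


def random_unit_quaternions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotations as unit quaternions (scalar-first)."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def water_topology(n_waters: int, model: str = "TIP3P",
                   solute_atoms: Sequence[AtomRecord] = (),
                   solute_bonds: Sequence[tuple[int, int]] = ()) -> Topology:
    """Topology of ``n_waters`` rigid waters, optionally appended to a solute."""
    atoms = list(solute_atoms)
    bonds = list(solute_bonds)
    params = WATER_SITE_PARAMS[model.upper().replace("TIP4P2005", "TIP4P-2005")]
    for w in range(n_waters):
        o_index = len(atoms)
        for s, (name, element, charge, eps, rmh, acceptor) in enumerate(params):
            atoms.append(
                AtomRecord(
                    atom_index=o_index + s,
                    atom_name=name,
                    residue_name="HOH",
                    residue_number=1000 + w,
                    molecule_class="water",
                    element=element,
                    partial_charge=charge,
                    lj_epsilon=eps,
                    lj_rmin_half=rmh,
                    is_acceptor=acceptor,
                )
            )
            if s > 0:
                bonds.append((o_index, o_index + s))
    return assign_symmetry_groups(Topology(atoms=atoms, bonds=bonds))


def _water_block(positions: np.ndarray, quats: np.ndarray,
                 geometry: WaterGeometry) -> np.ndarray:
    """Stacked site coordinates for many waters (one frame)."""
    blocks = [build_rigid_water(p, q, geometry) for p, q in zip(positions, quats)]
    return np.concatenate(blocks) if blocks else np.empty((0, 3))


# ---------------------------------------------------------------------------
# uniform box
# ---------------------------------------------------------------------------


def gen_uniform_water_box(spec: GeneratorSpec) -> tuple[Topology, TrajectoryEnsemble]:
    """Waters uniform in the box with uniform orientations, per frame.

    Default conditions (1 water, 5000 frames, 2.5 A box) are the calibration
    regime of the entropy estimator's homogeneous zero point: dense enough
    that nearest-neighbor distances sit well inside the curvature scale of
    the rotation group.
    """
    rng = np.random.default_rng(spec.seed)
    n_waters = int(spec.params.get("n_waters", 1))
    box = np.asarray(spec.box, dtype=float)
    geometry = _geometry(spec.water_model)
    top = water_topology(n_waters, spec.water_model)
    frames = []
    for _ in range(spec.n_frames):
        pos = rng.uniform(0.0, 1.0, size=(n_waters, 3)) * box
        quats = random_unit_quaternions(rng, n_waters)
        frames.append(Frame(coordinates=_water_block(pos, quats, geometry), box=box))
    ens = TrajectoryEnsemble(
        state_label="native", replicate_id=0, ensemble_kind="fixed_NVT",
        frames=frames, sampling_interval=2.0, topology=top,
    )
    return top, ens


# ---------------------------------------------------------------------------
# gaussian-confined sites
# ---------------------------------------------------------------------------


def _orientation_batch(rng: np.random.Generator, n: int, law: str,
                       concentration_deg: float = 10.0) -> np.ndarray:
    if law == "uniform":
        return random_unit_quaternions(rng, n)
    if law == "fixed":
        return np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    if law == "concentrated":
        # small random rotations about random axes around the identity
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = np.abs(rng.normal(0.0, math.radians(concentration_deg), size=n))
        half = angles / 2.0
        return np.column_stack([np.cos(half), axes * np.sin(half)[:, None]])
    raise ValueError(f"unknown orientation law {law!r}")


def gen_gaussian_sites(spec: GeneratorSpec) -> tuple[Topology, TrajectoryEnsemble]:
    """One water per planted site per frame, Gaussian positional scatter.

    params: ``centers`` (list of xyz), ``sigma`` (A, default 0.25),
    ``orientation_law`` in {uniform, fixed, concentrated},
    ``protein_position`` (optional xyz of a fixed dummy solute atom).
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    centers = np.asarray(spec.params.get("centers", [box / 2.0]), dtype=float)
    sigma = float(spec.params.get("sigma", 0.25))
    law = spec.params.get("orientation_law", "uniform")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 2.4:
                raise ValueError("planted sites closer than 2.4 A overlap")
    geometry = _geometry(spec.water_model)

    solute_atoms: list[AtomRecord] = []
    protein_position = spec.params.get("protein_position")
    if protein_position is not None:
        solute_atoms.append(
            AtomRecord(
                atom_index=0, atom_name="CA", residue_name="ALA", residue_number=1,
                molecule_class="protein", element="C", partial_charge=0.0,
                lj_epsilon=0.02, lj_rmin_half=2.0,
            )
        )
    top = water_topology(len(centers), spec.water_model, solute_atoms=solute_atoms)
    n_solute = len(solute_atoms)

    frames = []
    for _ in range(spec.n_frames):
        pos = centers + rng.normal(0.0, sigma, size=centers.shape)
        quats = _orientation_batch(rng, len(centers), law)
        coords = _water_block(pos, quats, geometry)
        if n_solute:
            coords = np.concatenate([np.asarray([protein_position], dtype=float), coords])
        frames.append(Frame(coordinates=coords, box=box))
    ens = TrajectoryEnsemble(
        state_label="native", replicate_id=0, ensemble_kind="fixed_NVT",
        frames=frames, sampling_interval=2.0, topology=top,
    )
    return top, ens


# ---------------------------------------------------------------------------
# two-state toy solute
# ---------------------------------------------------------------------------


def _toy_atom(index: int, name: str, key: str, resname: str, resid: int) -> AtomRecord:
    p = TOY_PARAMS[key]
    return AtomRecord(
        atom_index=index, atom_name=name, residue_name=resname, residue_number=resid,
        molecule_class="protein", element=p["element"], partial_charge=p["charge"],
        lj_epsilon=p["epsilon"], lj_rmin_half=p["rmin_half"], is_acceptor=p["acceptor"],
    )


_METHYL_DIRS = np.array([
    [0.943, 0.0, -0.333],
    [-0.471, 0.816, -0.333],
    [-0.471, -0.816, -0.333],
])


def _build_contact_unit(kind: str, base: np.ndarray, resid0: int, start_index: int):
    """Atoms, bonds, and compact/extended coordinates for one planted contact.

    Returns (atoms, bonds, compact_coords, extended_coords, moving_mask);
    the second group of the pair is displaced along +z in the extended state.
    """
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    compact: list[np.ndarray] = []
    moving: list[bool] = []

    def add(name, key, resname, resid, coord, move):
        atoms.append(_toy_atom(start_index + len(atoms), name, key, resname, resid))
        compact.append(np.asarray(coord, dtype=float))
        moving.append(move)

    z = np.array([0.0, 0.0, 1.0])
    if kind == "hbond":
        # carbonyl acceptor (fixed) + amide donor (moving), collinear N-H...O=C
        add("O", "O", "GLY", resid0, base, False)
        add("C", "C", "GLY", resid0, base - 1.23 * z, False)
        add("N", "N", "ALA", resid0 + 1, base + 2.9 * z, True)
        add("HN", "HN", "ALA", resid0 + 1, base + 1.9 * z, True)
        add("CB", "CB", "ALA", resid0 + 1, base + 4.35 * z, True)
        bonds += [(0, 1), (2, 3), (2, 4)]
    elif kind == "nonpolar":
        add("CG", "CG", "ILE", resid0, base, False)
        for k, d in enumerate(_METHYL_DIRS):
            add(f"HG{k + 1}", "HG", "ILE", resid0, base + 1.09 * d, False)
        add("CG", "CG", "LEU", resid0 + 1, base + 4.1 * z, True)
        for k, d in enumerate(_METHYL_DIRS * np.array([1.0, 1.0, -1.0])):
            add(f"HG{k + 1}", "HG", "LEU", resid0 + 1, base + 4.1 * z + 1.09 * d, True)
        bonds += [(0, 1), (0, 2), (0, 3), (4, 5), (4, 6), (4, 7)]
    elif kind == "coophyd":
        # two carbonyl acceptors 5.0 A apart, bridged by a dedicated water
        add("O", "O", "SER", resid0, base, False)
        add("C", "C", "SER", resid0, base - 1.23 * z, False)
        add("O", "O", "THR", resid0 + 1, base + 5.0 * z, True)
        add("C", "C", "THR", resid0 + 1, base + 6.23 * z, True)
        bonds += [(0, 1), (2, 3)]
    else:
        raise ValueError(f"unknown planted contact kind {kind!r}")

    bonds = [(start_index + i, start_index + j) for i, j in bonds]
    return atoms, bonds, np.stack(compact), np.asarray(moving)


def _bridge_water_pose(o1: np.ndarray, o2: np.ndarray, offset_y: float = 1.28):
    """Position/orientation of a water bridging two acceptors, hydrogens
    pointed at the two oxygens."""
    mid = (o1 + o2) / 2.0 + np.array([0.0, offset_y, 0.0])
    u1 = (o1 - mid) / np.linalg.norm(o1 - mid)
    u2 = (o2 - mid) / np.linalg.norm(o2 - mid)
    b = (u1 + u2) / np.linalg.norm(u1 + u2)
    p = (u1 - u2) / np.linalg.norm(u1 - u2)
    rot = np.column_stack([p, np.cross(b, p), b])
    return mid, _matrix_to_quat(rot)


def _place_waters(rng, n, box, avoid_coords, min_solute_dist, min_water_dist, max_tries=20000):
    placed: list[np.ndarray] = []
    avoid = np.asarray(avoid_coords, dtype=float)
    for _ in range(max_tries):
        if len(placed) == n:
            break
        cand = rng.uniform(0.0, 1.0, size=3) * box
        if len(avoid) and np.min(np.linalg.norm(avoid - cand, axis=1)) < min_solute_dist:
            continue
        if placed and np.min(np.linalg.norm(np.asarray(placed) - cand, axis=1)) < min_water_dist:
            continue
        placed.append(cand)
    if len(placed) < n:
        raise RuntimeError("could not place waters; box too crowded for the exclusion radii")
    return np.stack(placed)


def gen_two_state_toy(spec: GeneratorSpec):
    """Compact and extended replicate ensembles of a planted-contact solute.

    params: ``contacts`` (list of kinds, default one of each),
    ``n_waters`` (default 12), ``n_replicates`` (default 3),
    ``jitter`` (A, default 0.03), ``separation`` (A, default 25.0),
    ``water_exclusion`` (A, default 12.0).

    Both states share one topology (identical particle inventory); in the
    extended state the second group of every planted pair is displaced by
    ``separation`` along +z so the partners are solvent-separated.  Bulk
    waters are kept ``water_exclusion`` away from the solute in *both*
    conformations so their random dipolar fields perturb the planted
    interaction energies only weakly.
    """
    contacts = list(spec.params.get("contacts", ["hbond", "nonpolar", "coophyd"]))
    n_waters = int(spec.params.get("n_waters", 12))
    n_replicates = int(spec.params.get("n_replicates", 3))
    jitter = float(spec.params.get("jitter", 0.03))
    separation = float(spec.params.get("separation", 25.0))
    water_excl = float(spec.params.get("water_exclusion", 12.0))
    box = np.asarray(spec.params.get("box", (42.0, 42.0, 72.0)), dtype=float)
    geometry = _geometry(spec.water_model)

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    compact_parts: list[np.ndarray] = []
    moving_parts: list[np.ndarray] = []
    bridge_pairs: list[tuple[int, int]] = []  # (O1, O2) atom indices per coophyd
    for k, kind in enumerate(contacts):
        base = np.array([9.0 + 12.0 * k, box[1] / 2.0, 20.0])
        start = len(atoms)
        a, b, coords, moving = _build_contact_unit(kind, base, resid0=10 * (k + 1), start_index=start)
        if kind == "coophyd":
            bridge_pairs.append((start, start + 2))
        atoms += a
        bonds += b
        compact_parts.append(coords)
        moving_parts.append(moving)
    compact_solute = np.concatenate(compact_parts)
    moving_mask = np.concatenate(moving_parts)
    extended_solute = compact_solute.copy()
    extended_solute[moving_mask] += np.array([0.0, 0.0, separation])
    n_solute = len(atoms)

    if len(bridge_pairs) > n_waters - 1:
        raise ValueError("not enough waters for the requested bridges")
    top = water_topology(n_waters, spec.water_model, solute_atoms=atoms, solute_bonds=bonds)
    sites_per_water = geometry.n_sites

    compact_ens, extended_ens = [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng([spec.seed, rep])
        base_wpos = _place_waters(
            rng, n_waters, box,
            np.concatenate([compact_solute, extended_solute]),
            water_excl, 2.8,
        )
        base_quats = random_unit_quaternions(rng, n_waters)
        # dedicate the first waters to the planted bridges (compact state only)
        bridge_pos, bridge_quat = [], []
        for o1, o2 in bridge_pairs:
            pos, quat = _bridge_water_pose(compact_solute[o1 - 0], compact_solute[o2 - 0])
            bridge_pos.append(pos)
            bridge_quat.append(quat)

        def make_frames(solute_coords, bridged):
            frames = []
            for _ in range(spec.n_frames):
                wpos = base_wpos.copy()
                wq = base_quats.copy()
                if bridged:
                    for bi, (p, q) in enumerate(zip(bridge_pos, bridge_quat)):
                        wpos[bi] = p
                        wq[bi] = q
                coords = np.concatenate([
                    solute_coords + rng.normal(0.0, jitter, size=solute_coords.shape),
                    _water_block(wpos, wq, geometry)
                    + np.repeat(rng.normal(0.0, jitter, size=(n_waters, 3)),
                                sites_per_water, axis=0),
                ])
                frames.append(Frame(coordinates=coords, box=box))
            return frames

        compact_ens.append(TrajectoryEnsemble(
            state_label="native", replicate_id=rep, ensemble_kind="restrained_NPT",
            frames=make_frames(compact_solute, bridged=True),
            sampling_interval=100.0, topology=top,
        ))
        extended_ens.append(TrajectoryEnsemble(
            state_label="extended", replicate_id=rep, ensemble_kind="restrained_NPT",
            frames=make_frames(extended_solute, bridged=False),
            sampling_interval=100.0, topology=top,
        ))
    return top, compact_ens, extended_ens


# ---------------------------------------------------------------------------
# Bernoulli persistence oracle
# ---------------------------------------------------------------------------


def gen_bernoulli_contacts(spec: GeneratorSpec):
    """Replicates in which each planted hydrogen bond is present w.p. ``p``.

    params: ``p`` (presence probability, default 0.6), ``n_contacts``
    (default 1), ``n_replicates`` (default 40); ``spec.n_frames`` frames per
    replicate (study convention: 40 x 100).  An absent contact's donor group
    is displaced 8 A along z, far outside every criterion.
    """
    p = float(spec.params.get("p", 0.6))
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    n_contacts = int(spec.params.get("n_contacts", 1))
    n_replicates = int(spec.params.get("n_replicates", 40))
    n_frames = spec.n_frames if spec.n_frames != 5000 else 100
    box = np.asarray(spec.params.get("box", (30.0, 30.0, 30.0)), dtype=float)

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    compact_parts = []
    moving_parts = []
    for k in range(n_contacts):
        base = np.array([6.0 + 9.0 * k, box[1] / 2.0, 10.0])
        a, b, coords, moving = _build_contact_unit("hbond", base, 10 * (k + 1), len(atoms))
        atoms += a
        bonds += b
        compact_parts.append(coords)
        moving_parts.append(moving)
    present = np.concatenate(compact_parts)
    moving_mask = np.concatenate(moving_parts)
    absent = present.copy()
    absent[moving_mask] += np.array([0.0, 0.0, 8.0])
    top = water_topology(0, spec.water_model, solute_atoms=atoms, solute_bonds=bonds)

    unit_of = np.repeat(np.arange(n_contacts), len(present) // n_contacts)
    ensembles = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([spec.seed, rep])
        frames = []
        for _ in range(n_frames):
            on = rng.random(n_contacts) < p
            coords = np.where(on[unit_of, None], present, absent)
            coords = coords + rng.normal(0.0, 0.02, size=coords.shape)
            frames.append(Frame(coordinates=coords, box=box))
        ensembles.append(TrajectoryEnsemble(
            state_label="native", replicate_id=rep, ensemble_kind="restrained_NPT",
            frames=frames, sampling_interval=100.0, topology=top,
        ))
    return top, ensembles


_RECIPES = {
    "uniform_box": gen_uniform_water_box,
    "gaussian_sites": gen_gaussian_sites,
    "two_state_toy": gen_two_state_toy,
    "bernoulli_contacts": gen_bernoulli_contacts,
}


def generate(spec: GeneratorSpec):
    """Dispatch on ``spec.recipe``; return value depends on the recipe."""
    try:
        fn = _RECIPES[spec.recipe]
    except KeyError:
        raise ValueError(f"unknown recipe {spec.recipe!r}") from None
    return fn(spec)
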
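"""Pairwise non-bonded energies and the decompositions built on them.

The energy model is the classical fixed-charge form: a Coulomb term
``C q_i q_j / r_ij`` plus a 12-6 Lennard-Jones term with Lorentz-Berthelot
combination (geometric-mean well depth, additive rmin/2).  The LJ term is
multiplied by the CHARMM energy-switching function between ``vdw_switch_on``
and ``vdw_cutoff`` and is zero beyond the cutoff; distances use the minimum
image convention under the orthorhombic box.

Per-atom and per-group attributions are only well defined for pairwise
energy forms, so the electrostatics here are direct sums (optionally
truncated), never mesh/Ewald; the scheme used is recorded in
:class:`EnergyOptions` and carried into report metadata.

The single shared kernel is the *group energy*

    E_group = 1/2 * sum_{i in group} sum_{j != i} E_ij ,

whose special cases are the per-atom energy (singleton group), the total
non-bonded energy (group = all atoms), and the interaction energies assigned
to hydrogen bonds, non-polar contacts, and cooperatively hydrated pairs.
Pairs internal to the group count once; pairs with the environment count at
half weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model_io import (
    Frame,
    Topology,
    TrajectoryEnsemble,
    TrajectoryError,
    minimum_image_displacement,
)

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyOptions",
    "StateEnergyResult",
    "AtomEnergyResult",
    "BondedParameters",
    "pair_energy",
    "interaction_rows",
    "group_energy",
    "total_nonbonded_energy",
    "ensemble_total_energy",
    "state_energy_difference",
    "state_energy_statistics",
    "bonded_energy",
    "atom_energy_table",
    "component_breakdown",
]

#: kcal*Angstrom/mol/e^2; the MD-engine convention for 1/(4 pi eps0).
COULOMB_CONSTANT = 332.0636


@dataclass
class EnergyOptions:
    """Non-bonded evaluation settings.

    vdW interactions switch off between ``vdw_switch_on`` and ``vdw_cutoff``
    (defaults 9.0 / 11.0 Angstrom).  Electrostatics are direct pairwise sums:
    ``direct_all_pairs`` (every minimum-image pair) or ``direct_cutoff``
    (truncated at ``elec_cutoff``).
    """

    coulomb_constant: float = COULOMB_CONSTANT
    vdw_switch_on: float = 9.0
    vdw_cutoff: float = 11.0
    elec_scheme: str = "direct_all_pairs"
    elec_cutoff: float | None = None
    minimum_image: bool = True

    def __post_init__(self) -> None:
        if not self.vdw_switch_on < self.vdw_cutoff:
            raise ValueError("vdw_switch_on must be less than vdw_cutoff")
        if self.elec_scheme not in ("direct_all_pairs", "direct_cutoff"):
            raise ValueError(f"unknown electrostatics scheme {self.elec_scheme!r}")
        if self.elec_scheme == "direct_cutoff" and not self.elec_cutoff:
            raise ValueError("direct_cutoff scheme requires elec_cutoff")

    def validate_box(self, box: np.ndarray) -> None:
        if self.minimum_image:
            half = float(np.min(box)) / 2.0
            cuts = [self.vdw_cutoff] + ([self.elec_cutoff] if self.elec_cutoff else [])
            if any(c >= half for c in cuts):
                raise ValueError(
                    f"cutoffs {cuts} must be below half the smallest box length ({half:.2f})"
                )


@dataclass
class StateEnergyResult:
    """Mean total energy of one state, with spread over replicate simulations."""

    state_label: str
    mean_energy: float
    std_over_replicates: float
    n_snapshots: int


@dataclass
class AtomEnergyResult:
    """Per-atom interaction energy in two states and their difference."""

    atom_index: int
    E_atom_native: float
    E_atom_extended: float
    delta_E_atom: float
    partial_charge: float
    is_polar: bool


def _switch_factor(r2: np.ndarray, ron: float, roff: float) -> np.ndarray:
    """CHARMM vdW energy-switching function evaluated on squared distances."""
    ron2, roff2 = ron * ron, roff * roff
    denom = (roff2 - ron2) ** 3
    sw = ((roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2)) / denom
    out = np.where(r2 <= ron2, 1.0, sw)
    return np.where(r2 >= roff2, 0.0, out)


def interaction_rows(
    rows: Sequence[int] | np.ndarray,
    frame: Frame,
    topology: Topology,
    options: EnergyOptions,
) -> np.ndarray:
    """Non-bonded energies E_ij for each row atom i against every atom j.

    Returns an array of shape (len(rows), n_atoms) with zeros at self-pairs
    and excluded (1-2/1-3/1-4) pairs.  Raises on exactly overlapping
    non-excluded atoms.
    """
    rows = np.asarray(rows, dtype=int)
    coords = frame.coordinates
    box = frame.box
    options.validate_box(box)
    delta = coords[rows][:, None, :] - coords[None, :, :]
    if options.minimum_image:
        delta = minimum_image_displacement(delta, box)
    r2 = np.einsum("ijk,ijk->ij", delta, delta)

    excl = topology.exclusion_mask()[rows]
    zero_r = r2 <= 0.0
    if np.any(zero_r & ~excl):
        bad = np.argwhere(zero_r & ~excl)[0]
        raise ValueError(
            f"overlapping atoms: {rows[bad[0]]} and {bad[1]} at zero distance"
        )
    r2_safe = np.where(zero_r, 1.0, r2)
    inv_r = 1.0 / np.sqrt(r2_safe)

    q = topology.charges
    elec = options.coulomb_constant * np.outer(q[rows], q) * inv_r
    if options.elec_scheme == "direct_cutoff":
        elec = np.where(r2 > options.elec_cutoff**2, 0.0, elec)

    eps = topology.lj_epsilons
    rmh = topology.lj_rmin_halves
    eps_ij = np.sqrt(np.outer(eps[rows], eps))
    rmin_ij = rmh[rows][:, None] + rmh[None, :]
    s6 = (rmin_ij * rmin_ij / r2_safe) ** 3
    lj = eps_ij * (s6 * s6 - 2.0 * s6)
    lj *= _switch_factor(r2, options.vdw_switch_on, options.vdw_cutoff)

    energy = elec + lj
    energy[excl] = 0.0
    return energy


def pair_energy(
    i: int,
    j: int,
    frame: Frame,
    topology: Topology,
    options: EnergyOptions | None = None,
) -> float:
    """Non-bonded energy of one atom pair (0 for excluded pairs)."""
    if i == j:
        raise ValueError("pair energy requires two distinct atoms")
    options = options or EnergyOptions()
    return float(interaction_rows([i], frame, topology, options)[0, j])


def _iter_frames(frame_or_ensemble) -> list[Frame]:
    if isinstance(frame_or_ensemble, Frame):
        return [frame_or_ensemble]
    if isinstance(frame_or_ensemble, TrajectoryEnsemble):
        return frame_or_ensemble.frames
    raise TypeError("expected a Frame or TrajectoryEnsemble")


def group_energy(
    member_atoms: Iterable[int],
    frame_or_ensemble,
    topology: Topology,
    options: EnergyOptions | None = None,
) -> float:
    """1/2 sum over group members of their interaction with every other atom.

    Over an ensemble the snapshot mean is returned.
    """
    members = sorted(set(int(m) for m in member_atoms))
    if not members:
        raise ValueError("group_energy requires a non-empty atom set")
    options = options or EnergyOptions()
    values = [
        0.5 * float(interaction_rows(members, f, topology, options).sum())
        for f in _iter_frames(frame_or_ensemble)
    ]
    return float(np.mean(values))


def total_nonbonded_energy(
    frame: Frame, topology: Topology, options: EnergyOptions | None = None
) -> float:
    """Total non-bonded energy of a frame (group energy of all atoms)."""
    options = options or EnergyOptions()
    return 0.5 * float(
        interaction_rows(np.arange(topology.n_atoms), frame, topology, options).sum()
    )


# ---------------------------------------------------------------------------
# bonded terms (internal-consistency use; CMAP and Urey-Bradley omitted)
# ---------------------------------------------------------------------------


@dataclass
class BondedParameters:
    """Harmonic bond/angle, periodic dihedral, harmonic improper parameters.

    Conventions (CHARMM-style): E_bond = k_b (b - b0)^2 with b0 in Angstrom;
    E_angle = k_theta (theta - theta0)^2 with theta0 in degrees (evaluated in
    radians); E_dihedral = k_chi (1 + cos(n chi - delta)); E_improper =
    k_psi (psi - psi0)^2.  Note the force constants absorb the conventional
    1/2 factor.
    """

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int, float, float]] = field(default_factory=list)


def _angle_at(b: np.ndarray, a: np.ndarray, c: np.ndarray, box: np.ndarray) -> float:
    """Angle (radians) at vertex a between directions a->b and a->c."""
    v1 = minimum_image_displacement(b - a, box)
    v2 = minimum_image_displacement(c - a, box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3, box) -> float:
    b0 = minimum_image_displacement(p0 - p1, box)
    b1 = minimum_image_displacement(p2 - p1, box)
    b2 = minimum_image_displacement(p3 - p2, box)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))


def bonded_energy(frame: Frame, topology: Topology, params: BondedParameters) -> float:
    """Sum of bond + angle + dihedral + improper terms for one frame."""
    c = frame.coordinates
    box = frame.box
    e = 0.0
    for i, j, kb, b0 in params.bonds:
        r = np.linalg.norm(minimum_image_displacement(c[j] - c[i], box))
        e += kb * (r - b0) ** 2
    for i, j, k, kt, t0 in params.angles:
        theta = _angle_at(c[i], c[j], c[k], box)
        e += kt * (theta - np.deg2rad(t0)) ** 2
    for i, j, k, l, kchi, n, delta in params.dihedrals:
        chi = _dihedral(c[i], c[j], c[k], c[l], box)
        e += kchi * (1.0 + np.cos(n * chi - np.deg2rad(delta)))
    for i, j, k, l, kpsi, psi0 in params.impropers:
        psi = _dihedral(c[i], c[j], c[k], c[l], box)
        e += kpsi * (psi - np.deg2rad(psi0)) ** 2
    return float(e)


# ---------------------------------------------------------------------------
# state energies
# ---------------------------------------------------------------------------


def ensemble_total_energy(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    options: EnergyOptions | None = None,
    bonded_params: BondedParameters | None = None,
) -> float:
    """Snapshot-mean total energy (non-bonded plus optional bonded terms)."""
    options = options or EnergyOptions()
    vals = []
    for f in ensemble.frames:
        e = total_nonbonded_energy(f, topology, options)
        if bonded_params is not None:
            e += bonded_energy(f, topology, bonded_params)
        vals.append(e)
    return float(np.mean(vals))


def _check_inventory(top_a: Topology, top_b: Topology) -> None:
    if top_a.inventory() != top_b.inventory():
        raise TrajectoryError(
            "particle inventories differ between states; energy differences "
            "require the same number of particles of each type"
        )


def state_energy_difference(
    state: TrajectoryEnsemble,
    native: TrajectoryEnsemble,
    options: EnergyOptions | None = None,
    *,
    topology: Topology | None = None,
    bonded_params: BondedParameters | None = None,
) -> float:
    """Mean total energy of ``state`` minus mean total energy of ``native``.

    Both ensembles must carry (or be given) topologies with identical
    particle inventories.
    """
    top_state = state.topology or topology
    top_native = native.topology or topology
    if top_state is None or top_native is None:
        raise ValueError("a topology is required for both ensembles")
    _check_inventory(top_state, top_native)
    e_state = ensemble_total_energy(state, top_state, options, bonded_params)
    e_native = ensemble_total_energy(native, top_native, options, bonded_params)
    return e_state - e_native


def state_energy_statistics(
    replicates: Sequence[TrajectoryEnsemble],
    topology: Topology,
    options: EnergyOptions | None = None,
    bonded_params: BondedParameters | None = None,
) -> StateEnergyResult:
    """Mean and sample std of the total energy over replicate ensembles."""
    if not replicates:
        raise ValueError("at least one replicate required")
    vals = [ensemble_total_energy(r, topology, options, bonded_params) for r in replicates]
    std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return StateEnergyResult(
        state_label=replicates[0].state_label,
        mean_energy=float(np.mean(vals)),
        std_over_replicates=std,
        n_snapshots=sum(r.n_frames for r in replicates),
    )


# ---------------------------------------------------------------------------
# per-atom and per-component decompositions
# ---------------------------------------------------------------------------


def _per_atom_energies(ensemble: TrajectoryEnsemble, topology: Topology,
                       options: EnergyOptions) -> np.ndarray:
    """Snapshot-mean E_atom (half row sums) for every atom."""
    acc = np.zeros(topology.n_atoms)
    all_rows = np.arange(topology.n_atoms)
    for f in ensemble.frames:
        acc += 0.5 * interaction_rows(all_rows, f, topology, options).sum(axis=1)
    return acc / ensemble.n_frames


def atom_energy_table(
    native: TrajectoryEnsemble,
    extended: TrajectoryEnsemble,
    topology: Topology,
    options: EnergyOptions | None = None,
) -> tuple[list[AtomEnergyResult], dict[str, float]]:
    """Per-protein-atom energies in both states plus all/polar/non-polar sums.

    The sums are over protein atoms of delta_E_atom; polar + non-polar equals
    the total by construction of the exhaustive polarity partition.
    """
    options = options or EnergyOptions()
    e_nat = _per_atom_energies(native, topology, options)
    e_ext = _per_atom_energies(extended, topology, options)
    results = []
    for i in topology.protein_indices:
        a = topology.atoms[i]
        results.append(
            AtomEnergyResult(
                atom_index=int(i),
                E_atom_native=float(e_nat[i]),
                E_atom_extended=float(e_ext[i]),
                delta_E_atom=float(e_nat[i] - e_ext[i]),
                partial_charge=a.partial_charge,
                is_polar=a.is_polar,
            )
        )
    delta = np.array([r.delta_E_atom for r in results])
    polar = np.array([r.is_polar for r in results])
    sums = {
        "all": float(delta.sum()),
        "polar": float(delta[polar].sum()),
        "nonpolar": float(delta[~polar].sum()),
    }
    return results, sums


_CLASS_LABEL = {"protein": "protein", "water": "water", "ion": "salt"}


def component_breakdown(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    options: EnergyOptions | None = None,
    bonded_params: BondedParameters | None = None,
) -> dict[tuple[str, str], float]:
    """Snapshot-mean energy binned by unordered molecule-class pair.

    Keys are ``(pair_label, term)`` such as ``("protein-water", "nonbonded")``;
    bonded terms are reported only for protein-protein.  The entries sum to
    the total system energy.
    """
    options = options or EnergyOptions()
    classes = sorted(set(topology.class_of), key=MOLECULE_ORDER.index)
    idx_of = {c: np.flatnonzero(topology.class_of == c) for c in classes}
    acc: dict[tuple[str, str], float] = {}
    bonded_acc = 0.0
    for f in ensemble.frames:
        rows = interaction_rows(np.arange(topology.n_atoms), f, topology, options)
        for ai, ca in enumerate(classes):
            for cb in classes[ai:]:
                block = rows[np.ix_(idx_of[ca], idx_of[cb])].sum()
                if ca == cb:
                    block *= 0.5
                key = (f"{_CLASS_LABEL[ca]}-{_CLASS_LABEL[cb]}", "nonbonded")
                acc[key] = acc.get(key, 0.0) + float(block)
        if bonded_params is not None:
            bonded_acc += bonded_energy(f, topology, bonded_params)
    nf = ensemble.n_frames
    out = {k: v / nf for k, v in acc.items()}
    if bonded_params is not None:
        out[("protein-protein", "bonded")] = bonded_acc / nf
    return out


MOLECULE_ORDER = ["protein", "water", "ion"]
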
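"""Geometric detection of protein-protein interactions and their bookkeeping.

Three interaction kinds are detected per snapshot:

* **hbond** -- donor and acceptor heavy atoms (O/N) within 3.2 Angstrom with a
  donor-H-acceptor angle of 130 degrees or more for some donor hydrogen;
* **nonpolar** -- two carbon/sulfur atoms not bonded to O or N within
  4.5 Angstrom, excluding same-residue and 1-2/1-3/1-4 pairs;
* **coophyd** -- a *cooperatively hydrated* pair: two donor/acceptor atoms
  3.2-6.0 Angstrom apart bridged by a single water oxygen within 4.0 Angstrom
  of both, with the water on the hydrogen side of each donor (donor-H-waterO
  angle >= 90 deg, vertex at the hydrogen) and on the lone-pair side of each
  acceptor (angle at the acceptor between its bonded heavy atom and the
  water oxygen >= 90 deg).

All cutoffs are boundary-inclusive.  Chemically indistinguishable atoms
(carboxylate oxygens, flipped ring carbons, methyl hydrogens, ...) are merged
into one contact: the contact exists in a frame if *any* symmetry-equivalent
alternative passes, and the atoms entering energy sums are resolved per frame
by the shortest defining heavy-atom distance.  For non-polar contacts every
alternative pair passing simultaneously adds to the frame count, so the
persistence of a ring-ring contact can exceed 1.

*Persistence* is the mean count per frame, averaged over replicate
ensembles; a contact is persistent when that mean exceeds the threshold
(default 0.5) strictly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .model_io import (
    Frame,
    Topology,
    TrajectoryEnsemble,
    minimum_image_displacement,
)
from .nonbonded import EnergyOptions, group_energy

__all__ = [
    "DetectionCriteria",
    "Slot",
    "ContactRecord",
    "ContactDetector",
    "detect_hbonds",
    "detect_nonpolar",
    "detect_coophyd",
    "resolve_symmetry",
    "persistence",
    "survey_contacts",
    "contact_census",
    "contact_energy",
]

CONTACT_KINDS = ("hbond", "nonpolar", "coophyd")


@dataclass
class DetectionCriteria:
    """Distance/angle cutoffs (Angstrom, degrees) and the persistence threshold."""

    hb_heavy_dist_max: float = 3.2
    hb_angle_min: float = 130.0
    np_dist_max: float = 4.5
    ch_polar_dist_min: float = 3.2
    ch_polar_dist_max: float = 6.0
    ch_water_dist_max: float = 4.0
    ch_donor_angle_min: float = 90.0
    ch_acceptor_angle_min: float = 90.0
    persistence_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hb_heavy_dist_max", "np_dist_max", "ch_polar_dist_min",
                     "ch_polar_dist_max", "ch_water_dist_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hb_angle_min", "ch_donor_angle_min", "ch_acceptor_angle_min"):
            ang = getattr(self, name)
            if not 0.0 < ang <= 180.0:
                raise ValueError(f"{name} must lie in (0, 180]")
        if self.ch_polar_dist_min >= self.ch_polar_dist_max:
            raise ValueError("cooperative-hydration distance range is empty")


@dataclass(frozen=True)
class Slot:
    """One side of a contact: a set of symmetry-equivalent atoms in a residue."""

    residue_name: str
    residue_number: int
    atom_names: tuple[str, ...]
    role: str  # 'donor' | 'acceptor' | 'polar' | 'nonpolar'

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.residue_number} " + "/".join(self.atom_names)


@dataclass
class ContactRecord:
    """A detected interaction, identified by its unordered pair of slots."""

    kind: str
    slots: tuple[Slot, Slot]
    persistence: float = math.nan
    persistence_std: float = math.nan
    E_native: float = math.nan
    E_native_std: float = math.nan
    E_extended: float = math.nan
    E_extended_std: float = math.nan
    delta_E: float = math.nan
    count: int = 1  # frame-local multiplicity when returned by a detector

    @property
    def key(self):
        return (self.kind, tuple(sorted(
            (s.residue_number, s.residue_name, s.atom_names, s.role) for s in self.slots
        )))

    @property
    def label(self) -> str:
        return " -- ".join(s.label for s in sorted(
            self.slots, key=lambda s: (s.residue_number, s.atom_names)))


def _angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Angle at ``vertex`` between directions vertex->a and vertex->b (degrees)."""
    v1 = minimum_image_displacement(a - vertex, box)
    v2 = minimum_image_displacement(b - vertex, box)
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


class ContactDetector:
    """Per-topology detection machinery shared by the three contact kinds."""

    def __init__(self, topology: Topology, criteria: DetectionCriteria | None = None):
        self.top = topology
        self.criteria = criteria or DetectionCriteria()
        adj = topology.adjacency
        atoms = topology.atoms
        protein = set(int(i) for i in topology.protein_indices)

        self.donor_hydrogens: dict[int, list[int]] = {}
        self.donors: list[int] = []
        self.acceptors: list[int] = []
        self.acceptor_heavies: dict[int, list[int]] = {}
        for i in sorted(protein):
            a = atoms[i]
            if a.is_donor:
                hs = [j for j in adj[i] if atoms[j].element == "H"]
                if not hs:
                    raise ValueError(f"donor atom {i} ({a.atom_name}) has no bonded hydrogen")
                self.donors.append(i)
                self.donor_hydrogens[i] = hs
            if a.is_acceptor:
                heavies = [j for j in adj[i] if atoms[j].element != "H"]
                self.acceptors.append(i)
                self.acceptor_heavies[i] = heavies
        self.polar_partners = sorted(set(self.donors) | set(self.acceptors))

        self.nonpolar_atoms = [
            i for i in sorted(protein)
            if atoms[i].element in ("C", "S")
            and not any(atoms[j].element in ("N", "O") for j in adj[i])
        ]
        self.water_oxygens = topology.water_oxygen_indices
        self.excluded = topology.excluded_pairs

    # -- helpers -----------------------------------------------------------

    def _slot(self, atom_index: int, role: str) -> Slot:
        a = self.top.atoms[atom_index]
        alts = self.top.symmetry_alternatives(atom_index)
        names = tuple(sorted(self.top.atoms[i].atom_name for i in alts))
        return Slot(a.residue_name, a.residue_number, names, role)

    def slot_atoms(self, slot: Slot) -> list[int]:
        """Concrete atom indices matching a slot's residue and name set."""
        return [
            a.atom_index for a in self.top.atoms
            if a.residue_number == slot.residue_number
            and a.residue_name == slot.residue_name
            and a.atom_name in slot.atom_names
        ]

    def _pair_excluded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.excluded

    def _dist(self, i: int, j: int, frame: Frame) -> float:
        d = minimum_image_displacement(
            frame.coordinates[j] - frame.coordinates[i], frame.box)
        return float(np.linalg.norm(d))

    # -- detectors -----------------------------------------------------------

    def detect_hbonds(self, frame: Frame) -> list[ContactRecord]:
        """Frame-local direct hydrogen bonds (one record per symmetry-merged pair)."""
        crit = self.criteria
        c = frame.coordinates
        box = frame.box
        found: dict[tuple, ContactRecord] = {}
        if not self.donors or not self.acceptors:
            return []
        dpos = c[self.donors]
        apos = c[self.acceptors]
        delta = minimum_image_displacement(dpos[:, None, :] - apos[None, :, :], box)
        dist = np.linalg.norm(delta, axis=-1)
        for di, ai in zip(*np.nonzero(dist <= crit.hb_heavy_dist_max)):
            d, acp = self.donors[di], self.acceptors[ai]
            if d == acp or self._pair_excluded(d, acp):
                continue
            ok = any(
                _angle_deg(c[h], c[d], c[acp], box) >= crit.hb_angle_min
                for h in self.donor_hydrogens[d]
            )
            if not ok:
                continue
            rec = ContactRecord(
                kind="hbond", slots=(self._slot(d, "donor"), self._slot(acp, "acceptor"))
            )
            found.setdefault(rec.key, rec)  # any passing alternative counts once
        return list(found.values())

    def detect_nonpolar(self, frame: Frame) -> list[ContactRecord]:
        """Frame-local non-polar contacts; count = simultaneous alternative pairs."""
        crit = self.criteria
        c = frame.coordinates
        box = frame.box
        idx = self.nonpolar_atoms
        if len(idx) < 2:
            return []
        pos = c[idx]
        delta = minimum_image_displacement(pos[:, None, :] - pos[None, :, :], box)
        dist = np.linalg.norm(delta, axis=-1)
        found: dict[tuple, ContactRecord] = {}
        atoms = self.top.atoms
        for ii, jj in zip(*np.nonzero(np.triu(dist <= crit.np_dist_max, k=1))):
            i, j = idx[ii], idx[jj]
            if (atoms[i].residue_number == atoms[j].residue_number
                    and atoms[i].residue_name == atoms[j].residue_name):
                continue
            if self._pair_excluded(i, j):
                continue
            rec = ContactRecord(
                kind="nonpolar",
                slots=(self._slot(i, "nonpolar"), self._slot(j, "nonpolar")),
            )
            if rec.key in found:
                found[rec.key].count += 1
            else:
                found[rec.key] = rec
        return list(found.values())

    def _bridging_water(self, i: int, j: int, frame: Frame) -> int | None:
        """Water oxygen within the cutoff of both partners, minimizing the
        sum of the two O-partner distances; None if no water qualifies."""
        if len(self.water_oxygens) == 0:
            return None
        c = frame.coordinates
        box = frame.box
        wpos = c[self.water_oxygens]
        di = np.linalg.norm(minimum_image_displacement(wpos - c[i], box), axis=-1)
        dj = np.linalg.norm(minimum_image_displacement(wpos - c[j], box), axis=-1)
        cut = self.criteria.ch_water_dist_max
        ok = (di <= cut) & (dj <= cut)
        if not np.any(ok):
            return None
        cand = np.flatnonzero(ok)
        best = cand[np.argmin(di[cand] + dj[cand])]
        return int(self.water_oxygens[best])

    def _partner_angle_ok(self, p: int, w: int, frame: Frame) -> bool:
        """Water-side angle criterion for one polar partner."""
        c = frame.coordinates
        box = frame.box
        crit = self.criteria
        atoms = self.top.atoms
        if atoms[p].is_donor:
            for h in self.donor_hydrogens.get(p, []):
                if _angle_deg(c[h], c[p], c[w], box) >= crit.ch_donor_angle_min:
                    return True
        if atoms[p].is_acceptor:
            for heavy in self.acceptor_heavies.get(p, []):
                if _angle_deg(c[p], c[heavy], c[w], box) >= crit.ch_acceptor_angle_min:
                    return True
        return False

    def detect_coophyd(self, frame: Frame) -> list[ContactRecord]:
        """Frame-local cooperatively hydrated pairs (single bridge per pair)."""
        crit = self.criteria
        c = frame.coordinates
        box = frame.box
        partners = self.polar_partners
        if len(partners) < 2 or len(self.water_oxygens) == 0:
            return []
        pos = c[partners]
        delta = minimum_image_displacement(pos[:, None, :] - pos[None, :, :], box)
        dist = np.linalg.norm(delta, axis=-1)
        in_range = (dist >= crit.ch_polar_dist_min) & (dist <= crit.ch_polar_dist_max)
        found: dict[tuple, ContactRecord] = {}
        atoms = self.top.atoms
        for ii, jj in zip(*np.nonzero(np.triu(in_range, k=1))):
            i, j = partners[ii], partners[jj]
            w = self._bridging_water(i, j, frame)
            if w is None:
                continue
            if not (self._partner_angle_ok(i, w, frame)
                    and self._partner_angle_ok(j, w, frame)):
                continue
            role_i = "donor" if atoms[i].is_donor else "acceptor"
            role_j = "donor" if atoms[j].is_donor else "acceptor"
            rec = ContactRecord(
                kind="coophyd", slots=(self._slot(i, role_i), self._slot(j, role_j))
            )
            found.setdefault(rec.key, rec)
        return list(found.values())

    def detect(self, frame: Frame, kind: str) -> list[ContactRecord]:
        return {
            "hbond": self.detect_hbonds,
            "nonpolar": self.detect_nonpolar,
            "coophyd": self.detect_coophyd,
        }[kind](frame)

    # -- symmetry resolution and energy atom sets ----------------------------

    def resolve_symmetry(self, record: ContactRecord, frame: Frame) -> tuple[int, int]:
        """Concrete atom pair minimizing the defining heavy-atom distance."""
        cands_a = self.slot_atoms(record.slots[0])
        cands_b = self.slot_atoms(record.slots[1])
        if not cands_a or not cands_b:
            raise ValueError(f"contact {record.label}: slot atoms absent from topology")
        best = None
        best_d = math.inf
        for i in cands_a:
            for j in cands_b:
                if i == j:
                    continue
                d = self._dist(i, j, frame)
                if d < best_d:
                    best_d = d
                    best = (i, j)
        assert best is not None
        return best

    def _closest(self, candidates: Sequence[int], ref: int, frame: Frame) -> int:
        return min(candidates, key=lambda k: self._dist(k, ref, frame))

    def energy_atoms(self, record: ContactRecord, frame: Frame) -> list[int]:
        """Atom set entering the interaction-energy sum, resolved for one frame.

        hbond: donor, its hydrogen, acceptor, and the acceptor's bonded atoms.
        nonpolar: both heavy atoms plus their bonded hydrogens.
        coophyd: per partner, donor + donor hydrogen or acceptor + bonded
        heavy atom; the bridging water belongs to the environment in both
        states and is excluded.
        """
        i, j = self.resolve_symmetry(record, frame)
        adj = self.top.adjacency
        atoms = self.top.atoms
        if record.kind == "nonpolar":
            members = {i, j}
            for heavy in (i, j):
                members.update(h for h in adj[heavy] if atoms[h].element == "H")
            return sorted(members)
        members: set[int] = set()
        resolved = dict(zip(record.slots, (i, j)))
        for slot, p in resolved.items():
            other = j if p == i else i
            if record.kind == "hbond":
                if slot.role == "donor":
                    hs = self.donor_hydrogens[p]
                    h = max(hs, key=lambda h: _angle_deg(
                        frame.coordinates[h], frame.coordinates[p],
                        frame.coordinates[other], frame.box))
                    members.update((p, h))
                else:
                    members.add(p)
                    members.update(adj[p])
            else:  # coophyd
                if slot.role == "donor":
                    members.update((p, self._closest(self.donor_hydrogens[p], other, frame)))
                else:
                    heavies = self.acceptor_heavies[p] or list(adj[p])
                    members.update((p, self._closest(heavies, other, frame)))
        return sorted(members)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def detect_hbonds(frame: Frame, topology: Topology,
                  criteria: DetectionCriteria | None = None) -> list[ContactRecord]:
    return ContactDetector(topology, criteria).detect_hbonds(frame)


def detect_nonpolar(frame: Frame, topology: Topology,
                    criteria: DetectionCriteria | None = None) -> list[ContactRecord]:
    return ContactDetector(topology, criteria).detect_nonpolar(frame)


def detect_coophyd(frame: Frame, topology: Topology,
                   criteria: DetectionCriteria | None = None) -> list[ContactRecord]:
    return ContactDetector(topology, criteria).detect_coophyd(frame)


def resolve_symmetry(record: ContactRecord, frame: Frame, topology: Topology,
                     criteria: DetectionCriteria | None = None) -> tuple[int, int]:
    return ContactDetector(topology, criteria).resolve_symmetry(record, frame)


def _per_replicate_counts(
    key,
    kind: str,
    ensembles: Sequence[TrajectoryEnsemble],
    detector: ContactDetector,
) -> np.ndarray:
    out = []
    for ens in ensembles:
        total = 0.0
        for frame in ens.frames:
            for rec in detector.detect(frame, kind):
                if rec.key == key:
                    total += rec.count
        out.append(total / ens.n_frames)
    return np.asarray(out)


def persistence(
    record: ContactRecord,
    ensembles: Sequence[TrajectoryEnsemble],
    topology: Topology,
    criteria: DetectionCriteria | None = None,
) -> tuple[float, float]:
    """Mean count per frame over replicates, and the std over replicates."""
    if not ensembles or any(e.n_frames == 0 for e in ensembles):
        raise ValueError("persistence requires at least one replicate with frames")
    det = ContactDetector(topology, criteria)
    vals = _per_replicate_counts(record.key, record.kind, ensembles, det)
    std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), std


def survey_contacts(
    ensembles: Sequence[TrajectoryEnsemble],
    topology: Topology,
    criteria: DetectionCriteria | None = None,
    kinds: Sequence[str] = CONTACT_KINDS,
) -> dict[tuple, ContactRecord]:
    """Detect all contacts across replicate ensembles and fill persistence.

    Returns records keyed by contact identity; a record's persistence is the
    mean per-frame count averaged over replicates (std over replicates).
    """
    if not ensembles:
        raise ValueError("survey_contacts requires at least one ensemble")
    criteria = criteria or DetectionCriteria()
    det = ContactDetector(topology, criteria)
    counts: dict[tuple, np.ndarray] = {}
    templates: dict[tuple, ContactRecord] = {}
    n_rep = len(ensembles)
    for r, ens in enumerate(ensembles):
        for frame in ens.frames:
            for kind in kinds:
                for rec in det.detect(frame, kind):
                    if rec.key not in counts:
                        counts[rec.key] = np.zeros(n_rep)
                        templates[rec.key] = rec
                    counts[rec.key][r] += rec.count
    out: dict[tuple, ContactRecord] = {}
    for key, per_rep in counts.items():
        frames = np.asarray([e.n_frames for e in ensembles], dtype=float)
        per_frame = per_rep / frames
        rec = templates[key]
        rec = replace(
            rec,
            persistence=float(np.mean(per_frame)),
            persistence_std=float(np.std(per_frame, ddof=1)) if n_rep > 1 else 0.0,
            count=1,
        )
        out[key] = rec
    return out


def contact_census(
    ensembles: Sequence[TrajectoryEnsemble],
    topology: Topology,
    criteria: DetectionCriteria | None = None,
) -> dict[str, tuple[int, int]]:
    """Per kind: (contacts seen in >= 1 frame, contacts above the persistence threshold)."""
    criteria = criteria or DetectionCriteria()
    records = survey_contacts(ensembles, topology, criteria)
    out = {}
    for kind in CONTACT_KINDS:
        recs = [r for r in records.values() if r.kind == kind]
        persistent = [r for r in recs if r.persistence > criteria.persistence_threshold]
        out[kind] = (len(recs), len(persistent))
    return out


def contact_energy(
    record: ContactRecord,
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    options: EnergyOptions | None = None,
    criteria: DetectionCriteria | None = None,
) -> float:
    """Snapshot-mean group energy of the contact's (frame-resolved) atom set."""
    det = ContactDetector(topology, criteria)
    options = options or EnergyOptions()
    vals = [
        group_energy(det.energy_atoms(record, frame), frame, topology, options)
        for frame in ensemble.frames
    ]
    return float(np.mean(vals))
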
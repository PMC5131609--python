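"""Domain types and file I/O for topologies, frames, and snapshot ensembles.

The canonical topology input is a plain-text tab-separated table with one row
per atom and the columns::

    index  name  residue  resid  class  element  charge  epsilon  rmin_half  acceptor  bonds

where ``class`` is one of ``protein``/``water``/``ion``, ``charge`` is the
partial charge in units of the elementary charge, ``epsilon`` (kcal/mol) and
``rmin_half`` (Angstrom) are the Lennard-Jones well depth and half-minimum
distance, ``acceptor`` is ``1`` for oxygen/nitrogen atoms with an available
lone pair (lone-pair availability cannot be inferred from connectivity alone,
so it is declared in the input), and ``bonds`` is a comma-separated list of
0-based indices of covalently bonded partners (``-`` for none).

Polarity and donor status are derived, never declared:

* an atom is *polar* iff ``|charge| >= 0.3`` (the CHARMM charge partition
  places carbonyl/amide/hydroxyl/charged-group atoms on the polar side and
  aliphatic/aromatic carbons, sulfur, and their hydrogens plus the proline
  backbone nitrogen on the non-polar side);
* an atom is a *donor* iff it is oxygen or nitrogen with at least one bonded
  hydrogen.

Trajectory frames are carried as plain coordinate arrays with an orthorhombic
box.  Supported on-disk formats: multi-frame XYZ (box lengths stored on the
comment line), multi-model PDB (via biotite), and DCD (via mdtraj's raw DCD
layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TopologyError",
    "TrajectoryError",
    "AtomRecord",
    "Topology",
    "Frame",
    "TrajectoryEnsemble",
    "WaterGeometry",
    "TIP3P_GEOMETRY",
    "TIP4P2005_GEOMETRY",
    "POLARITY_CHARGE_THRESHOLD",
    "read_topology",
    "write_topology",
    "read_frames",
    "write_frames",
    "assign_symmetry_groups",
    "derive_exclusions",
]

#: |partial charge| at or above which an atom counts as polar (e units).
POLARITY_CHARGE_THRESHOLD = 0.3

MOLECULE_CLASSES = ("protein", "water", "ion")
STATE_LABELS = ("native", "extended", "intermediate1", "intermediate2", "intermediate3")
ENSEMBLE_KINDS = ("restrained_NPT", "fixed_NVT")


class TopologyError(ValueError):
    """Raised for malformed, inconsistent, or incomplete topology input."""


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent coordinate/trajectory input."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with force-field parameters and interaction flags."""

    atom_index: int
    atom_name: str
    residue_name: str
    residue_number: int
    molecule_class: str
    element: str
    partial_charge: float
    lj_epsilon: float
    lj_rmin_half: float
    is_polar: bool = False
    is_donor: bool = False
    is_acceptor: bool = False
    symmetry_group: str | None = None

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise TopologyError(
                f"atom {self.atom_index} ({self.atom_name}): unknown molecule class "
                f"{self.molecule_class!r}"
            )
        if self.lj_epsilon < 0:
            raise TopologyError(
                f"atom {self.atom_index} ({self.atom_name}): negative LJ epsilon"
            )


@dataclass
class WaterGeometry:
    """Rigid water geometry (bond lengths in Angstrom, angles in degrees)."""

    r_OH: float = 0.9572
    theta_HOH: float = 104.52
    r_OL: float = 0.1546
    theta_HOL: float = 52.26
    model_name: str = "TIP3P"

    @property
    def n_sites(self) -> int:
        return 4 if self.model_name.upper().startswith("TIP4P") else 3


TIP3P_GEOMETRY = WaterGeometry(model_name="TIP3P")
TIP4P2005_GEOMETRY = WaterGeometry(model_name="TIP4P-2005")


def derive_exclusions(n_atoms: int, bonds: Sequence[tuple[int, int]]):
    """1-2, 1-3, and 1-4 pair sets from the covalent bond graph.

    Returns (excl_12, excl_13, excl_14) as sets of sorted index tuples; the
    three sets are disjoint (a pair is classified by its shortest bond path).
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise TopologyError(f"bond ({i}, {j}) references a nonexistent atom index")
        if i == j:
            raise TopologyError(f"bond ({i}, {j}) is a self-pair")
        adj[i].add(j)
        adj[j].add(i)

    excl_12: set[tuple[int, int]] = set()
    excl_13: set[tuple[int, int]] = set()
    excl_14: set[tuple[int, int]] = set()
    for a in range(n_atoms):
        one = adj[a]
        two: set[int] = set()
        for b in one:
            two |= adj[b]
        two -= one | {a}
        three: set[int] = set()
        for c in two:
            three |= adj[c]
        three -= one | two | {a}
        for b in one:
            excl_12.add((min(a, b), max(a, b)))
        for c in two:
            excl_13.add((min(a, c), max(a, c)))
        for d in three:
            excl_14.add((min(a, d), max(a, d)))
    # shortest-path classification: 1-2 wins over 1-3 wins over 1-4
    excl_13 -= excl_12
    excl_14 -= excl_12 | excl_13
    return excl_12, excl_13, excl_14


@dataclass
class Topology:
    """Ordered atom collection with bonds, derived exclusions, and symmetry groups.

    ``symmetry_groups`` maps a group identifier (e.g. ``"ASP44:OD"``) to the
    tuple of atom indices that are exchangeable by an internal rotation or
    ring flip.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    symmetry_groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._cache: dict[str, object] = {}
        n = len(self.atoms)
        self.bonds = [(min(i, j), max(i, j)) for i, j in self.bonds]
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i}, {j}) references a nonexistent atom index")
        self._derive_flags()
        self._validate_waters()
        seen: dict[int, str] = {}
        for gid, members in self.symmetry_groups.items():
            for m in members:
                if m in seen:
                    raise TopologyError(
                        f"atom {m} belongs to two symmetry groups ({seen[m]}, {gid})"
                    )
                seen[m] = gid

    # -- derived structure -------------------------------------------------

    def _derive_flags(self) -> None:
        adj = self.adjacency
        new_atoms = []
        for a in self.atoms:
            has_h = any(self.atoms[b].element == "H" for b in adj[a.atom_index])
            is_donor = a.element in ("N", "O") and has_h
            if a.is_acceptor and a.element not in ("N", "O"):
                raise TopologyError(
                    f"atom {a.atom_index} ({a.atom_name}): acceptor flag on element "
                    f"{a.element!r} (acceptors must be N or O)"
                )
            new_atoms.append(
                replace(
                    a,
                    is_polar=abs(a.partial_charge) >= POLARITY_CHARGE_THRESHOLD,
                    is_donor=is_donor,
                )
            )
        self.atoms = new_atoms

    def _validate_waters(self) -> None:
        for o_idx, h_idxs, _virt in self.water_molecules:
            if len(h_idxs) != 2:
                raise TopologyError(
                    f"water oxygen {o_idx} has {len(h_idxs)} bonded hydrogens (need 2)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def adjacency(self) -> list[set[int]]:
        if "adjacency" not in self._cache:
            adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
            for i, j in self.bonds:
                adj[i].add(j)
                adj[j].add(i)
            self._cache["adjacency"] = adj
        return self._cache["adjacency"]  # type: ignore[return-value]

    @property
    def exclusions(self) -> tuple[set[tuple[int, int]], ...]:
        if "exclusions" not in self._cache:
            self._cache["exclusions"] = derive_exclusions(self.n_atoms, self.bonds)
        return self._cache["exclusions"]  # type: ignore[return-value]

    @property
    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Union of 1-2, 1-3, and 1-4 pairs (sorted index tuples)."""
        e12, e13, e14 = self.exclusions
        return e12 | e13 | e14

    def exclusion_mask(self) -> np.ndarray:
        """(n, n) boolean matrix: True for self-pairs and 1-2/1-3/1-4 pairs."""
        if "exclusion_mask" not in self._cache:
            n = self.n_atoms
            mask = np.zeros((n, n), dtype=bool)
            np.fill_diagonal(mask, True)
            for i, j in self.excluded_pairs:
                mask[i, j] = mask[j, i] = True
            self._cache["exclusion_mask"] = mask
        return self._cache["exclusion_mask"]  # type: ignore[return-value]

    def _array(self, key: str, getter) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.asarray([getter(a) for a in self.atoms])
        return self._cache[key]  # type: ignore[return-value]

    @property
    def charges(self) -> np.ndarray:
        return self._array("charges", lambda a: a.partial_charge)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self._array("lj_epsilons", lambda a: a.lj_epsilon)

    @property
    def lj_rmin_halves(self) -> np.ndarray:
        return self._array("lj_rmin_halves", lambda a: a.lj_rmin_half)

    @property
    def polar_mask(self) -> np.ndarray:
        return self._array("polar_mask", lambda a: a.is_polar)

    @property
    def class_of(self) -> np.ndarray:
        return self._array("class_of", lambda a: a.molecule_class)

    @property
    def elements(self) -> np.ndarray:
        return self._array("elements", lambda a: a.element)

    @property
    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(self.class_of == "protein")

    @property
    def water_molecules(self) -> list[tuple[int, list[int], list[int]]]:
        """Per water molecule: (oxygen index, hydrogen indices, virtual-site indices)."""
        if "water_molecules" not in self._cache:
            out = []
            adj = self.adjacency
            for a in self.atoms:
                if a.molecule_class == "water" and a.element == "O":
                    hs = sorted(b for b in adj[a.atom_index] if self.atoms[b].element == "H")
                    vs = sorted(
                        b for b in adj[a.atom_index] if self.atoms[b].element not in ("H", "O")
                    )
                    out.append((a.atom_index, hs, vs))
            self._cache["water_molecules"] = out
        return self._cache["water_molecules"]  # type: ignore[return-value]

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        return np.asarray([o for o, _, _ in self.water_molecules], dtype=int)

    def symmetry_alternatives(self, atom_index: int) -> tuple[int, ...]:
        """Indices exchangeable with ``atom_index`` (itself if ungrouped)."""
        a = self.atoms[atom_index]
        if a.symmetry_group is None:
            return (atom_index,)
        return self.symmetry_groups[a.symmetry_group]

    def inventory(self) -> dict[tuple[str, str], int]:
        """Particle counts keyed by (molecule class, element)."""
        counts: dict[tuple[str, str], int] = {}
        for a in self.atoms:
            key = (a.molecule_class, a.element)
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class Frame:
    """One snapshot: coordinates (Angstrom) and an orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TrajectoryError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class TrajectoryEnsemble:
    """An ordered frame sequence labeled by state, replicate, and ensemble kind."""

    state_label: str
    replicate_id: int
    ensemble_kind: str
    frames: list[Frame]
    sampling_interval: float = 100.0  # ps between saved snapshots
    topology: Topology | None = None

    def __post_init__(self) -> None:
        if self.state_label not in STATE_LABELS:
            raise TrajectoryError(f"unknown state label {self.state_label!r}")
        if self.ensemble_kind not in ENSEMBLE_KINDS:
            raise TrajectoryError(f"unknown ensemble kind {self.ensemble_kind!r}")
        if not self.frames:
            raise TrajectoryError("ensemble has no frames")
        n = self.frames[0].n_atoms
        if any(f.n_atoms != n for f in self.frames):
            raise TrajectoryError("frames differ in atom count")
        if self.topology is not None and self.topology.n_atoms != n:
            raise TrajectoryError(
                f"frame atom count {n} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# topology I/O
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = (
    "index name residue resid class element charge epsilon rmin_half acceptor bonds"
).split()


def read_topology(path: str | Path, format: str = "tabular", *,
                  lj_by_type: Mapping[str, tuple[float, float]] | None = None) -> Topology:
    """Read a topology from disk.

    ``format='tabular'`` reads the canonical TSV documented in the module
    docstring.  ``format='psf-like'`` reads the ``!NATOM`` / ``!NBOND``
    sections of a text PSF; because PSF files carry no Lennard-Jones
    parameters, a ``lj_by_type`` map (atom type -> (epsilon, rmin/2)) must be
    supplied, and every atom's type must be present in it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular_topology(path)
    if format == "psf-like":
        return _read_psf_topology(path, lj_by_type or {})
    raise ValueError(f"unknown topology format {format!r}")


def _read_tabular_topology(path: Path) -> Topology:
    atoms: list[AtomRecord] = []
    bonds: set[tuple[int, int]] = set()
    acceptor_flags: list[bool] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if header is None:
                if fields != _TOPOLOGY_COLUMNS:
                    raise TopologyError(
                        f"{path}:{lineno}: bad header; expected columns "
                        f"{' '.join(_TOPOLOGY_COLUMNS)}"
                    )
                header = fields
                continue
            if len(fields) != len(_TOPOLOGY_COLUMNS):
                raise TopologyError(
                    f"{path}:{lineno}: expected {len(_TOPOLOGY_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            rec = dict(zip(_TOPOLOGY_COLUMNS, fields))
            try:
                idx = int(rec["index"])
                charge = float(rec["charge"])
                eps = float(rec["epsilon"])
                rmin_half = float(rec["rmin_half"])
            except ValueError as exc:
                raise TopologyError(f"{path}:{lineno}: {exc}") from exc
            if idx != len(atoms):
                raise TopologyError(
                    f"{path}:{lineno}: atom index {idx} out of order "
                    f"(expected {len(atoms)})"
                )
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=rec["name"],
                    residue_name=rec["residue"],
                    residue_number=int(rec["resid"]),
                    molecule_class=rec["class"],
                    element=rec["element"],
                    partial_charge=charge,
                    lj_epsilon=eps,
                    lj_rmin_half=rmin_half,
                    is_acceptor=rec["acceptor"] not in ("0", "-", ""),
                )
            )
            if rec["bonds"] not in ("-", ""):
                for tok in rec["bonds"].split(","):
                    j = int(tok)
                    if j == idx:
                        raise TopologyError(f"{path}:{lineno}: atom bonded to itself")
                    bonds.add((min(idx, j), max(idx, j)))
    if not atoms:
        raise TopologyError(f"{path}: no atom records found")
    return Topology(atoms=atoms, bonds=sorted(bonds))


def _read_psf_topology(path: Path, lj_by_type: Mapping[str, tuple[float, float]]) -> Topology:
    lines = path.read_text().splitlines()
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i]
        if "!NATOM" in line:
            n_atoms = int(line.split()[0])
            for k in range(n_atoms):
                i += 1
                parts = lines[i].split()
                if len(parts) < 8:
                    raise TopologyError(f"{path}:{i + 1}: malformed PSF atom line")
                _, _segid, resid, resname, name, atype, charge, _mass = parts[:8]
                if atype not in lj_by_type:
                    raise TopologyError(
                        f"{path}: no LJ parameters supplied for atom "
                        f"{name} (type {atype}) in residue {resname}{resid}"
                    )
                eps, rmin_half = lj_by_type[atype]
                element = name[0] if name[0].isalpha() else name[1]
                mol_class = "water" if resname in ("TIP3", "TIP4", "HOH", "WAT", "SPC") else (
                    "ion" if resname in ("SOD", "CLA", "POT", "NA", "CL", "K") else "protein"
                )
                atoms.append(
                    AtomRecord(
                        atom_index=k,
                        atom_name=name,
                        residue_name=resname,
                        residue_number=int(resid),
                        molecule_class=mol_class,
                        element=element,
                        partial_charge=float(charge),
                        lj_epsilon=eps,
                        lj_rmin_half=rmin_half,
                    )
                )
        elif "!NBOND" in line:
            n_bonds = int(line.split()[0])
            vals: list[int] = []
            while len(vals) < 2 * n_bonds:
                i += 1
                vals.extend(int(v) for v in lines[i].split())
            bonds = [(vals[2 * k] - 1, vals[2 * k + 1] - 1) for k in range(n_bonds)]
        i += 1
    if not atoms:
        raise TopologyError(f"{path}: no !NATOM section found")
    return Topology(atoms=atoms, bonds=bonds)


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write the canonical tabular topology format."""
    partners: list[list[int]] = [[] for _ in range(topology.n_atoms)]
    for i, j in topology.bonds:
        partners[i].append(j)
        partners[j].append(i)
    with open(path, "w") as fh:
        fh.write("\t".join(_TOPOLOGY_COLUMNS) + "\n")
        for a in topology.atoms:
            blist = ",".join(str(j) for j in sorted(partners[a.atom_index])) or "-"
            fh.write(
                "\t".join(
                    [
                        str(a.atom_index),
                        a.atom_name,
                        a.residue_name,
                        str(a.residue_number),
                        a.molecule_class,
                        a.element,
                        f"{a.partial_charge:.6f}",
                        f"{a.lj_epsilon:.6f}",
                        f"{a.lj_rmin_half:.6f}",
                        "1" if a.is_acceptor else "0",
                        blist,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# frame I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".xyz": "xyz", ".dcd": "dcd", ".pdb": "pdb-multi"}.get(suffix, suffix.lstrip("."))


def read_frames(
    path: str | Path,
    format: str | None = None,
    *,
    topology: Topology | None = None,
    box: Sequence[float] | None = None,
    state_label: str = "native",
    replicate_id: int = 0,
    ensemble_kind: str = "restrained_NPT",
    sampling_interval: float = 100.0,
) -> TrajectoryEnsemble:
    """Read a snapshot ensemble from XYZ, multi-model PDB, or DCD.

    ``box`` supplies the orthorhombic box for formats/files that do not carry
    one per frame; per-frame boxes from the file take precedence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "xyz":
        frames = _read_xyz(path, box)
    elif fmt == "dcd":
        frames = _read_dcd(path, box)
    elif fmt == "pdb-multi":
        frames = _read_pdb(path, box)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if topology is not None and frames and frames[0].n_atoms != topology.n_atoms:
        raise TrajectoryError(
            f"{path}: frame atom count {frames[0].n_atoms} does not match "
            f"topology ({topology.n_atoms} atoms)"
        )
    return TrajectoryEnsemble(
        state_label=state_label,
        replicate_id=replicate_id,
        ensemble_kind=ensemble_kind,
        frames=frames,
        sampling_interval=sampling_interval,
        topology=topology,
    )


def _read_xyz(path: Path, box: Sequence[float] | None) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryError(f"{path}: bad atom-count line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        frame_box = _parse_xyz_box(comment)
        if frame_box is None:
            if box is None:
                raise TrajectoryError(
                    f"{path}: no box on XYZ comment line and none supplied"
                )
            frame_box = np.asarray(box, dtype=float)
        if i + 2 + n > len(lines):
            raise TrajectoryError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryError(f"{path}: malformed atom line {i + 3 + k}")
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coordinates=coords, box=frame_box))
        i += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return frames


def _parse_xyz_box(comment: str) -> np.ndarray | None:
    toks = comment.split()
    if len(toks) >= 4 and toks[0].lower() == "box":
        return np.asarray([float(t) for t in toks[1:4]])
    return None


def _read_dcd(path: Path, box: Sequence[float] | None) -> list[Frame]:
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path)) as fh:
        xyz, cell_lengths, cell_angles = fh.read()
    frames = []
    for k in range(xyz.shape[0]):
        if cell_lengths is not None and np.all(cell_lengths[k] > 0):
            if cell_angles is not None and not np.allclose(cell_angles[k], 90.0, atol=1e-3):
                raise TrajectoryError(f"{path}: non-orthorhombic box in frame {k}")
            frame_box = np.asarray(cell_lengths[k], dtype=float)
        elif box is not None:
            frame_box = np.asarray(box, dtype=float)
        else:
            raise TrajectoryError(f"{path}: DCD frame {k} has no box and none supplied")
        frames.append(Frame(coordinates=np.asarray(xyz[k], dtype=float), box=frame_box))
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return frames


def _read_pdb(path: Path, box: Sequence[float] | None) -> list[Frame]:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack (model, atom)
    frame_box = None
    if stack.box is not None:
        b = np.asarray(stack.box)
        if b.ndim == 3:
            b = b[0]
        lengths = np.linalg.norm(b, axis=1)
        off_diag = b - np.diag(np.diag(b))
        if np.any(np.abs(off_diag) > 1e-6 * max(1.0, lengths.max())):
            raise TrajectoryError(f"{path}: non-orthorhombic box")
        frame_box = lengths
    if frame_box is None:
        if box is None:
            raise TrajectoryError(f"{path}: no CRYST1 box and none supplied")
        frame_box = np.asarray(box, dtype=float)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return [Frame(coordinates=c, box=frame_box) for c in coords]


def write_frames(ensemble: TrajectoryEnsemble, path: str | Path,
                 format: str | None = None, *,
                 elements: Sequence[str] | None = None) -> None:
    """Write an ensemble to XYZ (box on the comment line) or DCD."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if elements is None:
        if ensemble.topology is not None:
            elements = [a.element for a in ensemble.topology.atoms]
        else:
            elements = ["X"] * ensemble.n_atoms
    if fmt == "xyz":
        with open(path, "w") as fh:
            for frame in ensemble.frames:
                fh.write(f"{frame.n_atoms}\n")
                fh.write("box {:.6f} {:.6f} {:.6f}\n".format(*frame.box))
                for el, (x, y, z) in zip(elements, frame.coordinates):
                    fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            for frame in ensemble.frames:
                fh.write(
                    frame.coordinates[None].astype(np.float32),
                    cell_lengths=frame.box[None].astype(np.float32),
                    cell_angles=np.full((1, 3), 90.0, dtype=np.float32),
                )
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# symmetry-group templates
# ---------------------------------------------------------------------------

#: Exchangeable atom-name sets by residue name (CHARMM naming).  Atoms related
#: by a carboxylate/guanidinium torsion, an aromatic ring flip, a methyl
#: rotation, or branched-methyl exchange are chemically indistinguishable.
SYMMETRY_TEMPLATES: dict[str, tuple[tuple[str, ...], ...]] = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "ARG": (("NH1", "NH2"), ("HH11", "HH12", "HH21", "HH22")),
    "LYS": (("HZ1", "HZ2", "HZ3"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
    "LEU": (("CD1", "CD2"),),
    "VAL": (("CG1", "CG2"),),
}

#: Applied to any residue exposing both names (C-terminal carboxylate).
_CTERM_TEMPLATE = ("OT1", "OT2")
#: Water hydrogens are exchangeable in any water model.
_WATER_TEMPLATES = (("H1", "H2"), ("HW1", "HW2"))


def assign_symmetry_groups(topology: Topology) -> Topology:
    """Attach built-in symmetry-group templates; atoms without a template keep none.

    Returns a new Topology; group identifiers are ``"<RES><resid>:<first name>"``.
    """
    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    for a in topology.atoms:
        by_residue.setdefault((a.residue_name, a.residue_number), {})[a.atom_name] = a.atom_index

    groups: dict[str, tuple[int, ...]] = {}
    group_of: dict[int, str] = {}

    def register(resname: str, resid: int, names: tuple[str, ...], name_map: dict[str, int]):
        members = tuple(name_map[n] for n in names if n in name_map)
        if len(members) < 2:
            return
        gid = f"{resname}{resid}:{names[0]}"
        groups[gid] = members
        for m in members:
            group_of[m] = gid

    for (resname, resid), name_map in by_residue.items():
        for names in SYMMETRY_TEMPLATES.get(resname, ()):
            register(resname, resid, names, name_map)
        register(resname, resid, _CTERM_TEMPLATE, name_map)
        if topology.atoms[next(iter(name_map.values()))].molecule_class == "water":
            for names in _WATER_TEMPLATES:
                register(resname, resid, names, name_map)

    atoms = [replace(a, symmetry_group=group_of.get(a.atom_index)) for a in topology.atoms]
    return Topology(atoms=atoms, bonds=list(topology.bonds), symmetry_groups=groups)


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the central cell (orthorhombic box)."""
    return delta - box * np.round(delta / box)


def minimum_image_distance(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image Euclidean distance between two points."""
    d = minimum_image_displacement(np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float),
                                   np.asarray(box, dtype=float))
    return float(np.linalg.norm(d))
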
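"""Hydration-site thermodynamics via inhomogeneous fluid solvation theory.

A *hydration site* is a high-occupancy locus of water density near the solute,
found by clustering water-oxygen positions over fixed-solute snapshots.  Each
site contributes

    dG_site = dE_site - T * dS_site ,

with the energetic part referenced to neat water,

    dE_site = E_site - n * E_bulk ,

where ``E_site`` is the mean interaction energy of the site water with its
whole environment (full pair weight, matching the bulk reference convention)
and ``n`` is the mean number of waters in the site per frame.  The entropic
part uses the two-particle approximation ``dS = S_sw + S_ww - n S_bulk`` with
the water-water term assigned zero (the solute-water term captures most
first-shell correlation), and ``S_sw`` estimated nonparametrically from
nearest-neighbor distances in the combined translational + orientational
space of the site water:

    S_sw = n R [ <ln( pi d_nn^6 n F / (48 V_i) )> + gamma ] ,

where ``d_nn^2 = d_trans^2 + d_orient^2``, ``d_trans`` is the minimum-image
Euclidean distance (Angstrom), ``d_orient = 2 acos(|q1 . q2|)`` is the
rotation-group geodesic metric (radians, quaternion double cover handled by
the absolute value), ``F`` is the frame count, ``V_i`` the frame volume, and
``gamma`` Euler's constant correcting the asymptotic bias of the first
neighbor (k = 1).  The normalization constant 48 = 8 pi^2 * 6 / pi^3 embeds
the full rotation-group volume 8 pi^2, so a water distributed uniformly over
the box and over orientations (both hydrogen images counted as distinct
orientations) has S_sw = 0; accordingly, hydrogen-exchange symmetry reduction
of the orientational metric is off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .model_io import Frame, Topology, TrajectoryEnsemble, minimum_image_displacement
from .nonbonded import EnergyOptions, interaction_rows

__all__ = [
    "GAS_CONSTANT_R",
    "EULER_GAMMA",
    "BulkReference",
    "BULK_WATER_TABLE",
    "bulk_reference",
    "EstimatorConfig",
    "WaterObservation",
    "HydrationSite",
    "orientational_distance",
    "translational_distance",
    "water_orientation_quaternion",
    "extract_water_observations",
    "nearest_neighbor_distances",
    "ssw_knn",
    "cluster_hydration_sites",
    "site_energy",
    "site_free_energy",
    "analyze_hydration_sites",
]

#: kcal/mol/K
GAS_CONSTANT_R = 0.0019872
EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class BulkReference:
    """Per-molecule thermodynamics of neat water for one model/salt treatment.

    Units kcal/mol; ``minus_T_S_bulk`` is -T*S_bulk at the simulation
    temperature.  The triple satisfies G = E + (-T S) up to the 1-decimal
    rounding of each member (0.15 kcal/mol worst case).
    """

    water_model: str
    nacl_mM: float
    E_bulk: float
    G_bulk: float
    minus_T_S_bulk: float

    def __post_init__(self) -> None:
        if abs(self.G_bulk - (self.E_bulk + self.minus_T_S_bulk)) > 0.15 + 1e-9:
            raise ValueError(
                f"inconsistent bulk reference for {self.water_model}/{self.nacl_mM} mM: "
                f"G != E - T*S beyond rounding"
            )


#: Bulk references for the villin study treatments (TIP3P at five NaCl
#: concentrations and TIP4P-2005 in pure water), at 300 K.
BULK_WATER_TABLE: tuple[BulkReference, ...] = (
    BulkReference("TIP3P", 0, -9.8, -6.3, 3.5),
    BulkReference("TIP3P", 50, -10.2, -6.5, 3.8),
    BulkReference("TIP3P", 100, -10.6, -6.5, 4.1),
    BulkReference("TIP3P", 150, -11.1, -6.3, 4.7),
    BulkReference("TIP3P", 200, -11.4, -6.5, 5.0),
    BulkReference("TIP4P-2005", 0, -11.6, -7.0, 4.6),
)


def bulk_reference(water_model: str, nacl_mM: float = 0.0) -> BulkReference:
    """Look up the built-in bulk reference for a water model / salt pairing."""
    for ref in BULK_WATER_TABLE:
        if ref.water_model.upper() == water_model.upper() and ref.nacl_mM == nacl_mM:
            return ref
    raise KeyError(f"no bulk reference for {water_model!r} at {nacl_mM} mM NaCl")


@dataclass
class EstimatorConfig:
    """Settings for the nearest-neighbor entropy estimator."""

    k: int = 1
    gas_constant_R: float = GAS_CONSTANT_R
    temperature_T: float = 300.0
    euler_gamma: float = EULER_GAMMA
    water_symmetry_in_orientation: bool = False
    exclude_same_frame_neighbors: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.temperature_T <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class WaterObservation:
    """One water in one frame: oxygen position, orientation, frame volume."""

    frame_index: int
    position: np.ndarray
    orientation: np.ndarray  # unit quaternion, scalar-first
    frame_volume: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be unit norm")


@dataclass
class HydrationSite:
    """A clustered water locus and its IFST thermodynamics (kcal/mol)."""

    center: np.ndarray
    site_radius: float = 1.0
    occupancy: float = math.nan
    n_eff: float = math.nan
    E_site: float = math.nan
    delta_E_ifst: float = math.nan
    S_sw: float = math.nan
    minus_T_delta_S: float = math.nan
    delta_G_ifst: float = math.nan


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

#: rotation by pi about the molecular z axis (the HOH bisector): exchanges
#: the two hydrogens of the reference water.
_Q_H_EXCHANGE = np.array([0.0, 0.0, 0.0, 1.0])


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def orientational_distance(q1: np.ndarray, q2: np.ndarray,
                           water_symmetry: bool = False) -> float:
    """2*acos(|q1 . q2|), in [0, pi]; optionally minimized over H1<->H2 exchange."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    dot = abs(float(np.dot(q1, q2)))
    if water_symmetry:
        dot = max(dot, abs(float(np.dot(q1, _quat_mul(q2, _Q_H_EXCHANGE)))))
    return 2.0 * math.acos(min(1.0, dot))


def translational_distance(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image Euclidean distance under an orthorhombic box."""
    d = minimum_image_displacement(
        np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float),
        np.asarray(box, dtype=float),
    )
    return float(np.linalg.norm(d))


def water_orientation_quaternion(o: np.ndarray, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Unit quaternion (scalar-first) rotating the reference water onto the molecule.

    Reference orientation: oxygen at the origin, H-O-H bisector along +z,
    molecular plane equal to the xz plane with H1 at positive x.
    """
    u1 = np.asarray(h1, dtype=float) - np.asarray(o, dtype=float)
    u2 = np.asarray(h2, dtype=float) - np.asarray(o, dtype=float)
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    z = u1 + u2
    z = z / np.linalg.norm(z)
    x = u1 - u2
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    rot = np.column_stack([x, y, z])
    from scipy.spatial.transform import Rotation

    q_xyzw = Rotation.from_matrix(rot).as_quat()
    q = np.concatenate([[q_xyzw[3]], q_xyzw[:3]])
    return q if q[0] >= 0 else -q


def extract_water_observations(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    water_oxygens: Sequence[int] | None = None,
) -> list[WaterObservation]:
    """Position/orientation observations for selected waters in every frame."""
    waters = topology.water_molecules
    if water_oxygens is not None:
        keep = set(int(i) for i in water_oxygens)
        waters = [w for w in waters if w[0] in keep]
    obs = []
    for fi, frame in enumerate(ensemble.frames):
        c = frame.coordinates
        vol = frame.volume
        for o_idx, (h1, h2), _ in [(o, hs, v) for o, hs, v in waters]:
            obs.append(
                WaterObservation(
                    frame_index=fi,
                    position=c[o_idx],
                    orientation=water_orientation_quaternion(c[o_idx], c[h1], c[h2]),
                    frame_volume=vol,
                )
            )
    return obs


# ---------------------------------------------------------------------------
# nearest-neighbor entropy
# ---------------------------------------------------------------------------


def nearest_neighbor_distances(
    positions: np.ndarray,
    quaternions: np.ndarray,
    frame_indices: np.ndarray,
    box: np.ndarray,
    config: EstimatorConfig | None = None,
) -> np.ndarray:
    """k-th nearest-neighbor distance in the combined (trans, orient) metric.

    Same-frame pairs are excluded when configured; exact duplicates (zero
    combined distance) are never used as neighbors.  Entries with no usable
    neighbor come back NaN.
    """
    config = config or EstimatorConfig()
    positions = np.asarray(positions, dtype=float)
    quats = np.asarray(quaternions, dtype=float)
    frame_indices = np.asarray(frame_indices)
    m = len(positions)
    out = np.full(m, np.nan)
    chunk = max(1, int(2_000_000 // max(m, 1)))
    n_zero = 0
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        delta = positions[sl][:, None, :] - positions[None, :, :]
        delta = minimum_image_displacement(delta, box)
        d2_trans = np.einsum("ijk,ijk->ij", delta, delta)
        dots = np.abs(quats[sl] @ quats.T)
        if config.water_symmetry_in_orientation:
            qsym = _quat_mul(quats, _Q_H_EXCHANGE)
            dots = np.maximum(dots, np.abs(quats[sl] @ qsym.T))
        d_orient = 2.0 * np.arccos(np.clip(dots, -1.0, 1.0))
        d2 = d2_trans + d_orient**2
        rows = np.arange(sl.start, sl.stop)
        d2[np.arange(len(rows)), rows] = np.inf
        if config.exclude_same_frame_neighbors:
            d2[frame_indices[sl][:, None] == frame_indices[None, :]] = np.inf
        # rounding in the quaternion dot product keeps exact duplicates a hair
        # above zero, so duplicates are cut at a squared-distance tolerance
        zero = d2 < 1e-14
        n_zero += int(np.count_nonzero(zero))
        d2[zero] = np.inf  # duplicated observations cannot be neighbors
        if config.k == 1:
            vals = np.sqrt(np.min(d2, axis=1))
        else:
            part = np.partition(d2, config.k - 1, axis=1)[:, config.k - 1]
            vals = np.sqrt(part)
        vals[~np.isfinite(vals)] = np.nan
        out[sl] = vals
    if n_zero:
        warnings.warn(
            f"excluded {n_zero} zero-distance (degenerate duplicate) neighbor pair(s)",
            RuntimeWarning,
        )
    return out


def ssw_knn(
    observations: Sequence[WaterObservation],
    box: np.ndarray,
    config: EstimatorConfig | None = None,
    total_frames: int | None = None,
) -> float:
    """Solute-water entropy (kcal/mol/K) from nearest-neighbor distances.

    ``total_frames`` is the number of frames sampled (F); when omitted it is
    taken as the number of distinct frame indices present.  The mean waters
    per frame n = (number of observations)/F multiplies the per-observation
    estimate.
    """
    config = config or EstimatorConfig()
    if len(observations) < 2:
        raise ValueError("entropy estimation requires at least 2 observations")
    positions = np.stack([o.position for o in observations])
    quats = np.stack([o.orientation for o in observations])
    frames = np.asarray([o.frame_index for o in observations])
    volumes = np.asarray([o.frame_volume for o in observations])
    if np.any(volumes <= 0):
        raise ValueError("all frame volumes must be positive")
    m = len(observations)
    f = total_frames if total_frames is not None else len(np.unique(frames))
    n_per_frame = m / f

    d = nearest_neighbor_distances(positions, quats, frames, np.asarray(box, float), config)
    usable = np.isfinite(d)
    n_dropped = int(m - usable.sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} observation(s) with no non-degenerate neighbor",
            RuntimeWarning,
        )
    if usable.sum() < 2:
        raise ValueError("degenerate observation set: fewer than 2 usable neighbors")
    # k = 1 bias constant is Euler's gamma (= -digamma(1)); general k uses -digamma(k)
    bias = config.euler_gamma if config.k == 1 else -float(digamma(config.k))
    logs = np.log(np.pi * d[usable] ** 6 * m / (48.0 * volumes[usable]))
    return float(n_per_frame * config.gas_constant_R * (np.mean(logs) + bias))


# ---------------------------------------------------------------------------
# hydration sites
# ---------------------------------------------------------------------------


def cluster_hydration_sites(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    protein_atoms: Sequence[int] | None = None,
    surface_cutoff: float | None = 4.1,
    site_radius: float = 1.0,
    min_center_separation: float = 2.4,
    min_occupancy: float = 0.5,
) -> list[HydrationSite]:
    """Greedy density clustering of water-oxygen observations into sites.

    The densest remaining observation (count of observations within
    ``site_radius``) seeds a site; its members are removed, and centers are
    kept at least ``min_center_separation`` apart.  Clustering stops when the
    best remaining candidate would be occupied in fewer than ``min_occupancy``
    of the frames.  The stored center is refined to the member centroid.
    Only sites whose center lies within ``surface_cutoff`` of a protein heavy
    atom are retained (pass ``surface_cutoff=None`` to disable the filter).
    """
    ow = topology.water_oxygen_indices
    if len(ow) == 0:
        raise ValueError("topology contains no water molecules")
    n_frames = ensemble.n_frames
    pts = np.concatenate([f.coordinates[ow] for f in ensemble.frames])
    frame_of = np.repeat(np.arange(n_frames), len(ow))

    active = np.ones(len(pts), dtype=bool)
    centers: list[np.ndarray] = []
    occupancies: list[float] = []
    while active.sum() > 0:
        idx = np.flatnonzero(active)
        tree = cKDTree(pts[idx])
        counts = tree.query_ball_point(pts[idx], r=site_radius, return_length=True)
        order = np.argsort(counts)[::-1]
        chosen = None
        for o in order:
            cand = pts[idx[o]]
            if counts[o] / n_frames < min_occupancy:
                break
            if all(np.linalg.norm(cand - c) >= min_center_separation for c in centers):
                chosen = o
                break
        if chosen is None:
            break
        members_local = tree.query_ball_point(pts[idx[chosen]], r=site_radius)
        members = idx[np.asarray(members_local, dtype=int)]
        center = pts[members].mean(axis=0)
        occ = len(np.unique(frame_of[members])) / n_frames
        centers.append(center)
        occupancies.append(occ)
        active[members] = False

    sites = [
        HydrationSite(center=c, site_radius=site_radius, occupancy=o, n_eff=o)
        for c, o in zip(centers, occupancies)
    ]
    if surface_cutoff is not None:
        if protein_atoms is None:
            protein_atoms = [
                i for i in topology.protein_indices if topology.atoms[i].element != "H"
            ]
        if len(protein_atoms) == 0:
            raise ValueError("surface filter requested but no protein atoms available")
        ppos = ensemble.frames[0].coordinates[np.asarray(protein_atoms, dtype=int)]
        sites = [
            s
            for s in sites
            if np.min(np.linalg.norm(ppos - s.center, axis=1)) <= surface_cutoff
        ]
    return sites


def _site_water_per_frame(site: HydrationSite, ensemble: TrajectoryEnsemble,
                          topology: Topology) -> list[tuple[int, int]]:
    """(frame index, water oxygen index) for occupied frames (closest water)."""
    ow = topology.water_oxygen_indices
    hits = []
    for fi, frame in enumerate(ensemble.frames):
        d = np.linalg.norm(
            minimum_image_displacement(frame.coordinates[ow] - site.center, frame.box),
            axis=1,
        )
        j = int(np.argmin(d))
        if d[j] <= site.site_radius:
            hits.append((fi, int(ow[j])))
    return hits


def site_energy(
    site: HydrationSite,
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    bulk: BulkReference,
    options: EnergyOptions | None = None,
) -> tuple[float, float]:
    """(E_site, dE_IFST): site-water interaction energy and its bulk-referenced value.

    E_site is the full (not half-weighted) interaction of the site's water
    molecule with every atom outside it, averaged over occupied frames;
    dE_IFST = E_site - n_eff * E_bulk.
    """
    options = options or EnergyOptions()
    hits = _site_water_per_frame(site, ensemble, topology)
    if not hits:
        raise ValueError("site is never occupied in this ensemble")
    by_oxygen = {o: (hs, virt) for o, hs, virt in topology.water_molecules}
    vals = []
    for fi, o_idx in hits:
        hs, virt = by_oxygen[o_idx]
        members = [o_idx] + hs + virt
        # intra-molecule pairs are 1-2/1-3 exclusions, so row sums are purely
        # water-environment interactions at full pair weight
        rows = interaction_rows(members, ensemble.frames[fi], topology, options)
        vals.append(float(rows.sum()))
    e_site = float(np.mean(vals))
    n_eff = site.n_eff if math.isfinite(site.n_eff) else len(hits) / ensemble.n_frames
    return e_site, e_site - n_eff * bulk.E_bulk


def site_ssw(
    site: HydrationSite,
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    config: EstimatorConfig | None = None,
) -> float:
    """S_sw of the site's water observations (kcal/mol/K)."""
    hits = _site_water_per_frame(site, ensemble, topology)
    if len(hits) < 2:
        raise ValueError("site occupied in fewer than 2 frames")
    by_oxygen = {o: hs for o, hs, _ in topology.water_molecules}
    obs = []
    for fi, o_idx in hits:
        c = ensemble.frames[fi].coordinates
        h1, h2 = by_oxygen[o_idx]
        obs.append(
            WaterObservation(
                frame_index=fi,
                position=c[o_idx],
                orientation=water_orientation_quaternion(c[o_idx], c[h1], c[h2]),
                frame_volume=ensemble.frames[fi].volume,
            )
        )
    return ssw_knn(obs, ensemble.frames[0].box, config, total_frames=ensemble.n_frames)


def site_free_energy(
    site: HydrationSite,
    bulk: BulkReference,
    config: EstimatorConfig | None = None,
) -> HydrationSite:
    """Complete a site's dS/dG from its computed dE_IFST and S_sw.

    dS_IFST = S_sw - n_eff * S_bulk (the water-water term is zero by
    convention); -T dS_IFST = -T S_sw - n_eff * (-T S_bulk);
    dG_IFST = dE_IFST + (-T dS_IFST).
    """
    config = config or EstimatorConfig()
    if not math.isfinite(site.delta_E_ifst) or not math.isfinite(site.S_sw):
        raise ValueError("site requires delta_E_ifst and S_sw before free energy")
    t = config.temperature_T
    site.minus_T_delta_S = -t * site.S_sw - site.n_eff * bulk.minus_T_S_bulk
    site.delta_G_ifst = site.delta_E_ifst + site.minus_T_delta_S
    return site


def analyze_hydration_sites(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    bulk: BulkReference,
    options: EnergyOptions | None = None,
    config: EstimatorConfig | None = None,
    **cluster_kwargs,
) -> list[HydrationSite]:
    """Cluster sites and fill in energies, entropies, and free energies."""
    config = config or EstimatorConfig()
    sites = cluster_hydration_sites(ensemble, topology, **cluster_kwargs)
    for site in sites:
        site.E_site, site.delta_E_ifst = site_energy(site, ensemble, topology, bulk, options)
        site.S_sw = site_ssw(site, ensemble, topology, config)
        site_free_energy(site, bulk, config)
    return sites
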
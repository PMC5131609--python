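"""Treatment orchestration: detect persistent contacts on the native state,
evaluate their interaction energies in both states, aggregate over
replicates, and emit report tables.

Persistent contacts are defined on the native-state replicates only and the
same atom sets are then evaluated in the extended state, so the contact list
never depends on extended-state sampling.  Replicate statistics are the
arithmetic mean and sample standard deviation; report TSVs round energies to
one decimal (full precision is kept in the JSON outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import (
    CONTACT_KINDS,
    ContactRecord,
    DetectionCriteria,
    contact_energy,
    survey_contacts,
)
from .ifst import BulkReference, EstimatorConfig, analyze_hydration_sites, bulk_reference
from .model_io import Topology, TrajectoryEnsemble
from .nonbonded import (
    BondedParameters,
    EnergyOptions,
    atom_energy_table,
    component_breakdown,
    state_energy_statistics,
)

logger = logging.getLogger("hydrofold")

__all__ = [
    "TreatmentConfig",
    "ReportTable",
    "aggregate_replicates",
    "temperature_correct_enthalpy",
    "evaluate_contact_energies",
    "analyze_two_state",
    "run_treatment",
]


@dataclass
class TreatmentConfig:
    """One system treatment: labels, physical settings, and input inventory.

    ``synthetic`` (a recipe mapping) and the path-based inventory are
    mutually exclusive ways of supplying ensembles.
    """

    forcefield_label: str = "toy"
    water_model: str = "TIP3P"
    nacl_mM: float = 0.0
    bulk: BulkReference | None = None
    criteria: DetectionCriteria = field(default_factory=DetectionCriteria)
    energy: EnergyOptions = field(default_factory=EnergyOptions)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    synthetic: dict | None = None
    topology_path: str | None = None
    native_paths: list[str] = field(default_factory=list)
    extended_paths: list[str] = field(default_factory=list)
    box: tuple[float, float, float] | None = None
    run_ifst: bool = False
    output_dir: str | None = None

    def resolve_bulk(self) -> BulkReference:
        return self.bulk or bulk_reference(self.water_model, self.nacl_mM)

    def digest(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            return str(obj)

        fields = dataclasses.asdict(self)
        fields.pop("output_dir", None)  # where results land is not part of the analysis
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ReportTable:
    """Row table plus a footer of column means, recomputed on demand."""

    def __init__(self, name: str, data: pd.DataFrame,
                 footer_columns: Sequence[str] | None = None):
        self.name = name
        self.data = data.reset_index(drop=True)
        if footer_columns is None:
            footer_columns = [c for c in data.columns
                              if pd.api.types.is_numeric_dtype(data[c])]
        self.footer_columns = list(footer_columns)

    def footer(self) -> dict[str, float]:
        """Column means over the listed rows."""
        if self.data.empty:
            return {c: math.nan for c in self.footer_columns}
        return {c: float(self.data[c].mean()) for c in self.footer_columns}

    def to_tsv(self, path: str | Path, decimals: int = 1) -> None:
        df = self.data.copy()
        for c in self.footer_columns:
            df[c] = df[c].round(decimals)
        footer = {c: round(v, decimals) for c, v in self.footer().items()}
        label_col = df.columns[0]
        footer_row = {label_col: "Mean", **footer}
        df = pd.concat([df, pd.DataFrame([footer_row])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "rows": self.data.to_dict(orient="records"),
            "footer": self.footer(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation over replicates."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("aggregate_replicates requires at least one value")
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), std


def temperature_correct_enthalpy(dH_at_Tm: float, Tm: float, Cp: float,
                                 T_target: float) -> float:
    """Extrapolate a folding enthalpy from the melting temperature.

    dH(T) = dH(Tm) + Cp * (Tm - T); temperatures in Celsius (only the
    difference enters), Cp in kcal/mol/K, enthalpies in kcal/mol.  Folding
    heat capacity is negative in the dH = H_folded - H_unfolded convention
    used here, hence the folding enthalpy becomes less exothermic on
    cooling below Tm when Cp (quoted positive for unfolding) is positive.
    """
    if Cp < 0:
        raise ValueError("heat capacity must be non-negative")
    return dH_at_Tm + Cp * (Tm - T_target)


def evaluate_contact_energies(
    records: Sequence[ContactRecord],
    native_replicates: Sequence[TrajectoryEnsemble],
    extended_replicates: Sequence[TrajectoryEnsemble],
    topology: Topology,
    options: EnergyOptions | None = None,
    criteria: DetectionCriteria | None = None,
) -> list[ContactRecord]:
    """Fill per-state group energies (mean +/- std over replicates) and delta."""
    out = []
    for rec in records:
        e_nat = [contact_energy(rec, ens, topology, options, criteria)
                 for ens in native_replicates]
        e_ext = [contact_energy(rec, ens, topology, options, criteria)
                 for ens in extended_replicates]
        mn, sn = aggregate_replicates(e_nat)
        me, se = aggregate_replicates(e_ext)
        out.append(dataclasses.replace(
            rec, E_native=mn, E_native_std=sn, E_extended=me, E_extended_std=se,
            delta_E=mn - me,
        ))
    return out


def _contact_frame(records: Sequence[ContactRecord]) -> pd.DataFrame:
    rows = [
        {
            "atom_1": rec.slots[0].label,
            "atom_2": rec.slots[1].label,
            "persistence": rec.persistence,
            "persistence_std": rec.persistence_std,
            "E_native": rec.E_native,
            "E_native_std": rec.E_native_std,
            "E_extended": rec.E_extended,
            "E_extended_std": rec.E_extended_std,
            "delta_E": rec.delta_E,
        }
        for rec in sorted(records, key=lambda r: r.persistence)
    ]
    return pd.DataFrame(rows, columns=[
        "atom_1", "atom_2", "persistence", "persistence_std", "E_native",
        "E_native_std", "E_extended", "E_extended_std", "delta_E",
    ])


def analyze_two_state(
    topology: Topology,
    native_replicates: Sequence[TrajectoryEnsemble],
    extended_replicates: Sequence[TrajectoryEnsemble],
    criteria: DetectionCriteria | None = None,
    options: EnergyOptions | None = None,
    bonded_params: BondedParameters | None = None,
) -> dict[str, ReportTable]:
    """Contact, energy, and census report tables for a native/extended pair."""
    criteria = criteria or DetectionCriteria()
    options = options or EnergyOptions()
    if not native_replicates or not extended_replicates:
        raise ValueError("both native and extended replicates are required")

    logger.info("surveying contacts on %d native replicates", len(native_replicates))
    records = survey_contacts(native_replicates, topology, criteria)
    persistent = [r for r in records.values()
                  if r.persistence > criteria.persistence_threshold]
    logger.info("found %d contacts, %d persistent", len(records), len(persistent))
    evaluated = evaluate_contact_energies(
        persistent, native_replicates, extended_replicates, topology, options, criteria)

    tables: dict[str, ReportTable] = {}
    for kind in CONTACT_KINDS:
        recs = [r for r in evaluated if r.kind == kind]
        tables[kind] = ReportTable(
            kind, _contact_frame(recs),
            footer_columns=["persistence", "E_native", "E_extended", "delta_E"],
        )

    census_rows = []
    for kind in CONTACT_KINDS:
        total = sum(1 for r in records.values() if r.kind == kind)
        npers = sum(1 for r in evaluated if r.kind == kind)
        census_rows.append({"kind": kind, "total": total, "persistent": npers})
    tables["census"] = ReportTable("census", pd.DataFrame(census_rows),
                                   footer_columns=["total", "persistent"])

    nat_stat = state_energy_statistics(native_replicates, topology, options, bonded_params)
    ext_stat = state_energy_statistics(extended_replicates, topology, options, bonded_params)
    tables["state_energy"] = ReportTable(
        "state_energy",
        pd.DataFrame([
            {"state": "native", "mean_energy": nat_stat.mean_energy,
             "std": nat_stat.std_over_replicates, "n_snapshots": nat_stat.n_snapshots},
            {"state": "extended", "mean_energy": ext_stat.mean_energy,
             "std": ext_stat.std_over_replicates, "n_snapshots": ext_stat.n_snapshots},
            {"state": "delta (extended - native)",
             "mean_energy": ext_stat.mean_energy - nat_stat.mean_energy,
             "std": math.nan, "n_snapshots": nat_stat.n_snapshots},
        ]),
        footer_columns=[],
    )

    def pooled(replicates, label):
        frames = [f for ens in replicates for f in ens.frames]
        return TrajectoryEnsemble(
            state_label=label, replicate_id=0,
            ensemble_kind=replicates[0].ensemble_kind, frames=frames,
            sampling_interval=replicates[0].sampling_interval, topology=topology,
        )

    nat_pool = pooled(native_replicates, "native")
    ext_pool = pooled(extended_replicates, "extended")
    _, sums = atom_energy_table(nat_pool, ext_pool, topology, options)
    tables["atom_sums"] = ReportTable(
        "atom_sums",
        pd.DataFrame([{"delta_E_total": sums["all"], "delta_E_polar": sums["polar"],
                       "delta_E_nonpolar": sums["nonpolar"]}]),
        footer_columns=[],
    )

    comp_nat = component_breakdown(nat_pool, topology, options, bonded_params)
    comp_ext = component_breakdown(ext_pool, topology, options, bonded_params)
    comp_rows = []
    for key in sorted(set(comp_nat) | set(comp_ext)):
        en = comp_nat.get(key, 0.0)
        ee = comp_ext.get(key, 0.0)
        comp_rows.append({
            "interaction": key[0], "term": key[1], "E_native": en, "E_extended": ee,
            "delta_E": en - ee, "favored_state": "native" if en <= ee else "extended",
        })
    tables["components"] = ReportTable("components", pd.DataFrame(comp_rows),
                                       footer_columns=[])
    return tables


def run_treatment(
    config: TreatmentConfig,
    topology: Topology | None = None,
    native_replicates: Sequence[TrajectoryEnsemble] | None = None,
    extended_replicates: Sequence[TrajectoryEnsemble] | None = None,
    ifst_ensemble: TrajectoryEnsemble | None = None,
) -> dict[str, ReportTable]:
    """Run a full treatment analysis; ensembles may be passed directly,
    generated from ``config.synthetic``, or loaded from the path inventory."""
    from . import model_io, synthetic

    if native_replicates is None:
        if config.synthetic is not None:
            spec = synthetic.GeneratorSpec(
                seed=int(config.synthetic.get("seed", 0)),
                n_frames=int(config.synthetic.get("n_frames", 20)),
                water_model=config.water_model,
                recipe=config.synthetic.get("recipe", "two_state_toy"),
                params=dict(config.synthetic.get("params", {})),
            )
            if spec.recipe != "two_state_toy":
                raise ValueError("run_treatment requires the two_state_toy recipe")
            topology, native_replicates, extended_replicates = synthetic.generate(spec)
        else:
            if config.topology_path is None:
                raise ValueError("config supplies neither ensembles nor paths")
            topology = model_io.read_topology(config.topology_path)
            topology = model_io.assign_symmetry_groups(topology)
            native_replicates = [
                model_io.read_frames(p, topology=topology, box=config.box,
                                     state_label="native", replicate_id=i)
                for i, p in enumerate(config.native_paths)
            ]
            extended_replicates = [
                model_io.read_frames(p, topology=topology, box=config.box,
                                     state_label="extended", replicate_id=i)
                for i, p in enumerate(config.extended_paths)
            ]
    if topology is None or extended_replicates is None:
        raise ValueError("topology and extended replicates are required")

    tables = analyze_two_state(
        topology, native_replicates, extended_replicates,
        criteria=config.criteria, options=config.energy,
    )

    if config.run_ifst:
        ens = ifst_ensemble or native_replicates[0]
        sites = analyze_hydration_sites(
            ens, topology, config.resolve_bulk(),
            options=config.energy, config=config.estimator,
        )
        tables["hydration_sites"] = ReportTable(
            "hydration_sites",
            pd.DataFrame([
                {"x": s.center[0], "y": s.center[1], "z": s.center[2],
                 "occupancy": s.occupancy, "E_site": s.E_site,
                 "delta_E_ifst": s.delta_E_ifst, "minus_T_delta_S": s.minus_T_delta_S,
                 "delta_G_ifst": s.delta_G_ifst}
                for s in sites
            ]),
            footer_columns=["occupancy", "delta_E_ifst", "minus_T_delta_S",
                            "delta_G_ifst"],
        )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "forcefield_label": config.forcefield_label,
            "water_model": config.water_model,
            "nacl_mM": config.nacl_mM,
            "elec_scheme": config.energy.elec_scheme,
            "config_digest": config.digest(),
        }
        (out / "provenance.json").write_text(json.dumps(meta, indent=1))
        for name, table in tables.items():
            table.to_tsv(out / f"{name}.tsv")
            table.to_json(out / f"{name}.json")
        logger.info("wrote %d tables to %s", len(tables), out)
    return tables
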
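"""Published villin-headpiece worked-example data (CHARMM22/TIP3P/NaCl).

Per-contact interaction energies, state-energy components, and atom-class
sums reported for the folded (native, PDB 1YRF N68H) versus fully extended
villin headpiece, used as inputs for the aggregation layer's worked examples.
Energies in kcal/mol; persistence is mean contacts per frame over 40
replicate simulations.  These tables are *data*, not package output: the
package's own detectors and energy kernels are exercised on synthetic
ensembles, while these published values feed the replicate-aggregation and
report-table machinery.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "hbond_table",
    "nonpolar_table",
    "coophyd_table",
    "component_table",
    "atom_sum_table",
    "census_table",
    "STATE_TOTALS",
    "GLU45_SITE_DG",
    "LYS48_SITE_DG",
    "BRIDGE_SITE_DG",
    "FOLDING_ENTHALPY_TM",
    "MELTING_TEMPERATURE_C",
    "HEAT_CAPACITY",
]

#: Mean hydration-site free-energy contributions (kcal/mol) around the
#: independently hydrated GLU45 and LYS48 side chains in the extended state,
#: and the single cooperatively hydrating site bridging them in the native
#: state.
#: Mean total system energy (value, std over replicates) of the two states.
STATE_TOTALS = {"native": (-88985.7, 16.0), "extended": (-88949.6, 16.5)}

GLU45_SITE_DG = -4.24
LYS48_SITE_DG = -7.64
BRIDGE_SITE_DG = -13.69

#: Calorimetric villin folding enthalpy (kcal/mol) at the melting
#: temperature, with the folding heat capacity (kcal/mol/K) used to
#: extrapolate it to other temperatures.
FOLDING_ENTHALPY_TM = -31.0
MELTING_TEMPERATURE_C = 74.4
HEAT_CAPACITY = 0.374

_HBOND_ROWS = [
    # donor, acceptor, persistence, pers_std, E_native, E_nat_std, E_extended, E_ext_std, delta
    ("PHE47 N", "SER43 O", 0.96, 0.06, -6.1, 0.3, -5.4, 0.2, -0.7),
    ("LYS48 N", "ASP44 O", 0.99, 0.01, 3.9, 0.2, 4.5, 0.3, -0.6),
    ("PHE51 N", "PHE47 O", 0.99, 0.01, 0.3, 0.3, 2.1, 0.2, -1.7),
    ("ARG55 NE", "ASP44 OD1/OD2", 1.00, 0.00, -100.1, 0.2, -99.2, 0.4, -1.0),
    ("ARG55 NH1/NH2", "ASP44 OD1/OD2", 1.00, 0.00, -97.1, 0.0, -94.1, 0.4, -3.0),
    ("PHE58 N", "THR54 O", 1.00, 0.01, -8.7, 0.2, -7.8, 0.2, -1.0),
    ("ALA59 N", "ARG55 O", 0.96, 0.02, -2.2, 0.2, -0.8, 0.2, -1.4),
    ("GLN66 N", "PRO62 O", 0.99, 0.01, -4.9, 0.2, -3.9, 0.2, -0.9),
    ("GLN67 N", "LEU63 O", 1.00, 0.00, 0.6, 0.2, 1.1, 0.3, -0.5),
    ("HIS68 N", "TRP64 O", 0.99, 0.01, 2.6, 0.2, 3.8, 0.2, -1.2),
    ("LEU69 N", "LYS65 O", 0.99, 0.01, 0.4, 0.2, 1.5, 0.2, -1.1),
    ("LYS70 N", "GLN66 O", 0.99, 0.01, 0.7, 0.2, 1.7, 0.2, -1.0),
    ("LYS71 N", "GLN67 O", 0.99, 0.01, 0.4, 0.3, 1.8, 0.2, -1.4),
    ("GLU72 N", "HIS68 O", 0.99, 0.01, -2.0, 0.3, -0.9, 0.2, -1.1),
    ("LYS73 N", "LEU69 O", 0.95, 0.03, 1.6, 0.2, 1.3, 0.4, 0.3),
]

_NONPOLAR_ROWS = [
    ("MET53 CE", "LEU61 CD1/CD2", 1.10, 0.14, -11.4, 0.1, -10.7, 0.1, -0.7),
    ("LEU61 CD1/CD2", "LYS65 CB", 1.11, 0.49, -8.4, 0.1, -7.5, 0.1, -0.9),
    ("PHE51 CE1/CE2", "LEU75 CD1/CD2", 1.13, 0.10, -6.1, 0.1, -5.9, 0.1, -0.3),
    ("MET53 SD", "LEU61 CD1/CD2", 1.14, 0.12, -12.6, 0.1, -11.2, 0.1, -1.4),
    ("PHE47 CE1/CE2", "PHE58 CD1/CD2", 1.22, 0.12, 0.0, 0.1, 0.4, 0.1, -0.4),
    ("PHE51 CE1/CE2", "PHE58 CE1/CE2", 1.25, 0.22, 3.1, 0.1, 3.1, 0.1, 0.0),
    ("VAL50 CG1/CG2", "PHE51 CE1/CE2", 1.28, 0.18, -2.0, 0.1, -1.7, 0.1, -0.3),
    ("VAL50 CG1/CG2", "PHE51 CD1/CD2", 1.31, 0.16, -4.7, 0.1, -4.4, 0.1, -0.4),
    ("PHE51 CD1/CD2", "PHE58 CE1/CE2", 1.34, 0.20, 0.4, 0.1, 0.4, 0.1, 0.0),
    ("PHE58 CE1/CE2", "GLN66 CG", 1.48, 0.12, -10.5, 0.1, -9.9, 0.1, -0.6),
    ("PHE47 CE1/CE2", "PHE51 CE1/CE2", 1.51, 0.08, 2.9, 0.1, 3.1, 0.1, -0.2),
    ("PHE47 CE1/CE2", "ARG55 CG", 1.57, 0.12, -3.4, 0.1, -2.9, 0.1, -0.5),
    ("PHE47 CD1/CD2", "PHE51 CD1/CD2", 1.60, 0.13, -2.8, 0.1, -2.3, 0.1, -0.5),
    ("PHE47 CE1/CE2", "PHE51 CD1/CD2", 1.76, 0.22, 0.1, 0.1, 0.4, 0.1, -0.3),
    ("PHE47 CD1/CD2", "ARG55 CG", 1.86, 0.15, -6.1, 0.1, -5.6, 0.1, -0.5),
]

_COOPHYD_ROWS = [
    ("LEU42 O", "ARG55 HH11/HH21", 0.63, 0.25, -67.22, 0.38, -68.4, 0.4, 1.2),
    ("ASP44 HN", "ASP44 OD1/OD2", 0.58, 0.14, -34.01, 0.31, -31.3, 0.3, -2.7),
    ("LYS48 O", "ALA49 O", 0.64, 0.08, 3.88, 0.30, 3.9, 0.2, -0.1),
    ("ALA49 O", "VAL50 O", 0.92, 0.08, 0.95, 0.22, 0.8, 0.2, 0.1),
    ("VAL50 O", "LYS73 HZ1/HZ2/HZ3", 0.85, 0.11, -5.18, 0.24, -5.3, 0.2, 0.1),
    ("ALA59 O", "LEU61 O", 0.89, 0.05, 17.08, 0.25, 16.4, 0.2, 0.7),
    ("ALA59 O", "GLN66 HE21", 0.87, 0.08, -16.43, 0.30, -16.9, 0.2, 0.5),
    ("GLN66 OE1", "LYS70 HZ1/HZ2/HZ3", 0.68, 0.13, -31.91, 0.20, -31.2, 0.2, -0.7),
    ("LYS71 O", "GLU72 O", 0.62, 0.06, 1.68, 0.20, 0.9, 0.2, 0.7),
    ("GLY74 O", "PHE76 OT1/OT2", 0.69, 0.14, -28.51, 0.38, -27.8, 0.3, -0.7),
    ("LEU75 O", "PHE76 OT1/OT2", 0.85, 0.10, -20.31, 0.33, -20.5, 0.3, 0.2),
    ("ASP44 OD1/OD2", "ARG55 HN", 0.51, 0.20, -29.87, 0.26, -29.0, 0.4, -0.9),
    ("ASP44 OD1/OD2", "SER56 HN", 0.86, 0.16, -22.47, 0.23, -22.2, 0.4, -0.3),
    ("GLU72 OE1/OE2", "LYS73 HZ1/HZ2/HZ3", 0.61, 0.20, -23.59, 0.30, -23.2, 0.3, -0.4),
    ("GLU45 OE1/OE2", "LYS48 HZ1/HZ2/HZ3", 0.69, 0.31, -23.93, 0.72, -23.2, 0.3, -0.7),
]

_CONTACT_COLUMNS = [
    "atom_1", "atom_2", "persistence", "persistence_std",
    "E_native", "E_native_std", "E_extended", "E_extended_std", "delta_E",
]


def hbond_table() -> pd.DataFrame:
    """Persistent direct hydrogen bonds (fifteen most persistent)."""
    return pd.DataFrame(_HBOND_ROWS, columns=_CONTACT_COLUMNS)


def nonpolar_table() -> pd.DataFrame:
    """Persistent non-polar contacts (fifteen most persistent)."""
    return pd.DataFrame(_NONPOLAR_ROWS, columns=_CONTACT_COLUMNS)


def coophyd_table() -> pd.DataFrame:
    """Persistent cooperatively hydrated interactions (fifteen rows)."""
    return pd.DataFrame(_COOPHYD_ROWS, columns=_CONTACT_COLUMNS)


def component_table() -> pd.DataFrame:
    """Bonded/non-bonded energy components of the native and extended states."""
    rows = [
        ("protein-protein", "bonded", 573.8, 1.0, 578.0, 1.2),
        ("protein-protein", "nonbonded", -642.6, 29.6, -165.5, 24.5),
        ("protein-water", "nonbonded", -1465.2, 46.6, -2106.7, 57.6),
        ("water-water", "nonbonded", -77156.9, 33.5, -76920.8, 52.5),
        ("protein-salt", "nonbonded", -179.1, 28.3, -367.2, 77.8),
        ("water-salt", "nonbonded", -9085.3, 46.5, -8974.0, 61.2),
        ("salt-salt", "nonbonded", -1030.3, 20.8, -993.4, 28.8),
    ]
    df = pd.DataFrame(
        rows,
        columns=["interaction", "term", "E_native", "E_native_std",
                 "E_extended", "E_extended_std"],
    )
    df["delta_E"] = (df["E_native"] - df["E_extended"]).round(1)
    return df


def atom_sum_table() -> pd.DataFrame:
    """All/polar/non-polar protein-atom energy sums per system treatment."""
    rows = [
        ("CHARMM22/TIP3P", -63.8, -34.3, -29.5),
        ("CHARMM36/TIP3P", -62.9, -31.3, -31.6),
        ("CHARMM36/TIP4P-2005", -49.7, -21.0, -28.7),
        ("CHARMM22/TIP3P/NaCl", -62.0, -31.5, -30.5),
    ]
    return pd.DataFrame(rows, columns=["treatment", "delta_E_total",
                                       "delta_E_polar", "delta_E_nonpolar"])


def census_table() -> pd.DataFrame:
    """Total and persistent contact counts per kind and treatment."""
    rows = [
        ("CHARMM22/TIP3P", 142, 27, 607, 72, 474, 17),
        ("CHARMM36/TIP3P", 130, 30, 526, 71, 470, 16),
        ("CHARMM36/TIP4P-2005", 146, 24, 532, 84, 531, 59),
        ("CHARMM22/TIP3P/NaCl", 127, 24, 533, 73, 438, 15),
    ]
    return pd.DataFrame(rows, columns=[
        "treatment", "hbond_total", "hbond_persistent",
        "nonpolar_total", "nonpolar_persistent",
        "coophyd_total", "coophyd_persistent",
    ])
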
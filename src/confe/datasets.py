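"""Reference tables from a reported ten-replicate 20-ns MD study of the
APOBEC3G catalytic domain (A3Gctd), NMR form (PDB 2KEM) vs crystal form
(PDB 3IR2).

These are small published summary tables, embedded as plain constants so
the replicate-statistics and table-combination arithmetic of this package
can be validated against an external calculation: per-run GBSA free
energies without entropy (G2), the negated entropic term (printed as
"TS", equal to -T*S so that G1 = G2 + TS_printed), and the combined G1;
and per-run main-chain RMSDs with the average count of waters in contact
with the catalytic Zn(2+) ("ligand H2O").

The absolute energies depend on that study's trajectories and force-field
variant and are not recomputable here; only the arithmetic that combines
and summarizes them is.
"""

from __future__ import annotations

import pandas as pd

# Replicate free energies (kcal/mol) after 20-ns MD; columns per form:
# G2 (enthalpy only), printed TS (= -T*S), G1 = G2 + printed TS.
_FREE_ENERGY_ROWS = [
    # run, crystal G2, crystal TS, crystal G1, nmr G2, nmr TS, nmr G1
    (1, -6043.13, -6702.60, -12745.74, -5884.37, -7027.53, -12911.90),
    (2, -6036.39, -6736.90, -12773.30, -5944.13, -7121.26, -13065.39),
    (3, -6044.50, -6847.83, -12892.33, -5923.86, -6868.51, -12792.37),
    (4, -6047.56, -6750.79, -12798.36, -5939.21, -7080.32, -13019.53),
    (5, -6024.11, -6719.73, -12743.84, -5936.12, -6916.54, -12852.66),
    (6, -6065.13, -6664.80, -12729.94, -5895.72, -6944.52, -12840.24),
    (7, -6034.97, -6781.37, -12816.35, -5935.67, -6947.93, -12883.60),
    (8, -6040.02, -6734.99, -12775.01, -5915.02, -6966.65, -12881.67),
    (9, -6026.65, -6828.27, -12854.92, -5941.27, -6922.34, -12863.61),
    (10, -6036.85, -6849.60, -12886.46, -5900.79, -6926.11, -12826.90),
]

# Published Average and sigma rows of the same table (kcal/mol).
FREE_ENERGY_PUBLISHED_SUMMARY = {
    "crystal": {"G2": -6039.93, "TS": -6761.69, "G1": -12801.62,
                "sigma_G2": 10.94, "sigma_TS": 60.04, "sigma_G1": 56.22},
    "nmr": {"G2": -5921.62, "TS": -6972.17, "G1": -12893.79,
            "sigma_G2": 20.37, "sigma_TS": 75.38, "sigma_G1": 81.28},
}

# Main-chain RMSD (A) after 20 ns per replicate, against each form's own
# pre-MD structure ("self") and the other form's ("other"), plus the
# average number of waters contacting the catalytic Zn ("ligand_h2o").
_RMSD_20NS_ROWS = [
    # run, crystal self, crystal other, crystal ligand_h2o,
    #      nmr self, nmr other, nmr ligand_h2o
    (1, 1.85, 3.59, 0.43, 2.21, 4.02, 0.30),
    (2, 1.96, 4.09, 0.32, 3.75, 4.13, 0.52),
    (3, 2.23, 4.29, 0.34, 1.86, 3.87, 0.22),
    (4, 2.13, 4.34, 0.50, 2.28, 4.05, 0.49),
    (5, 1.80, 3.85, 0.46, 2.62, 4.56, 0.25),
    (6, 2.48, 3.78, 0.27, 2.76, 4.52, 0.33),
    (7, 2.77, 3.64, 0.46, 2.76, 3.90, 0.32),
    (8, 1.82, 3.82, 0.30, 2.29, 4.72, 0.31),
    (9, 1.58, 4.13, 0.57, 3.27, 3.84, 0.32),
    (10, 1.82, 4.18, 0.58, 2.59, 4.00, 0.31),
]

RMSD_20NS_PUBLISHED_AVERAGES = {
    "crystal": {"self": 2.04, "other": 3.97, "ligand_h2o": 0.43},
    "nmr": {"self": 2.64, "other": 4.16, "ligand_h2o": 0.34},
}

# Main-chain RMSD (A) of three DNA-binding arginines after 20-ns MD.
ARGININE_RMSD = pd.DataFrame(
    {
        "nmr_vs_nmr": [3.95, 4.24, 2.29],
        "nmr_vs_xray": [8.20, 8.64, 2.24],
        "xray_vs_xray": [3.38, 2.60, 1.53],
        "xray_vs_nmr": [8.42, 8.35, 1.95],
    },
    index=["Arg213", "Arg215", "Arg320"],
)

# Published Zn-water contact statistics (mean +/- sigma over replicates).
ZN_WATER_CONTACTS = {"nmr": (0.34, 0.07), "crystal": (0.43, 0.10)}


def load_free_energy_runs() -> pd.DataFrame:
    """Per-run G2 / printed-TS / G1 for both forms, indexed by run."""
    df = pd.DataFrame(
        _FREE_ENERGY_ROWS,
        columns=["run", "crystal_G2", "crystal_TS", "crystal_G1",
                 "nmr_G2", "nmr_TS", "nmr_G1"],
    ).set_index("run")
    return df


def load_rmsd_runs() -> pd.DataFrame:
    """Per-run 20-ns main-chain RMSD and ligand-water count per form."""
    return pd.DataFrame(
        _RMSD_20NS_ROWS,
        columns=["run", "crystal_self", "crystal_other", "crystal_ligand_h2o",
                 "nmr_self", "nmr_other", "nmr_ligand_h2o"],
    ).set_index("run")
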
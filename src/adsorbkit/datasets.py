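"""Bundled reference tables.

``fn_gold_first_contact_times`` carries the published per-simulation first
contact times (ns) of each residue type for fibronectin FNIII(9-10)
adsorbing on Au(111): eight independent 100-ns runs differing in the
starting orientation (six 60-degree rotations of the conformation parallel
to the surface, plus N-terminus-down and C-terminus-down perpendicular
starts).  The contact criterion is a closest-atom distance below 0.3 nm.
Empty cells mean no residue of that type contacted the surface in that run;
ACE and NAC are the acetyl / N-acetyl caps.  The table is the reference
input for the residue-type aggregation utilities and the worked examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["fn_gold_first_contact_times", "FN_GOLD_SIM_IDS"]

FN_GOLD_SIM_IDS = ["0deg", "60deg", "120deg", "180deg", "240deg", "300deg",
                   "N-Term", "C-Term"]

_CELLS: dict[str, list[float | None]] = {
    "ACE": [0.275, 1.45, 20.2, 42.375, None, None, 0.0, None],
    "ALA": [None, 2.275, 20.8, 37.45, None, 84.4, 9.975, 28.825],
    "ARG": [0.75, 0.025, 0.1, 0.475, 0.05, 0.9, 0.025, 0.175],
    "ASN": [30.7, None, None, 18.55, 5.425, 0.3, None, 52.95],
    "ASP": [59.275, 4.875, 1.65, 4.7, 0.175, 0.05, 20.775, None],
    "GLN": [23.95, 21.725, 17.575, 36.6, None, None, None, None],
    "GLU": [1.15, 11.525, 60.4, 43.25, 4.6, 18.875, 22.775, 43.525],
    "GLY": [2.475, 1.225, 1.65, 5.725, 4.55, 0.85, 10.1, 0.2],
    "HIS": [0.025, 21.625, 60.425, 4.075, 4.625, 46.65, None, None],
    "ILE": [5.8, 21.325, 0.075, 36.9, None, None, None, 58.25],
    "LEU": [5.45, 7.975, 20.75, None, None, 21.975, 20.775, None],
    "LYS": [None, None, 7.15, 2.6, None, None, None, None],
    "NAC": [54.25, 1.225, None, None, None, None, None, 0.4],
    "PHE": [0.875, 71.2, 73.975, 31.375, 81.7, 41.6, None, None],
    "PRO": [2.875, 1.75, 60.5, 0.7, 4.625, 0.05, None, 0.0],
    "SER": [1.55, 30.55, 2.1, 0.025, 6.8, 0.125, None, None],
    "THR": [30.75, 1.95, 1.65, 1.15, 4.575, 22.025, 0.1, 0.175],
    "TYR": [None, 2.05, None, 4.4, None, None, None, 28.9],
    "VAL": [19.975, 11.3, 20.525, 40.9, 69.875, 60.9, None, 19.275],
}


def fn_gold_first_contact_times(long_format: bool = False):
    """The reference first-contact matrix (residue type x simulation, ns).

    With ``long_format=True`` the same data comes back as a list of
    per-simulation tables shaped like :func:`~adsorbkit.contacts.first_contact_times`
    output (one pseudo-residue per present cell), ready for
    :func:`~adsorbkit.contacts.aggregate_first_contact_by_type`.
    """
    matrix = pd.DataFrame(
        {sim: [(_CELLS[rt][j] if _CELLS[rt][j] is not None else np.nan)
               for rt in sorted(_CELLS)]
         for j, sim in enumerate(FN_GOLD_SIM_IDS)},
        index=pd.Index(sorted(_CELLS), name="residue_type"),
    )
    if not long_format:
        return matrix
    tables = []
    for sim in FN_GOLD_SIM_IDS:
        rows = []
        for rt in sorted(_CELLS):
            v = matrix.loc[rt, sim]
            rows.append({"residue_label": f"{rt}@{sim}", "residue_type": rt,
                         "sim_id": sim, "t_first_ns": v})
        tables.append(pd.DataFrame(rows))
    return tables
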
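"""Arginine side-chain orientation relative to the surface.

An Arg is *in contact* when any of its atoms lies within the atomic contact
cutoff (0.35 nm by default) of the surface.  A contacting side chain is
*parallel* when all three guanidinium C-N bonds (CZ-NE, CZ-NH1, CZ-NH2 — the
bonds spanning the guanidinium plane) make angles below the threshold
(default 30 deg) with the surface plane, otherwise *perpendicular*.  Per
(frame, Arg) exactly one of the three states holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import bond_plane_angle, delta_z
from .io_formats import AnalysisConfig, SurfaceModel, Topology, Trajectory

__all__ = [
    "NO_CONTACT",
    "CONTACT_PARALLEL",
    "CONTACT_PERPENDICULAR",
    "STATE_NAMES",
    "GuanidiniumGroup",
    "OrientationStateSeries",
    "find_guanidinium_groups",
    "classify_arg_state",
    "orientation_state_map",
    "first_contact_orientation_stats",
    "run_length_encode",
]

NO_CONTACT = 0
CONTACT_PARALLEL = 1
CONTACT_PERPENDICULAR = 2
STATE_NAMES = {NO_CONTACT: "no_contact",
               CONTACT_PARALLEL: "contact_parallel",
               CONTACT_PERPENDICULAR: "contact_perpendicular"}

_CORE_ATOMS = ("CZ", "NE", "NH1", "NH2")


@dataclass
class GuanidiniumGroup:
    """Atom bookkeeping for one arginine's guanidinium moiety."""

    arg_label: str
    cz: int
    ne: int
    nh1: int
    nh2: int
    all_atoms: np.ndarray  # every atom of the residue (contact test)


@dataclass
class OrientationStateSeries:
    """State per (frame, Arg): 0 no_contact, 1 parallel, 2 perpendicular."""

    times: np.ndarray
    states: np.ndarray          # (n_frames, n_arg) int
    arg_labels: list[str]
    contact_cutoff: float
    angle_threshold: float

    def as_long_table(self) -> pd.DataFrame:
        frames, args = np.meshgrid(np.arange(len(self.times)),
                                   np.arange(len(self.arg_labels)), indexing="ij")
        return pd.DataFrame({
            "time_ns": self.times[frames.ravel()],
            "arg_label": np.asarray(self.arg_labels, dtype=object)[args.ravel()],
            "state": [STATE_NAMES[s] for s in self.states.ravel()],
        })


def find_guanidinium_groups(topology: Topology,
                            residue_type: str = "ARG") -> list[GuanidiniumGroup]:
    """Locate every Arg and its CZ/NE/NH1/NH2 quartet, in topology order."""
    groups = []
    labels = topology.residue_labels()
    types = topology.residue_types()
    for label, rtype, idx in zip(labels, types, topology.residue_atom_indices()):
        if rtype != residue_type:
            continue
        names = {str(topology.atom_name[i]): int(i) for i in idx}
        missing = [a for a in _CORE_ATOMS if a not in names]
        if missing:
            raise ValueError(f"residue {label} lacks guanidinium atoms {missing}")
        groups.append(GuanidiniumGroup(arg_label=label, cz=names["CZ"], ne=names["NE"],
                                       nh1=names["NH1"], nh2=names["NH2"],
                                       all_atoms=idx))
    return groups


def classify_arg_state(frame_coords: np.ndarray, group: GuanidiniumGroup,
                       surface: SurfaceModel, contact_cutoff: float = 0.35,
                       angle_threshold: float = 30.0) -> int:
    """Classify one Arg in one frame (see module docstring for the rules)."""
    dz = delta_z(frame_coords[group.all_atoms], surface).value
    if not np.any(dz < contact_cutoff):
        return NO_CONTACT
    cz = frame_coords[group.cz]
    bonds = np.stack([frame_coords[group.ne] - cz,
                      frame_coords[group.nh1] - cz,
                      frame_coords[group.nh2] - cz])
    angles = bond_plane_angle(bonds)
    return CONTACT_PARALLEL if np.all(angles < angle_threshold) else CONTACT_PERPENDICULAR


def orientation_state_map(trajectory: Trajectory,
                          groups: list[GuanidiniumGroup] | Topology,
                          surface: SurfaceModel,
                          config: AnalysisConfig | None = None) -> OrientationStateSeries:
    """State of every Arg in every frame (rows in topology order).

    Vectorized across frames; equivalent to calling
    :func:`classify_arg_state` per (frame, group).
    """
    config = config or AnalysisConfig()
    if isinstance(groups, Topology):
        groups = find_guanidinium_groups(groups)
    if not groups:
        raise ValueError("no guanidinium groups supplied")
    n_frames = trajectory.n_frames
    states = np.empty((n_frames, len(groups)), dtype=int)
    coords = trajectory.coords
    for g, grp in enumerate(groups):
        dz = delta_z(coords[:, grp.all_atoms, :], surface).value  # (frames, atoms)
        in_contact = np.any(dz < config.contact_cutoff_atomic, axis=1)
        cz = coords[:, grp.cz, :]
        bonds = np.stack([coords[:, grp.ne, :] - cz,
                          coords[:, grp.nh1, :] - cz,
                          coords[:, grp.nh2, :] - cz], axis=1)  # (frames, 3, 3)
        angles = bond_plane_angle(bonds)                         # (frames, 3)
        parallel = np.all(angles < config.angle_threshold, axis=1)
        states[:, g] = np.where(in_contact,
                                np.where(parallel, CONTACT_PARALLEL, CONTACT_PERPENDICULAR),
                                NO_CONTACT)
    return OrientationStateSeries(times=trajectory.times, states=states,
                                  arg_labels=[g.arg_label for g in groups],
                                  contact_cutoff=config.contact_cutoff_atomic,
                                  angle_threshold=config.angle_threshold)


def first_contact_orientation_stats(series: OrientationStateSeries) -> dict:
    """Orientation at each Arg's first contact and the perpendicular fraction.

    The first contact event of an Arg is its first frame out of no_contact;
    re-contacts after later detachment are not counted.  The fraction is
    #(perpendicular at first contact) / #(Args that ever contact); it is
    None when nothing ever contacts.
    """
    records = []
    n_perp = 0
    n_contacting = 0
    for g, label in enumerate(series.arg_labels):
        col = series.states[:, g]
        hits = np.nonzero(col != NO_CONTACT)[0]
        if hits.size == 0:
            records.append({"arg_label": label, "t_first_ns": np.nan,
                            "first_state": None})
            continue
        i = hits[0]
        n_contacting += 1
        if col[i] == CONTACT_PERPENDICULAR:
            n_perp += 1
        records.append({"arg_label": label, "t_first_ns": float(series.times[i]),
                        "first_state": STATE_NAMES[int(col[i])]})
    fraction = (n_perp / n_contacting) if n_contacting else None
    return {"fraction_perpendicular": fraction,
            "n_contacting": n_contacting,
            "n_perpendicular_first": n_perp,
            "per_arg": pd.DataFrame(records),
            "angle_threshold": series.angle_threshold}


def run_length_encode(series: OrientationStateSeries) -> pd.DataFrame:
    """Run-length summary per Arg: (arg_label, state, t_start, t_end, dwell).

    Dwell times of perpendicular runs that precede a parallel run measure how
    long a side chain stays upright after touching down before flattening
    onto the surface.
    """
    rows = []
    t = series.times
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    for g, label in enumerate(series.arg_labels):
        col = series.states[:, g]
        start = 0
        for i in range(1, len(col) + 1):
            if i == len(col) or col[i] != col[start]:
                rows.append({"arg_label": label,
                             "state": STATE_NAMES[int(col[start])],
                             "t_start_ns": float(t[start]),
                             "t_end_ns": float(t[i - 1] + dt),
                             "dwell_ns": float(t[i - 1] + dt - t[start])})
                start = i
    return pd.DataFrame(rows)
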
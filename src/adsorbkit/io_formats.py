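"""Readers, writers and in-memory containers for the adsorption pipeline.

All downstream analyses consume only the types defined here.  The unit
convention is fixed once and for all at the reader boundary:

* lengths in **nm** (PDB and XYZ files, which carry Angstrom, are converted
  on read),
* times in **ns**,
* energies in **kJ/mol**.

Structure files (GRO, multi-model PDB) are parsed and written through
:mod:`mdtraj`, which natively works in nm; the XYZ dialect (plus an optional
TSV sidecar carrying residue metadata) is handled directly.  Energy tables
use the whitespace-delimited XVG dialect: ``#`` comment lines are skipped and
``@ s<k> legend "..."`` lines name the component columns.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Trajectory",
    "SurfaceModel",
    "EnergySeries",
    "AnalysisConfig",
    "ParseError",
    "StructureError",
    "read_structure",
    "write_structure",
    "read_energy_table",
    "write_results",
    "read_results",
]


class ParseError(ValueError):
    """A file record could not be interpreted in the stated dialect."""


class StructureError(ValueError):
    """Frames or metadata are mutually inconsistent (e.g. atom-count drift)."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom metadata for one molecular system.

    Atom ids are implicit 0-based positions.  File residue numbers are kept
    verbatim as labels (``residue_seq``) and never renumbered, so systems
    whose literature numbering starts deep into a sequence keep their
    published residue numbers.
    """

    atom_name: np.ndarray          # str, (n_atoms,)
    residue_name: np.ndarray       # str, (n_atoms,)
    residue_seq: np.ndarray        # int, (n_atoms,)
    chain_id: np.ndarray           # str, (n_atoms,)
    domain_id: np.ndarray | None = None   # optional str, (n_atoms,)
    element: np.ndarray | None = None     # optional str, (n_atoms,)
    radius: np.ndarray | None = None      # optional float nm, (n_atoms,)

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        n = len(self.atom_name)
        for arr, name in ((self.residue_name, "residue_name"),
                          (self.residue_seq, "residue_seq"),
                          (self.chain_id, "chain_id")):
            if len(arr) != n:
                raise StructureError(f"{name} length {len(arr)} != n_atoms {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_seq) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, s in zip(self.chain_id, self.residue_seq):
            seen.setdefault((c, int(s)), None)
        return list(seen)

    def residue_labels(self) -> list[str]:
        """Human-readable residue labels, e.g. ``A:ARG6``, in topology order."""
        labels = []
        first_name: dict[tuple[str, int], str] = {}
        for c, s, rn in zip(self.chain_id, self.residue_seq, self.residue_name):
            first_name.setdefault((c, int(s)), rn)
        for c, s in self.residue_keys():
            labels.append(f"{c}:{first_name[(c, s)]}{s}")
        return labels

    def residue_atom_indices(self) -> list[np.ndarray]:
        """Atom index arrays, one per residue, aligned with residue_keys()."""
        order = {k: i for i, k in enumerate(self.residue_keys())}
        buckets: list[list[int]] = [[] for _ in order]
        for i, (c, s) in enumerate(zip(self.chain_id, self.residue_seq)):
            buckets[order[(c, int(s))]].append(i)
        return [np.asarray(b, dtype=int) for b in buckets]

    def residue_types(self) -> list[str]:
        """Residue names per residue (caps like ACE/NAC included)."""
        first_name: dict[tuple[str, int], str] = {}
        for c, s, rn in zip(self.chain_id, self.residue_seq, self.residue_name):
            first_name.setdefault((c, int(s)), rn)
        return [first_name[k] for k in self.residue_keys()]


@dataclass
class Trajectory:
    """Frames x atoms x xyz coordinates (nm) with times (ns) and box (nm)."""

    times: np.ndarray              # (n_frames,) ns, strictly increasing
    coords: np.ndarray             # (n_frames, n_atoms, 3) nm
    box: np.ndarray | None = None  # (n_frames, 3) nm, orthorhombic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if len(self.times) != self.coords.shape[0]:
            raise StructureError("times length does not match number of frames")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if len(self.times) and self.times[0] < 0:
            raise StructureError("times must start at >= 0")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.coords.shape[0], 3):
                raise StructureError("box must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class SurfaceModel:
    """One or two ideal planes normal to z bounding the solvent slab (nm).

    The adsorbing surface is treated as a geometric plane: every criterion
    downstream is a pure distance-along-z threshold, so the metal lattice
    itself never needs to be read.  ``planes`` holds the z-coordinates of the
    plane(s); with two planes the solute is expected to live between them.
    """

    planes: Sequence[float]

    def __post_init__(self) -> None:
        planes = [float(p) for p in self.planes]
        if len(planes) not in (1, 2):
            raise ValueError("SurfaceModel takes one or two planes")
        if len(planes) == 2:
            if not planes[0] < planes[1]:
                raise ValueError("with two planes, plane_low < plane_high required")
        self.planes = planes

    @property
    def inter_plane_gap(self) -> float | None:
        if len(self.planes) == 2:
            return self.planes[1] - self.planes[0]
        return None


# canonical energy component keys
BONDED = "bonded_incl_14"
LJ = "lennard_jones"
COULOMB = "coulomb"


@dataclass
class EnergySeries:
    """Time-stamped energy components (kJ/mol) on an equally spaced grid.

    The bonded component is opaque: by convention it already folds in the
    intramolecular 1-4 Lennard-Jones and Coulomb terms, whose parameterization
    is entangled with the bonded force-field terms.  ``total`` always equals
    the sum of the components.
    """

    times: np.ndarray                        # ns
    components: dict[str, np.ndarray]        # kJ/mol
    total: np.ndarray | None = None
    sampling_interval: float | None = None   # ps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.components = {k: np.asarray(v, dtype=float) for k, v in self.components.items()}
        for k, v in self.components.items():
            if v.shape != self.times.shape:
                raise ValueError(f"component {k!r} length mismatch")
        csum = self.component_sum()
        if self.total is None:
            self.total = csum
        else:
            self.total = np.asarray(self.total, dtype=float)
            scale = max(1.0, float(np.abs(self.total).max(initial=0.0)))
            if np.abs(self.total - csum).max(initial=0.0) > 1e-6 * scale:
                raise ValueError("total does not equal the component sum (beyond 1e-6 rel.)")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be equally spaced")
            if self.sampling_interval is None:
                self.sampling_interval = float(dt[0] * 1e3)  # ns -> ps

    def component_sum(self) -> np.ndarray:
        out = np.zeros_like(self.times)
        for v in self.components.values():
            out = out + v
        return out

    def map(self, fn) -> "EnergySeries":
        """Apply ``fn(array) -> array`` to every component (total recomputed)."""
        return EnergySeries(
            times=self.times.copy(),
            components={k: fn(v) for k, v in self.components.items()},
            sampling_interval=self.sampling_interval,
        )


@dataclass
class AnalysisConfig:
    """Analysis thresholds and windows, all in the package unit convention.

    Defaults follow the standard criteria for adsorption analysis on flat
    gold: an atom touches the surface below 0.35 nm, a residue's first
    contact is counted below 0.3 nm of its closest atom, a side-chain bond
    is "parallel" below 30 degrees off the surface plane, and energy curves
    are baselined and smoothed over 1-ns windows.
    """

    contact_cutoff_atomic: float = 0.35   # nm
    contact_cutoff_residue: float = 0.30  # nm
    angle_threshold: float = 30.0         # degrees, alternative 45.0
    smooth_window: float = 1.0            # ns
    baseline_window: float = 1.0          # ns
    msd_fit_range: tuple[float, float] | None = None  # ns
    include_hydrogens: bool = True
    plateau_slope: float = 5.0            # contacts/ns, |slope| below -> plateau
    jump_slope: float = 50.0              # contacts/ns, slope above -> cooperative jump
    surface_z0: float | None = None       # recorded plane origin convention
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff_atomic", "contact_cutoff_residue",
                     "smooth_window", "baseline_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.angle_threshold < 90.0):
            raise ValueError("angle_threshold must lie in (0, 90) degrees")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("schema_version", None)
        if payload.get("msd_fit_range") is not None:
            payload["msd_fit_range"] = tuple(payload["msd_fit_range"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["schema_version"] = 1
        return d

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# structure files
# --------------------------------------------------------------------------

_DIALECTS = {"GRO", "PDB", "XYZ"}


def _infer_dialect(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("gro",):
        return "GRO"
    if ext in ("pdb", "ent"):
        return "PDB"
    if ext in ("xyz",):
        return "XYZ"
    raise ParseError(f"cannot infer structure dialect from {path.name!r}; pass dialect=")


def _from_mdtraj(traj) -> tuple[Topology, Trajectory]:
    top = traj.topology
    atom_name = [a.name for a in top.atoms]
    residue_name = [a.residue.name for a in top.atoms]
    residue_seq = [a.residue.resSeq for a in top.atoms]
    chain_id = [getattr(a.residue.chain, "chain_id", None) or chr(ord("A") + a.residue.chain.index % 26)
                for a in top.atoms]
    element = [a.element.symbol if a.element is not None else "" for a in top.atoms]
    topo = Topology(atom_name, residue_name, residue_seq, chain_id,
                    element=np.asarray(element, dtype=object))
    times = np.asarray(traj.time, dtype=float) / 1e3  # mdtraj ps -> ns
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(times), dtype=float)  # PDB MODELs carry no times
    box = traj.unitcell_lengths
    trj = Trajectory(times=times, coords=np.asarray(traj.xyz, dtype=float),
                     box=None if box is None else np.asarray(box, dtype=float))
    return topo, trj


def _read_xyz(path: Path) -> tuple[Topology, Trajectory]:
    # XYZ frames: natoms / comment / element x y z (Angstrom). A sidecar TSV
    # at <path>.residues.tsv may supply residue metadata; otherwise each atom
    # becomes its own UNK residue.
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    lines = path.read_text().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path.name} line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + nat >= len(lines) + 1 and len(lines) - i - 2 < nat:
            raise StructureError(f"{path.name}: frame starting at line {i + 1} truncated "
                                 f"({len(lines) - i - 2} of {nat} atom records)")
        block = lines[i + 2:i + 2 + nat]
        elems, xyz = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path.name} line {i + 3 + j}: malformed XYZ record {ln!r}")
            try:
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ParseError(f"{path.name} line {i + 3 + j}: non-numeric coordinate in {ln!r}") from exc
            elems.append(parts[0])
        if elements is None:
            elements = elems
        elif len(elems) != len(elements):
            raise StructureError(f"{path.name}: frame {len(frames) + 1} has {len(elems)} atoms, "
                                 f"expected {len(elements)}")
        frames.append(np.asarray(xyz) * 0.1)  # Angstrom -> nm
        i += 2 + nat
        lineno = i
    del lineno
    if not frames:
        raise ParseError(f"{path.name}: no frames found")
    assert elements is not None
    n = len(elements)
    sidecar = path.with_name(path.name + ".residues.tsv")
    if sidecar.exists():
        tab = pd.read_csv(sidecar, sep="\t")
        required = {"atom_name", "residue_name", "residue_seq", "chain_id"}
        if not required.issubset(tab.columns):
            raise ParseError(f"{sidecar.name}: missing columns {sorted(required - set(tab.columns))}")
        if len(tab) != n:
            raise StructureError(f"{sidecar.name}: {len(tab)} rows for {n} atoms")
        topo = Topology(tab["atom_name"].astype(str).to_numpy(),
                        tab["residue_name"].astype(str).to_numpy(),
                        tab["residue_seq"].to_numpy(),
                        tab["chain_id"].astype(str).to_numpy(),
                        element=np.asarray(elements, dtype=object))
    else:
        topo = Topology(np.asarray(elements, dtype=object),
                        np.asarray(["UNK"] * n, dtype=object),
                        np.arange(1, n + 1),
                        np.asarray(["A"] * n, dtype=object),
                        element=np.asarray(elements, dtype=object))
    trj = Trajectory(times=np.arange(len(frames), dtype=float),
                     coords=np.stack(frames))
    return topo, trj


def read_structure(path: str | Path, dialect: str | None = None) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-frame) structure file into package containers.

    Coordinates come back in nm regardless of the on-disk convention; GRO and
    multi-model PDB go through mdtraj, XYZ is parsed directly (with optional
    ``<file>.residues.tsv`` sidecar metadata).
    """
    import mdtraj as md

    path = Path(path)
    dialect = (dialect or _infer_dialect(path)).upper()
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "XYZ":
        return _read_xyz(path)
    try:
        traj = md.load(str(path))
    except Exception as exc:  # mdtraj raises heterogeneous exception types
        msg = str(exc)
        if re.search(r"atom|shape|broadcast|mismatch|number", msg, re.IGNORECASE):
            raise StructureError(f"{path.name}: inconsistent frames ({msg})") from exc
        raise ParseError(f"{path.name}: cannot parse as {dialect} ({msg})") from exc
    return _from_mdtraj(traj)


def write_structure(path: str | Path, topology: Topology, trajectory: Trajectory,
                    dialect: str | None = None) -> Path:
    """Write a Trajectory to GRO or PDB (multi-frame) via mdtraj."""
    import mdtraj as md

    path = Path(path)
    dialect = (dialect or _infer_dialect(path)).upper()
    if dialect == "XYZ":
        raise ValueError("XYZ writing is not supported; use GRO or PDB")
    top = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[tuple[str, int], object] = {}
    for i in range(topology.n_atoms):
        cid = topology.chain_id[i]
        if cid not in chains:
            chains[cid] = top.add_chain()
        key = (cid, int(topology.residue_seq[i]))
        if key not in residues:
            residues[key] = top.add_residue(topology.residue_name[i], chains[cid],
                                            resSeq=int(topology.residue_seq[i]))
        sym = topology.element[i] if topology.element is not None else ""
        try:
            elem = md.element.get_by_symbol(sym) if sym else md.element.carbon
        except KeyError:
            elem = md.element.carbon
        top.add_atom(topology.atom_name[i], elem, residues[key])
    n_frames = trajectory.n_frames
    box = trajectory.box
    if box is None:
        span = np.abs(trajectory.coords).max() * 2 + 1.0
        box = np.full((n_frames, 3), span)
    traj = md.Trajectory(trajectory.coords, top,
                         time=trajectory.times * 1e3,  # ns -> ps
                         unitcell_lengths=box,
                         unitcell_angles=np.full((n_frames, 3), 90.0))
    traj.save(str(path))
    return path


# --------------------------------------------------------------------------
# energy tables (XVG dialect)
# --------------------------------------------------------------------------

_COMPONENT_ALIASES = {
    BONDED: ("bond", "bonded", "bonded_incl_14"),
    LJ: ("lj", "lennard", "vdw", "lennard_jones"),
    COULOMB: ("coul", "coulomb", "electro"),
}


def _canonical_component(name: str) -> str:
    low = name.strip().lower().replace("-", "_").replace(" ", "_")
    for canon, keys in _COMPONENT_ALIASES.items():
        if any(k in low for k in keys):
            return canon
    return low


def read_energy_table(path: str | Path, column_names: Sequence[str] | None = None,
                      time_unit: str = "ns") -> EnergySeries:
    """Read an XVG-style whitespace table of energy components.

    ``#`` and ``@`` lines are comments; ``@ s<k> legend "name"`` lines, when
    present, name the data columns after the leading time column.  Column
    names are mapped onto the canonical component keys (bonded_incl_14,
    lennard_jones, coulomb) by substring match; a ``total`` column, if
    present, is validated against the component sum, otherwise the total is
    computed.  ``time_unit`` ("ns" or "ps") states the unit of column 0.
    """
    path = Path(path)
    legends: dict[int, str] = {}
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                m = re.match(r'@\s*s(\d+)\s+legend\s+"(.*)"', line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                continue
            parts = line.split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ParseError(f"{path.name} row at line {lineno}: expected {width} "
                                 f"columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                bad = next(p for p in parts if not _is_float(p))
                raise ParseError(f"{path.name} row at line {lineno}: non-numeric cell {bad!r}")
    if not rows:
        raise ParseError(f"{path.name}: no data rows")
    data = np.asarray(rows, dtype=float)
    times = data[:, 0] * (1e-3 if time_unit == "ps" else 1.0)
    ncomp = data.shape[1] - 1
    if column_names is not None:
        if len(column_names) != ncomp:
            raise ParseError(f"{path.name}: {len(column_names)} column names for {ncomp} columns")
        names = list(column_names)
    elif legends:
        names = [legends.get(i, f"component_{i}") for i in range(ncomp)]
    else:
        names = [f"component_{i}" for i in range(ncomp)]
    comps: dict[str, np.ndarray] = {}
    total = None
    for j, name in enumerate(names):
        canon = _canonical_component(name)
        if canon in ("total", "potential"):
            total = data[:, j + 1]
        else:
            comps[canon] = data[:, j + 1]
    return EnergySeries(times=times, components=comps, total=total)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# --------------------------------------------------------------------------
# result tables
# --------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
                  path: str | Path, format: str | None = None) -> Path:
    """Write result tables as TSV (single table) or JSON (one or many).

    TSV carries a header row and full float precision (repr round-trip).
    JSON stores ``{table_name: {column: [values...]}}`` and round-trips
    losslessly through :func:`read_results`.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if isinstance(tables, pd.DataFrame):
        tables = {"table": tables}
    if fmt == "TSV":
        if len(tables) != 1:
            raise ValueError("TSV output holds exactly one table; use JSON for bundles")
        (name, tab), = tables.items()
        tab.to_csv(path, sep="\t", index=False, float_format=None)
        return path
    if fmt == "JSON":
        payload = {name: {col: tab[col].tolist() for col in tab.columns}
                   for name, tab in tables.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path
    raise ValueError(f"unknown results format {fmt!r} (TSV or JSON)")


def read_results(path: str | Path) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`write_results` for the JSON layout (TSV via pandas)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        return {name: pd.DataFrame(cols) for name, cols in payload.items()}
    return {"table": pd.read_csv(path, sep="\t")}
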
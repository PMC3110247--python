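"""Domain-resolved structural metrics for a two-domain protein.

A multidomain protein can keep each domain's internal fold intact while the
domains reorient relative to each other on the surface.  Per-domain Calpha
RMSD (each domain superposed onto itself) then stays flat while the
whole-protein RMSD (one superposition over all Calpha) steps up at each
reorientation event.  The relative geometry of two binding sites is tracked
as a four-point dihedral: site-1 centroid, two anchor residues, site-2
centroid, all on Calpha positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from .geometry import dihedral, kabsch_superpose
from .io_formats import Topology, Trajectory

__all__ = [
    "DomainDefinition",
    "DihedralDistribution",
    "domain_rmsd_series",
    "binding_site_dihedral_series",
    "compare_distributions",
]


@dataclass
class DomainDefinition:
    """Residue-label bookkeeping for domains and binding-site groups.

    ``domains`` maps a domain id to the residue labels it owns (labels as
    produced by :meth:`Topology.residue_labels`, e.g. ``"A:ARG6"``).  The
    binding-site dihedral needs four point groups: the primary site residues
    (e.g. an RGD loop), two single anchor residues, and the secondary
    (synergy) site residues.  The anchors are a modelling choice and must be
    stated explicitly — results depend on them.
    """

    domains: dict[str, list[str]]
    primary_site: list[str] = field(default_factory=list)
    synergy_site: list[str] = field(default_factory=list)
    anchors: list[str] = field(default_factory=list)  # exactly two residue labels

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for did, labels in self.domains.items():
            dup = seen.intersection(labels)
            if dup:
                raise ValueError(f"domains overlap on residues {sorted(dup)}")
            seen.update(labels)
        if self.anchors and len(self.anchors) != 2:
            raise ValueError("exactly two anchor residues are required")

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainDefinition":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"domains": self.domains, "primary_site": self.primary_site,
                       "synergy_site": self.synergy_site, "anchors": self.anchors},
                      fh, indent=1)


@dataclass
class DihedralDistribution:
    """Circular sample summary of a dihedral series (degrees)."""

    samples: np.ndarray
    circular_mean: float
    circular_std: float

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "DihedralDistribution":
        s = np.asarray(samples, dtype=float)
        s = ((s + 180.0) % 360.0) - 180.0
        s = np.where(s <= -180.0, 180.0, s)
        return cls(samples=s,
                   circular_mean=float(circmean(s, high=180.0, low=-180.0)),
                   circular_std=float(circstd(s, high=180.0, low=-180.0)))


def _ca_indices(topology: Topology, labels: list[str]) -> np.ndarray:
    by_label = {lab: idx for lab, idx in
                zip(topology.residue_labels(), topology.residue_atom_indices())}
    out = []
    for lab in labels:
        if lab not in by_label:
            raise ValueError(f"residue {lab} not present in topology")
        idx = by_label[lab]
        ca = [i for i in idx if str(topology.atom_name[i]) == "CA"]
        if not ca:
            raise ValueError(f"residue {lab} has no CA atom")
        out.append(ca[0])
    return np.asarray(out, dtype=int)


def domain_rmsd_series(trajectory: Trajectory, topology: Topology,
                       domains: DomainDefinition,
                       reference_frame: int = 0) -> pd.DataFrame:
    """Per-domain and whole-protein Calpha RMSD versus time.

    Each series comes from an independent least-squares superposition onto
    the reference frame: the domain fit for the per-domain series and a fit
    over every domain's Calpha for the whole-protein series, equal weights.
    The reference defaults to the first frame (the relaxed start structure).
    """
    if not (0 <= reference_frame < trajectory.n_frames):
        raise ValueError("reference frame out of range")
    sels = {did: _ca_indices(topology, labels) for did, labels in domains.domains.items()}
    for did, sel in sels.items():
        if len(sel) < 3:
            raise ValueError(f"domain {did} has fewer than 3 Calpha atoms")
    all_sel = np.concatenate(list(sels.values()))
    ref = trajectory.coords[reference_frame]
    out = {"time_ns": trajectory.times}
    for did, sel in {**sels, "whole": all_sel}.items():
        key = f"rmsd_{did}_nm" if did != "whole" else "rmsd_whole_nm"
        out[key] = np.array([kabsch_superpose(trajectory.coords[f][sel], ref[sel]).rmsd
                             for f in range(trajectory.n_frames)])
    return pd.DataFrame(out)


def binding_site_dihedral_series(trajectory: Trajectory, topology: Topology,
                                 domains: DomainDefinition) -> np.ndarray:
    """Four-point binding-site dihedral (degrees) per frame.

    p1 = Calpha centroid of the primary site, p2/p3 = the two anchor
    residues' Calpha, p4 = Calpha centroid of the synergy site.  Invariant
    under rigid motion of the whole structure, so it isolates internal
    (inter-domain) reorientation.
    """
    if not (domains.primary_site and domains.synergy_site and domains.anchors):
        raise ValueError("primary_site, synergy_site and two anchors are all required")
    p1_idx = _ca_indices(topology, domains.primary_site)
    p4_idx = _ca_indices(topology, domains.synergy_site)
    a_idx = _ca_indices(topology, domains.anchors)
    c = trajectory.coords
    p1 = c[:, p1_idx, :].mean(axis=1)
    p2 = c[:, a_idx[0], :]
    p3 = c[:, a_idx[1], :]
    p4 = c[:, p4_idx, :].mean(axis=1)
    return dihedral(p1, p2, p3, p4)


def compare_distributions(free: DihedralDistribution | np.ndarray,
                          adsorbed: DihedralDistribution | np.ndarray,
                          min_samples: int = 50) -> dict:
    """Width ratio and circular mean shift between two dihedral ensembles.

    ``width_ratio = circ_std(adsorbed) / circ_std(free)`` (< 1 means the
    distribution narrowed after adsorption); the shift is the signed minimal
    difference of circular means on the circle, in (-180, 180].
    """
    if not isinstance(free, DihedralDistribution):
        free = DihedralDistribution.from_samples(free)
    if not isinstance(adsorbed, DihedralDistribution):
        adsorbed = DihedralDistribution.from_samples(adsorbed)
    for name, d in (("free", free), ("adsorbed", adsorbed)):
        if len(d.samples) < min_samples:
            raise ValueError(f"{name} distribution has fewer than {min_samples} samples")
    if free.circular_std == 0:
        ratio = np.inf if adsorbed.circular_std > 0 else 1.0
    else:
        ratio = adsorbed.circular_std / free.circular_std
    shift = adsorbed.circular_mean - free.circular_mean
    shift = ((shift + 180.0) % 360.0) - 180.0
    if shift == -180.0:
        shift = 180.0
    return {"width_ratio": float(ratio),
            "circular_mean_shift": float(shift),
            "narrowing": bool(ratio < 1.0)}
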
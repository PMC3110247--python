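"""Geometric primitives shared by every analysis stage.

The adsorbing surface is an ideal plane normal to z, so "distance to the
surface" is always a |z - z0| computation (min over two planes in slab
setups).  There is no minimum-image handling in z: the slab geometry makes
x,y periodicity irrelevant to every metric defined here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import SurfaceModel, Topology

__all__ = [
    "DeltaZ",
    "SuperpositionResult",
    "delta_z",
    "bond_plane_angle",
    "dihedral",
    "kabsch_superpose",
    "sphere_points",
    "sasa",
    "vdw_radii",
    "residue_type_sasa_fraction",
]


@dataclass
class DeltaZ:
    """Per-atom distance to the nearest surface plane (nm)."""

    value: np.ndarray          # >= 0, nm
    nearest_plane: np.ndarray  # plane index, 0 or 1
    outside_slab: np.ndarray   # True where an atom escapes a two-plane slab


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of a mobile onto a reference point set."""

    rmsd: float                # nm
    rotation: np.ndarray       # 3x3 proper orthogonal (det +1)
    translation: np.ndarray    # nm; x_aligned = (x - mobile_mean) @ R.T + translation


def delta_z(coords: np.ndarray, surface: SurfaceModel) -> DeltaZ:
    """Distance along z from each atom to the nearest surface plane.

    ``coords`` may be (..., 3); the result arrays share the leading shape.
    With two planes the minimum of the two distances is taken and atoms
    lying outside the slab are flagged (never silently clipped).
    """
    coords = np.asarray(coords, dtype=float)
    z = coords[..., 2]
    planes = np.asarray(surface.planes, dtype=float)
    dists = np.abs(z[..., None] - planes)  # (..., n_planes)
    nearest = np.argmin(dists, axis=-1)
    value = np.min(dists, axis=-1)
    if len(planes) == 2:
        outside = (z < planes[0]) | (z > planes[1])
    else:
        outside = np.zeros_like(z, dtype=bool)
    return DeltaZ(value=value, nearest_plane=nearest, outside_slab=outside)


def bond_plane_angle(bond_vector: np.ndarray, surface: SurfaceModel | None = None) -> np.ndarray:
    """Angle in degrees, in [0, 90], between bond vector(s) and the surface plane.

    This is the complement of the angle to the surface normal (+z), folded so
    the sign of the vector is irrelevant: an in-plane bond scores 0 degrees
    and a bond along the normal scores 90.  Accepts (..., 3) input.
    """
    v = np.asarray(bond_vector, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm == 0):
        raise ValueError("zero-length bond vector has no angle to the plane")
    sin_elev = np.abs(v[..., 2]) / norm
    ang = np.degrees(np.arcsin(np.clip(sin_elev, 0.0, 1.0)))
    return ang if ang.ndim else float(ang)


def dihedral(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Standard IUPAC sign convention (looking down p2->p3, positive for a
    clockwise rotation of p4 relative to p1).  Inputs may be (..., 3) stacks;
    the result is invariant under any rigid motion applied to all four
    points.  Raises if the central axis or a flanking bond is degenerate.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(b2n == 0) or np.any(np.linalg.norm(n1, axis=-1) == 0) \
            or np.any(np.linalg.norm(n2, axis=-1) == 0):
        raise ValueError("degenerate dihedral: collinear or coincident points")
    m1 = np.cross(b2 / b2n[..., None], n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang if ang.ndim else float(ang)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition (rotation + translation) via SVD.

    Reflections are excluded: the returned rotation is proper (det +1).  The
    RMSD is the global minimum over all rigid transforms of the selected
    points, equal weights.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        mobile = mobile[selection]
        reference = reference[selection]
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for superposition")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    A = mobile - mu_m
    B = reference - mu_r
    if np.linalg.matrix_rank(A) < 2 and np.linalg.matrix_rank(B) < 2:
        raise ValueError("rank-deficient point sets (collinear or coincident)")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = A @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - B) ** 2, axis=1))))
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=mu_r)


# --------------------------------------------------------------------------
# solvent accessible surface area (Shrake-Rupley)
# --------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-section spiral).

    The same ``n`` always yields bit-identical points, making SASA values
    exactly reproducible across runs and machines.
    """
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(coords: np.ndarray, radii: np.ndarray, probe_radius: float = 0.14,
         n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (nm^2), Shrake-Rupley.

    Each atom's accessible sphere (radius + probe) is sampled on a
    deterministic spiral lattice; a point survives if it lies outside every
    neighbour's accessible sphere.  ``total = result.sum()``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must be (n_atoms,)")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100 for a usable estimate")
    n = coords.shape[0]
    big = radii + probe_radius
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0 * big.max(), output_type="ndarray")
    neighbours: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d == 0.0:
            raise ValueError(f"atoms {i} and {j} have identical centers")
        if d < big[i] + big[j]:
            neighbours[i].append(j)
            neighbours[j].append(i)
    unit = sphere_points(n_sphere_points)
    out = np.empty(n, dtype=float)
    for i in range(n):
        pts = coords[i] + big[i] * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours[i]:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > big[j] ** 2
            if not exposed.any():
                break
        out[i] = 4.0 * np.pi * big[i] ** 2 * exposed.mean()
    return out


# van-der-Waals radii (nm) by element symbol; fallback 0.17 (carbon-like)
_VDW_NM = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
           "P": 0.180, "F": 0.147, "CL": 0.175, "BR": 0.185, "I": 0.198}


def vdw_radii(topology: Topology) -> np.ndarray:
    """Per-atom van-der-Waals radii (nm) from element symbols or atom names."""
    if topology.radius is not None:
        return np.asarray(topology.radius, dtype=float)
    out = np.empty(topology.n_atoms, dtype=float)
    for i in range(topology.n_atoms):
        sym = ""
        if topology.element is not None and topology.element[i]:
            sym = str(topology.element[i]).upper()
        else:
            name = str(topology.atom_name[i]).strip()
            sym = "".join(ch for ch in name if ch.isalpha())[:1].upper()
        out[i] = _VDW_NM.get(sym, _VDW_NM.get(sym[:1], 0.170))
    return out


def residue_type_sasa_fraction(topology: Topology, coords: np.ndarray,
                               residue_type: str = "ARG",
                               probe_radius: float = 0.14,
                               n_sphere_points: int = 960) -> float:
    """Fraction of the total SASA contributed by one residue type.

    Used e.g. to ask what share of a protein's accessible surface the
    arginines expose to the solvent (and hence to an approaching surface).
    """
    areas = sasa(np.asarray(coords, dtype=float), vdw_radii(topology),
                 probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    mask = np.array([rn == residue_type for rn in topology.residue_name], dtype=bool)
    total = areas.sum()
    if total == 0:
        raise ValueError("zero total surface area")
    return float(areas[mask].sum() / total)
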
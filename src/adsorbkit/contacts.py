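"""Contact kinetics between a polypeptide and a flat surface.

Covers the per-frame atomic contact count, per-residue minimum-distance maps
(with the inverse-distance normalization used for residue-resolved adsorption
maps), first-contact tables and their residue-type aggregation, and the
segmentation of the contact-number curve into adsorption phases (approach,
gradual increase, plateau, cooperative jump).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import centered_moving_average
from .geometry import delta_z
from .io_formats import AnalysisConfig, SurfaceModel, Topology, Trajectory

__all__ = [
    "ContactSeries",
    "PhaseSegmentation",
    "atomic_contact_count",
    "residue_min_dz_map",
    "first_contact_times",
    "aggregate_first_contact_by_type",
    "detect_adsorption_phases",
]

PHASE_LABELS = ("approach", "gradual_increase", "plateau", "cooperative_jump")


@dataclass
class ContactSeries:
    """Per-frame atomic contact counts and per-residue minimum distances."""

    times: np.ndarray                   # ns, (n_frames,)
    atomic_contacts: np.ndarray         # int counts, (n_frames,)
    per_residue_min_dz: np.ndarray | None = None  # nm, (n_frames, n_residues)
    residue_labels: list[str] | None = None
    cutoff: float | None = None         # nm used for the counts


@dataclass
class PhaseSegmentation:
    """Changepoints (ns) of the contact curve with a label per segment."""

    boundaries: list[float]             # interior changepoints, strictly increasing
    labels: list[str]                   # len == len(boundaries) + 1
    slopes: list[float] = field(default_factory=list)  # contacts/ns per segment

    def segments(self, t_start: float, t_end: float) -> list[tuple[float, float, str]]:
        edges = [t_start, *self.boundaries, t_end]
        return [(edges[i], edges[i + 1], self.labels[i]) for i in range(len(self.labels))]


def atomic_contact_count(trajectory: Trajectory, surface: SurfaceModel,
                         cutoff: float = 0.35,
                         atom_subset: np.ndarray | None = None) -> ContactSeries:
    """Count, per frame, the atoms strictly within ``cutoff`` of the surface.

    The contact criterion is the strict inequality dz < cutoff; an atom
    sitting exactly at the cutoff does not count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    coords = trajectory.coords
    if atom_subset is not None:
        atom_subset = np.asarray(atom_subset)
        if atom_subset.size == 0:
            raise ValueError("empty atom subset")
        coords = coords[:, atom_subset, :]
    dz = delta_z(coords, surface).value  # (frames, atoms)
    counts = np.count_nonzero(dz < cutoff, axis=1)
    return ContactSeries(times=trajectory.times, atomic_contacts=counts, cutoff=cutoff)


def residue_min_dz_map(trajectory: Trajectory, topology: Topology,
                       surface: SurfaceModel,
                       dz_ref: float | None = None) -> dict:
    """Per-frame, per-residue minimum atom distance and its normalized map.

    The normalized value is ``v(t, r) = clip(dz_ref / min_dz(t, r), 0, 1)``
    with ``dz_ref`` defaulting to the global minimum distance observed over
    the whole trajectory and all residues: v = 1 at the closest approach ever
    seen, v -> 0 as a residue recedes to infinity.  ``dz_ref`` is returned so
    reports can record the normalization actually used.
    """
    dz = delta_z(trajectory.coords, surface).value  # (frames, atoms)
    groups = topology.residue_atom_indices()
    n_frames = trajectory.n_frames
    out = np.empty((n_frames, len(groups)), dtype=float)
    for j, idx in enumerate(groups):
        out[:, j] = dz[:, idx].min(axis=1)
    ref = float(out.min()) if dz_ref is None else float(dz_ref)
    with np.errstate(divide="ignore"):
        norm = np.clip(ref / out, 0.0, 1.0)
    return {"min_dz": out, "normalized": norm, "dz_ref": ref,
            "residue_labels": topology.residue_labels(),
            "times": trajectory.times}


def first_contact_times(trajectory: Trajectory, topology: Topology,
                        surface: SurfaceModel, cutoff: float = 0.30,
                        sim_id: str = "sim") -> pd.DataFrame:
    """Earliest time each residue's closest atom comes within ``cutoff``.

    Returns a table with one row per residue: ``residue_label``,
    ``residue_type``, ``sim_id`` and ``t_first_ns`` (NaN when the criterion
    is never met).  The contact criterion is strict (dz < cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    res = residue_min_dz_map(trajectory, topology, surface)
    min_dz = res["min_dz"]
    hit = min_dz < cutoff
    rows = []
    types = topology.residue_types()
    for j, label in enumerate(res["residue_labels"]):
        frames = np.nonzero(hit[:, j])[0]
        t_first = float(trajectory.times[frames[0]]) if frames.size else np.nan
        rows.append({"residue_label": label, "residue_type": types[j],
                     "sim_id": sim_id, "t_first_ns": t_first})
    return pd.DataFrame(rows)


def aggregate_first_contact_by_type(tables: list[pd.DataFrame] | pd.DataFrame,
                                    cell_statistic: str = "min") -> dict:
    """Residue-type x simulation matrix of first-contact times, with averages.

    The cell for (type, sim) is the earliest first contact among residues of
    that type in that simulation (``cell_statistic="min"``; ``"mean"``
    averages over the residues instead).  Cells where no residue of the type
    ever contacted are absent (NaN) and excluded from the per-type mean; a
    type absent everywhere gets an absent mean.  The per-simulation minimum
    cell is flagged, mirroring the usual bold-facing of the fastest residue
    type per run.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise ValueError("need at least one first-contact table")
    if cell_statistic not in ("min", "mean"):
        raise ValueError("cell_statistic must be 'min' or 'mean'")
    long = pd.concat(tables, ignore_index=True)
    agg = getattr(long.groupby(["residue_type", "sim_id"])["t_first_ns"], cell_statistic)()
    matrix = agg.unstack("sim_id")
    sim_order: list[str] = []
    for tab in tables:
        for s in tab["sim_id"].unique():
            if s not in sim_order:
                sim_order.append(s)
    matrix = matrix.reindex(columns=sim_order)
    means = matrix.mean(axis=1, skipna=True)
    is_min = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for sim in matrix.columns:
        col = matrix[sim]
        if col.notna().any():
            is_min.loc[col.idxmin(), sim] = True
    return {"matrix": matrix, "mean": means, "is_column_min": is_min}


# --------------------------------------------------------------------------
# adsorption-phase segmentation
# --------------------------------------------------------------------------

def _segment_cost_factory(x: np.ndarray, y: np.ndarray):
    """O(1) least-squares line SSE for any [i, j) segment, via prefix sums."""
    z = np.concatenate([[0.0], np.cumsum(x)])
    zy = np.concatenate([[0.0], np.cumsum(y)])
    zxx = np.concatenate([[0.0], np.cumsum(x * x)])
    zxy = np.concatenate([[0.0], np.cumsum(x * y)])
    zyy = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(i, j):
        # vectorized over arrays i, j of equal shape; segments [i, j)
        n = (j - i).astype(float) if hasattr(j - i, "astype") else float(j - i)
        sx = z[j] - z[i]
        sy = zy[j] - zy[i]
        sxx = zxx[j] - zxx[i]
        sxy = zxy[j] - zxy[i]
        syy = zyy[j] - zyy[i]
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = syy_c - np.where(sxx_c > 1e-300, sxy_c * sxy_c / np.maximum(sxx_c, 1e-300), 0.0)
        return np.maximum(sse, 0.0)

    return cost


def _optimal_partition(x: np.ndarray, y: np.ndarray, beta: float,
                       sigma2: float, min_len: int) -> list[int]:
    """Optimal changepoint partition (dynamic programming, BIC-style penalty).

    Minimizes sum_k SSE_k / sigma2 + beta * (#segments); returns the interior
    breakpoint indices.
    """
    n = len(y)
    cost = _segment_cost_factory(x, y)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_len, n + 1):
        i = np.arange(0, j - min_len + 1)
        c = F[i] + cost(i, np.full_like(i, j)) / sigma2 + beta
        k = int(np.argmin(c))
        F[j] = c[k]
        prev[j] = i[k]
    cuts = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cuts.append(i)
        j = i
    return sorted(cuts)


def _refine_boundary(x: np.ndarray, y: np.ndarray, lo: int, b: int, hi: int,
                     radius: int, min_len: int) -> int:
    """Slide a boundary within +-radius to minimize the two-line SSE."""
    cost = _segment_cost_factory(x, y)
    best_b, best_c = b, np.inf
    for k in range(max(lo + min_len, b - radius), min(hi - min_len, b + radius) + 1):
        c = float(cost(np.array([lo]), np.array([k]))[0]
                  + cost(np.array([k]), np.array([hi]))[0])
        if c < best_c:
            best_b, best_c = k, c
    return best_b


def detect_adsorption_phases(atomic_contacts: np.ndarray, times: np.ndarray,
                             config: AnalysisConfig | None = None,
                             penalty: float = 12.0) -> PhaseSegmentation:
    """Segment a contact-number curve into adsorption phases.

    The series is smoothed with a centered window (``config.smooth_window``,
    default 1 ns), segmented by a piecewise-linear changepoint fit (optimal
    partitioning with a BIC-style penalty ``penalty * log(n)``, noise scale
    estimated robustly from first differences of the raw series), and each
    segment is labeled by its slope class: pre-first-contact segments are
    ``approach``, |slope| <= ``plateau_slope`` is ``plateau``, slope >=
    ``jump_slope`` is ``cooperative_jump``, anything else
    ``gradual_increase``.  A constant series yields one plateau segment.
    """
    config = config or AnalysisConfig()
    y_raw = np.asarray(atomic_contacts, dtype=float)
    t = np.asarray(times, dtype=float)
    if y_raw.shape != t.shape or y_raw.ndim != 1:
        raise ValueError("atomic_contacts and times must be matching 1-D arrays")
    n = len(y_raw)
    if n < 4:
        return PhaseSegmentation(boundaries=[], labels=[_label_segment(
            t, y_raw, 0, n, config, leading=False)],
            slopes=[_slope(t, y_raw, 0, n)])
    dt = t[1] - t[0]
    w = max(1, int(round(config.smooth_window / dt)))
    y = centered_moving_average(y_raw, w)

    # robust noise scale of the smoothed series
    d = np.diff(y_raw)
    mad = np.median(np.abs(d - np.median(d)))
    sigma2_raw = (1.4826 * mad) ** 2 / 2.0
    sigma2 = sigma2_raw / w
    sigma2 = max(sigma2, 1e-10 * max(float(np.var(y)), 1.0))

    # coarse grid keeps the DP cheap and the decimated noise near-independent;
    # the edge-shrunken smoothing region is excluded so truncated windows
    # cannot fake changepoints near t=0 / t=end
    stride = max(1, w // 2)
    half = w // 2 if n - w > 8 else 0
    ys = y[half:n - half or None:stride]
    xs = t[half:n - half or None:stride]
    m = len(ys)
    min_len_dec = 2
    beta = penalty * np.log(m)
    cuts_dec = _optimal_partition(xs, ys, beta=beta, sigma2=sigma2, min_len=min_len_dec)
    cuts = [half + c * stride for c in cuts_dec]

    # a slope knot smeared by the smoothing window shows up as a short blend
    # that the piecewise-linear fit may cut twice; merge cuts closer than the
    # window into their midpoint, then localize each boundary on the raw
    # series (exact for noise-free input)
    merged: list[int] = []
    group: list[int] = []
    for c in cuts + [10 * n]:
        if group and c - group[0] > int(1.5 * w):
            merged.append(int(round(np.mean(group))))
            group = []
        if c < 10 * n:
            group.append(c)
    edges = [0, *merged, n]
    refined: list[int] = []
    for k in range(1, len(edges) - 1):
        lo = max(edges[k - 1], refined[-1]) if refined else edges[k - 1]
        refined.append(_refine_boundary(t, y_raw, lo, edges[k], edges[k + 1],
                                        radius=max(stride, w // 2), min_len=2))
    refined = sorted(set(refined))

    edges = [0, *refined, n]
    labels, slopes = [], []
    leading = len(edges) > 2  # a lone segment is never "approach" (constant -> plateau)
    for k in range(len(edges) - 1):
        lab = _label_segment(t, y, edges[k], edges[k + 1], config, leading=leading)
        leading = leading and lab == "approach"
        labels.append(lab)
        slopes.append(_slope(t, y, edges[k], edges[k + 1]))
    return PhaseSegmentation(boundaries=[float(t[i]) for i in refined],
                             labels=labels, slopes=slopes)


def _slope(t, y, i, j) -> float:
    if j - i < 2:
        return 0.0
    A = np.polyfit(t[i:j], y[i:j], 1)
    return float(A[0])


def _label_segment(t, y, i, j, config: AnalysisConfig, leading: bool) -> str:
    # "approach" = pre-contact: a leading segment whose level is negligible
    # against the eventual contact numbers (noise in a count series is
    # clipped at zero, so the pre-contact baseline is small but not zero)
    if leading and np.mean(y[i:j]) < 0.05 * max(float(y.max()), 1e-12):
        return "approach"
    s = _slope(t, y, i, j)
    if s >= config.jump_slope:
        return "cooperative_jump"
    if abs(s) <= config.plateau_slope:
        return "plateau"
    return "gradual_increase"
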
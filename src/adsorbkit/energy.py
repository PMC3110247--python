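"""Adsorption-energy processing.

Raw component energies (bonded incl. 1-4 terms, Lennard-Jones, Coulomb) are
turned into time-dependent adsorption energies by subtracting, per component,
the mean over the first nanosecond of the run — the pre-contact baseline —
and smoothing with a 1-ns window centered on every sample.  No entropic term
is estimated anywhere: the curves are potential-energy differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import EnergySeries

__all__ = [
    "centered_moving_average",
    "baseline_adsorption_energy",
    "smooth_centered",
    "component_decomposition_report",
    "contact_energy_correlation",
    "CorrelationResult",
]


def centered_moving_average(y: np.ndarray, n_window: int) -> np.ndarray:
    """Centered moving average with truncated (shrinking) edge windows.

    Interior points average exactly the ``n_window`` samples centered on them
    (``n_window`` forced odd by adding one when even); near the edges the
    window shrinks instead of padding, so no data is fabricated at t=0 and
    the output has the input's length.
    """
    y = np.asarray(y, dtype=float)
    if n_window < 1:
        raise ValueError("window must span at least one sample")
    half = n_window // 2
    csum = np.concatenate([[0.0], np.cumsum(y)])
    idx = np.arange(len(y))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, len(y) - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _window_samples(series: EnergySeries, window_ns: float) -> int:
    if len(series.times) < 2:
        return 1
    dt = series.times[1] - series.times[0]
    n = int(round(window_ns / dt))
    return max(n, 1)


def baseline_adsorption_energy(series: EnergySeries,
                               baseline_window: float = 1.0) -> EnergySeries:
    """Subtract the pre-contact baseline from every component.

    Each component (and hence the total) is shifted by its own mean over
    ``[t0, t0 + baseline_window)``; afterwards each component averages to
    zero over the baseline window.  The window must fit inside the series.
    """
    t = series.times
    if len(t) == 0:
        raise ValueError("empty series")
    span = t[-1] - t[0]
    if baseline_window > span and len(t) > 1:
        raise ValueError(f"baseline window {baseline_window} ns exceeds the "
                         f"series span {span} ns")
    mask = t < t[0] + baseline_window
    if not mask.any():
        mask = np.zeros_like(t, dtype=bool)
        mask[0] = True
    return series.map(lambda v: v - v[mask].mean())


def smooth_centered(series: EnergySeries, window: float = 1.0) -> EnergySeries:
    """Centered moving-average smoothing of every component (window in ns)."""
    if len(series.times) > 1:
        dt = series.times[1] - series.times[0]
        if window < dt:
            raise ValueError("smoothing window shorter than the sampling interval")
    n = _window_samples(series, window)
    return series.map(lambda v: centered_moving_average(v, n))


def component_decomposition_report(series: EnergySeries) -> dict:
    """Tabulate components against time and report per-component extrema.

    Returns ``{"table": DataFrame, "extrema": DataFrame}``: the table has one
    column per component plus the total (total == component sum is enforced
    by the EnergySeries container itself); extrema lists each component's
    signed minimum/maximum and the times at which they occur.
    """
    cols = {"time_ns": series.times}
    for name in sorted(series.components):
        cols[name] = series.components[name]
    cols["total"] = series.total
    table = pd.DataFrame(cols)
    rows = []
    for name in list(sorted(series.components)) + ["total"]:
        v = table[name].to_numpy()
        imin, imax = int(np.argmin(v)), int(np.argmax(v))
        rows.append({"component": name,
                     "min": v[imin], "t_min_ns": series.times[imin],
                     "max": v[imax], "t_max_ns": series.times[imax]})
    return {"table": table, "extrema": pd.DataFrame(rows)}


@dataclass
class CorrelationResult:
    """Pearson correlation between contact count and adsorption energy."""

    r: float | None                 # None when either input is constant
    lags_ns: np.ndarray
    r_at_lag: np.ndarray            # energy shifted by +lag relative to contacts
    n: int


def contact_energy_correlation(contact_times: np.ndarray, contacts: np.ndarray,
                               energy: EnergySeries, *, use_total: bool = True,
                               component: str | None = None,
                               max_lag: float = 5.0) -> CorrelationResult:
    """Correlate the atomic contact count with the (smoothed) adsorption energy.

    The energy series is resampled onto the contact-frame times by
    nearest-time matching (energies are typically sampled three orders of
    magnitude faster than frames).  A negative ``r`` means more contacts go
    with lower energy, the signature of enthalpy-driven adsorption.  The lag
    profile shifts the energy by +-``max_lag`` ns in contact-frame steps.
    """
    contact_times = np.asarray(contact_times, dtype=float)
    contacts = np.asarray(contacts, dtype=float)
    signal = energy.total if use_total else energy.components[component]
    t0, t1 = max(contact_times[0], energy.times[0]), min(contact_times[-1], energy.times[-1])
    if t1 <= t0:
        raise ValueError("contact and energy series do not overlap in time")
    keep = (contact_times >= t0) & (contact_times <= t1)
    ct = contact_times[keep]
    cc = contacts[keep]
    idx = np.clip(np.searchsorted(energy.times, ct), 0, len(energy.times) - 1)
    left = np.clip(idx - 1, 0, len(energy.times) - 1)
    use_left = np.abs(energy.times[left] - ct) < np.abs(energy.times[idx] - ct)
    idx = np.where(use_left, left, idx)
    ee = signal[idx]

    def _pearson(a, b):
        if a.std() == 0 or b.std() == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1])

    r = _pearson(cc, ee)
    dt = ct[1] - ct[0] if len(ct) > 1 else max_lag
    max_shift = int(round(max_lag / dt)) if dt > 0 else 0
    lags, rs = [], []
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            a, b = cc[:len(cc) - s or None], ee[s:]
        else:
            a, b = cc[-s:], ee[:s]
        if len(a) < 3:
            continue
        rv = _pearson(a, b)
        lags.append(s * dt)
        rs.append(np.nan if rv is None else rv)
    return CorrelationResult(r=r, lags_ns=np.asarray(lags), r_at_lag=np.asarray(rs),
                             n=len(cc))
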
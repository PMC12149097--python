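"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures only give curve coordinates and a
numbers-at-risk table, but parametric extrapolation needs per-patient
(time, event) records.  The interval algorithm of Guyot et al. inverts
the KM product-limit construction: within each risk-table interval it
solves for integer event and censoring counts that reproduce both the
digitized survival steps and the published number at risk at the start
of the next interval, assuming censoring is spread uniformly across the
interval.  The reconstruction is deterministic.

Because the source analysis publishes no total-death counts, the
unconstrained variant is used; in the final interval (no later at-risk
figure to match) events follow the KM steps directly with no interim
censoring, and everyone still at risk after the last coordinate is
censored there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class KMCurve:
    """Digitized KM coordinates plus the risk table for one arm/endpoint."""

    times: np.ndarray          # strictly increasing, months
    survival: np.ndarray       # non-increasing, in [0, 1]
    risk_times: np.ndarray     # risk-table time points (first usually 0)
    n_at_risk: np.ndarray      # non-increasing counts
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.survival = np.asarray(self.survival, float)
        self.risk_times = np.asarray(self.risk_times, float)
        self.n_at_risk = np.asarray(self.n_at_risk, int)

    @property
    def n_total(self) -> int:
        return int(self.n_at_risk[0])

    def validate(self) -> None:
        if self.times.size < 2:
            raise ValueError("curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12:
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing over time")
        if self.n_at_risk[0] <= 0:
            raise ValueError("initial number at risk must be positive")


@dataclass
class PseudoIPD:
    """Reconstructed per-patient records."""

    time: np.ndarray
    event: np.ndarray
    arm: str = ""
    endpoint: str = ""
    interval_counts: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return int(self.time.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})


def clean_curve(raw: KMCurve) -> KMCurve:
    """Repair digitization noise: clip survival to [0, 1], enforce a
    monotone non-increasing staircase (running-minimum clip), drop
    duplicate times (keep the last reading), and anchor the curve at
    (0, 1) if the digitizer missed it."""
    t = np.asarray(raw.times, float)
    s = np.clip(np.asarray(raw.survival, float), 0.0, 1.0)
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    # deduplicate, keeping the last digitized reading at each time
    keep = np.r_[np.diff(t) > 1e-12, True]
    t, s = t[keep], s[keep]
    s = np.minimum.accumulate(s)
    if t[0] > 0:
        t = np.r_[0.0, t]
        s = np.r_[1.0, s]
    else:
        s[0] = min(1.0, max(s[0], s[1] if s.size > 1 else 0.0))
        s[0] = 1.0 if s[0] > 1 - 1e-6 else s[0]
        s = np.minimum.accumulate(s)
    if t.size < 2:
        raise ValueError("fewer than 2 distinct points after cleaning")
    out = KMCurve(t, s, raw.risk_times, raw.n_at_risk, raw.arm, raw.endpoint)
    out.validate()
    return out


def reconstruct(curve: KMCurve) -> PseudoIPD:
    """Guyot interval inversion of a cleaned KM curve.

    Raises ``ValueError`` naming the offending interval if the risk table
    is inconsistent with the curve (e.g. implies negative event counts or
    increasing numbers at risk).
    """
    curve.validate()
    t, s = curve.times, curve.survival
    rt, nr = curve.risk_times, curve.n_at_risk
    if rt[0] > t[0]:
        raise ValueError("risk table must start at or before the first coordinate")

    n_int = rt.size
    K = t.size
    # first coordinate index of each interval
    lower = np.searchsorted(t, rt, side="left")
    upper = np.r_[lower[1:], K]  # exclusive

    n_at = np.zeros(K + 1)       # at risk just before coordinate k
    d = np.zeros(K)              # events at coordinate k
    c = np.zeros(K)              # censored in [t_k, t_{k+1})
    cen_times: list[np.ndarray] = []
    km = np.ones(K)              # running KM of the reconstruction
    rows = []

    n_at[0] = nr[0]
    for i in range(n_int):
        lo, up = int(lower[i]), int(upper[i])
        if lo >= up:
            continue
        width_end = rt[i + 1] if i + 1 < n_int else t[-1]
        n_start = n_at[lo]
        if i + 1 < n_int:
            target = nr[i + 1]
            prev_km = km[lo - 1] if lo > 0 else 1.0
            ncen = max(0, min(int(n_start - target),
                              _initial_censor_guess(s, lo, up, n_start, target, prev_km)))
        else:
            target = None
            ncen = 0

        seen: set[int] = set()
        best = None
        best_gap = np.inf
        for _ in range(int(n_start) + 2):  # Guyot adjustment loop
            d_i, c_i, ct_i, n_end, km_i = _process_interval(
                t, s, lo, up, n_at[lo], ncen, width_end,
                km[lo - 1] if lo > 0 else 1.0,
            )
            gap = 0 if target is None else abs(n_end - target)
            if gap < best_gap:
                best, best_gap = (d_i, c_i, ct_i, n_end, km_i), gap
            if target is None or n_end == target:
                break
            seen.add(ncen)
            new_ncen = max(0, ncen + int(n_end - target))
            if new_ncen in seen:
                break
            ncen = new_ncen
        d_i, c_i, ct_i, n_end, km_i = best
        if target is not None and abs(n_end - target) > max(2, 0.02 * nr[0]):
            # beyond digitization rounding: the published counts cannot be
            # reproduced by any non-negative event/censor allocation
            detail = "implies negative event or censor counts" if n_end < target \
                else "unexplained loss to follow-up"
            raise ValueError(
                f"risk table inconsistent in interval {i} "
                f"[{rt[i]:g}, {width_end:g}): implied n at risk {n_end} vs "
                f"published {target} ({detail})")
        d[lo:up], c[lo:up] = d_i, c_i
        km[lo:up] = km_i
        cen_times.append(ct_i)
        n_at[up] = n_end
        rows.append({"interval": i, "t_start": rt[i], "t_end": width_end,
                     "events": int(d_i.sum()), "censored": int(c_i.sum())})

    if d.sum() < 1:
        raise ValueError("reconstruction produced no events; curve may be flat")

    ev_times = np.repeat(t, d.astype(int))
    cen_all = np.concatenate(cen_times) if cen_times else np.array([])
    # everyone still at risk after the last coordinate: censored there
    n_tail = int(round(n_at[upper[-1]] if n_int else 0))
    tail = np.full(max(n_tail, 0), t[-1])
    time = np.r_[ev_times, cen_all, tail]
    event = np.r_[np.ones(ev_times.size, int), np.zeros(cen_all.size + tail.size, int)]
    order = np.argsort(time, kind="stable")
    counts = pd.DataFrame(rows)
    return PseudoIPD(time[order], event[order], curve.arm, curve.endpoint, counts)


def _initial_censor_guess(s, lo, up, n_start, target, prev_km) -> int:
    """First guess for censorings in an interval: the at-risk drop not
    explained by the KM survival ratio across the interval."""
    s_end = s[up - 1]
    ratio = s_end / max(prev_km if lo == 0 else s[lo - 1], 1e-12)
    implied_events = n_start * max(0.0, 1.0 - ratio)
    return max(0, int(round(n_start - implied_events - target)))


def _process_interval(t, s, lo, up, n_start, ncen, t_end, km_prev):
    """One pass of the Guyot inner loop over coordinates lo..up-1.

    Censor times are spread uniformly over [t_lo, t_end); events at each
    coordinate follow from the KM step given the current at-risk count.
    Returns per-coordinate events/censorings, censor times, the at-risk
    count entering the next interval, and the running KM estimate.
    """
    k_n = up - lo
    d = np.zeros(k_n)
    c = np.zeros(k_n)
    if ncen > 0:
        ct = t[lo] + (np.arange(1, ncen + 1) - 0.5) * (t_end - t[lo]) / ncen
        idx = np.clip(np.searchsorted(t[lo:up], ct, side="right") - 1, 0, k_n - 1)
        np.add.at(c, idx, 1)
    else:
        ct = np.array([])
    n = n_start
    km_run = km_prev
    km_out = np.empty(k_n)
    frac_err = 0.0
    for j in range(k_n):
        k = lo + j
        if n > 0 and km_run > 0:
            d_exact = n * (1.0 - s[k] / km_run) + frac_err
        else:
            d_exact = 0.0
        d_j = int(round(d_exact))
        d_j = max(0, min(d_j, int(n)))
        frac_err = d_exact - d_j  # largest-remainder style carry
        if d_j > 0:
            km_run *= 1.0 - d_j / n
        d[j] = d_j
        n = n - d_j - c[j]
        if n < 0:
            c[j] += n  # cannot censor more than remain; clamp
            n = 0
        km_out[j] = km_run
    return d, c, ct, int(round(n)), km_out


# ---------------------------------------------------------------- file I/O

def read_curve_csv(points_path: str | Path, risk_path: str | Path,
                   arm: str = "", endpoint: str = "") -> KMCurve:
    """Load a digitized curve (columns time_months, survival) and its risk
    table (columns time_months, n_at_risk)."""
    pts = pd.read_csv(points_path)
    risk = pd.read_csv(risk_path)
    return KMCurve(pts["time_months"].to_numpy(), pts["survival"].to_numpy(),
                   risk["time_months"].to_numpy(), risk["n_at_risk"].to_numpy(),
                   arm, endpoint)


def write_curve_csv(curve: KMCurve, points_path: str | Path, risk_path: str | Path) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.survival}).to_csv(
        points_path, index=False)
    pd.DataFrame({"time_months": curve.risk_times, "n_at_risk": curve.n_at_risk}).to_csv(
        risk_path, index=False)


def write_ipd_csv(ipd: PseudoIPD, path: str | Path) -> None:
    ipd.to_frame().to_csv(path, index=False)
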
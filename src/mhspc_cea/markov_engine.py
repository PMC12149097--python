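"""Three-state Markov cohort engine (PFS, PD, Death).

The cohort starts progression-free; per-cycle transition matrices are
derived from the fitted progression-free-survival and overall-survival
curves by marginal matching: whenever feasible the state occupancies at
every cycle boundary reproduce the curves exactly,

    pi_PFS(t) = S_pfs(t),   pi_Death(t) = 1 - S_os(t),
    pi_PD(t)  = S_os(t) - S_pfs(t),

which is the partitioned-survival identity the three-state structure
implies.  Concretely, over cycle [t, t+1]:

    p(PFS->PFS) = S_pfs(t+1) / S_pfs(t)
    new deaths  d = S_os(t) - S_os(t+1); PFS members die at the marginal
    OS hazard d / S_os(t) (capped so PFS->PD stays non-negative) and
    PD->Death absorbs the remainder so cumulative deaths track 1 - S_os
    exactly.  Infeasible cells are clamped to [0, 1] with the row
    renormalised and a diagnostic logged.

Cycle length is 28 days, the horizon 13 years (169 complete cycles) and
outcomes are discounted at 5% a year by default.  Half-cycle correction
(accumulating on the average of start- and end-of-cycle occupancy) is on
by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
STATES = ("PFS", "PD", "Death")


@dataclass(frozen=True)
class ModelSettings:
    cycle_days: float = 28.0
    horizon_years: float = 13.0
    discount_annual: float = 0.05
    half_cycle_correction: bool = True

    def __post_init__(self):
        if not 0 <= self.discount_annual <= 0.08:
            raise ValueError("annual discount rate must lie in [0, 0.08]")
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")

    @property
    def n_cycles(self) -> int:
        return int(np.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_days))

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / (DAYS_PER_YEAR / 12.0)


@dataclass
class MarkovTrace:
    """Per-cycle occupancy and discounted accumulations for one arm."""

    occupancy: np.ndarray          # (n_cycles + 1, 3) at cycle boundaries
    matrices: np.ndarray           # (n_cycles, 3, 3)
    ly_cycle: np.ndarray           # discounted life-years accrued per cycle
    qaly_cycle: np.ndarray
    cost_cycle: np.ndarray
    ly_cycle_undisc: np.ndarray
    qaly_cycle_undisc: np.ndarray
    cost_cycle_undisc: np.ndarray
    settings: ModelSettings
    entry_cost: float = 0.0

    @property
    def total_ly(self) -> float:
        return float(self.ly_cycle.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_cycle.sum())

    @property
    def total_cost(self) -> float:
        return float(self.cost_cycle.sum() + self.entry_cost)

    def to_frame(self) -> pd.DataFrame:
        n = self.ly_cycle.size
        return pd.DataFrame({
            "cycle": np.arange(n),
            "time_years": np.arange(n) * self.settings.cycle_years,
            "pi_pfs": self.occupancy[:n, 0],
            "pi_pd": self.occupancy[:n, 1],
            "pi_death": self.occupancy[:n, 2],
            "ly_disc": self.ly_cycle,
            "qaly_disc": self.qaly_cycle,
            "cost_disc": self.cost_cycle,
        })


def discount_factor(cycle_index, settings: ModelSettings):
    """(1 + r)^(-t) with t the cycle start in years; 1 at cycle 0."""
    idx = np.asarray(cycle_index, dtype=float)
    if np.any(idx < 0):
        raise ValueError("cycle index must be non-negative")
    t_years = idx * settings.cycle_years
    return (1.0 + settings.discount_annual) ** (-t_years)


def transitions_from_curves(s_pfs, s_os, settings: ModelSettings,
                            tol: float = 1e-6) -> np.ndarray:
    """Per-cycle 3x3 row-stochastic matrices from survival evaluators.

    ``s_pfs`` and ``s_os`` map time in months to survival probability.
    S_pfs > S_os (progression-free patients must be alive) is clipped,
    with a warning when the violation exceeds ``tol``.
    """
    n = settings.n_cycles
    t = np.arange(n + 1) * settings.cycle_months
    sp = np.asarray(s_pfs(t), dtype=float)
    so = np.asarray(s_os(t), dtype=float)
    for name, s in (("PFS", sp), ("OS", so)):
        if np.any((s < -1e-12) | (s > 1 + 1e-12)):
            raise ValueError(f"{name} survival evaluator returned values outside [0, 1]")
    if np.any(sp > so + tol):
        log.warning("S_pfs exceeds S_os by up to %.3g; clipping to S_os",
                    float(np.max(sp - so)))
    sp = np.minimum(sp, so)

    mats = np.zeros((n, 3, 3))
    clamped = 0
    for i in range(n):
        p_stay = sp[i + 1] / sp[i] if sp[i] > 0 else 0.0
        p_stay = min(max(p_stay, 0.0), 1.0)
        d = max(so[i] - so[i + 1], 0.0)              # new deaths this cycle
        mu = d / so[i] if so[i] > 0 else 0.0         # marginal OS hazard
        if so[i] == sp[i] and so[i + 1] == sp[i + 1]:
            q_fd, q_fp = 1.0 - p_stay, 0.0           # nobody progresses
        else:
            q_fd = min(mu, 1.0 - p_stay)             # PFS -> Death share
            q_fp = max(1.0 - p_stay - q_fd, 0.0)     # PFS -> PD
        pi_pd = so[i] - sp[i]
        deaths_from_pfs = sp[i] * q_fd
        if pi_pd > 1e-15:
            q_pd_d = (d - deaths_from_pfs) / pi_pd
        else:
            q_pd_d = 0.0
        if q_pd_d < -1e-12 or q_pd_d > 1 + 1e-12:
            clamped += 1
        q_pd_d = min(max(q_pd_d, 0.0), 1.0)
        mats[i] = [
            [p_stay, q_fp, q_fd],
            [0.0, 1.0 - q_pd_d, q_pd_d],
            [0.0, 0.0, 1.0],
        ]
    if clamped:
        log.warning("marginal matching infeasible in %d of %d cycles; "
                    "probabilities clamped to [0, 1]", clamped, n)
    return mats


def run_trace(matrices: np.ndarray, settings: ModelSettings,
              u_pfs: float, u_pd: float,
              cost_pfs=0.0, cost_pd=0.0,
              entry_cost: float = 0.0, death_cost: float = 0.0) -> MarkovTrace:
    """Propagate the cohort and accumulate discounted outcomes.

    ``cost_pfs`` / ``cost_pd`` are USD per cycle per patient occupying the
    state (scalar or length-n_cycles array).  ``entry_cost`` is applied
    once at model entry (undiscounted, cycle 0); ``death_cost`` once per
    death, in the cycle it occurs.  Per-cycle quality weights use the
    half-cycle-corrected occupancy when enabled.
    """
    for name, u in (("u_pfs", u_pfs), ("u_pd", u_pd)):
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {u}")
    n = matrices.shape[0]
    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for i in range(n):
        occ[i + 1] = occ[i] @ matrices[i]
        if not np.isclose(occ[i + 1].sum(), 1.0, atol=1e-12):
            raise ValueError(f"occupancy not conserved at cycle {i + 1}")

    if settings.half_cycle_correction:
        occ_bar = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_bar = occ[:-1]

    df = discount_factor(np.arange(n), settings)
    cyc_years = settings.cycle_years
    c_pfs = np.broadcast_to(np.asarray(cost_pfs, float), (n,))
    c_pd = np.broadcast_to(np.asarray(cost_pd, float), (n,))

    ly_u = (occ_bar[:, 0] + occ_bar[:, 1]) * cyc_years
    qaly_u = (u_pfs * occ_bar[:, 0] + u_pd * occ_bar[:, 1]) * cyc_years
    new_deaths = occ[1:, 2] - occ[:-1, 2]
    cost_u = occ_bar[:, 0] * c_pfs + occ_bar[:, 1] * c_pd + death_cost * new_deaths

    return MarkovTrace(
        occupancy=occ, matrices=matrices,
        ly_cycle=ly_u * df, qaly_cycle=qaly_u * df, cost_cycle=cost_u * df,
        ly_cycle_undisc=ly_u, qaly_cycle_undisc=qaly_u, cost_cycle_undisc=cost_u,
        settings=settings, entry_cost=entry_cost,
    )
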
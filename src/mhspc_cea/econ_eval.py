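"""Incremental cost-effectiveness results and threshold-price analysis.

The comparison is rezvilutamide + ADT (intervention) versus
bicalutamide + ADT (comparator).  Outputs: per-arm discounted totals,
incremental cost dC and QALYs dQ, ICER = dC/dQ, and net monetary
benefit NMB = wtp * dQ - dC at the willingness-to-pay threshold
(37,256.3 USD/QALY, three times China's 2023 per-capita GDP).

Internal arithmetic is unrounded; rounding to cents / 2 decimals is an
output-layer concern (``EconResult.rounded``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_model import ARMS, Parameters, ae_cost, pd_cycle_cost, pfs_cycle_cost
from .markov_engine import ModelSettings, transitions_from_curves

DEFAULT_WTP = 37_256.3  # USD per QALY

INTERVENTION, COMPARATOR = "rezvilutamide", "bicalutamide"


@dataclass(frozen=True)
class EconResult:
    cost: dict            # per-arm total discounted cost, USD
    qaly: dict            # per-arm total discounted QALYs
    ly: dict              # per-arm total discounted life-years
    wtp: float = DEFAULT_WTP

    @property
    def delta_cost(self) -> float:
        return self.cost[INTERVENTION] - self.cost[COMPARATOR]

    @property
    def delta_qaly(self) -> float:
        return self.qaly[INTERVENTION] - self.qaly[COMPARATOR]

    @property
    def dominance(self) -> str:
        """'' when a conventional ICER applies; 'dominant' when the
        intervention saves money and gains QALYs; 'dominated' for the
        reverse; 'undefined' when dQ = 0."""
        dc, dq = self.delta_cost, self.delta_qaly
        if dq == 0:
            return "undefined"
        if dc <= 0 and dq > 0:
            return "dominant"
        if dc >= 0 and dq < 0:
            return "dominated"
        return ""

    @property
    def icer(self) -> float:
        """dC/dQ in USD per QALY; NaN where an ICER is not meaningful."""
        if self.dominance:
            return float("nan")
        return self.delta_cost / self.delta_qaly

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qaly - self.delta_cost

    def rounded(self) -> dict:
        """Reporting view: money to cents, (Q)ALYs to 2 decimals."""
        return {
            "cost": {a: round(c, 2) for a, c in self.cost.items()},
            "qaly": {a: round(q, 2) for a, q in self.qaly.items()},
            "delta_cost": round(self.delta_cost, 2),
            "delta_qaly": round(self.delta_qaly, 2),
            "icer": round(self.icer, 2) if not np.isnan(self.icer) else None,
            "nmb": round(self.nmb, 2),
            "dominance": self.dominance,
        }


def icer(c1: float, c0: float, q1: float, q0: float,
         ly1: float = float("nan"), ly0: float = float("nan"),
         wtp: float = DEFAULT_WTP) -> EconResult:
    """Incremental result from per-arm totals (intervention first)."""
    for v in (c1, c0, q1, q0):
        if not np.isfinite(v):
            raise ValueError("per-arm totals must be finite")
    return EconResult(
        cost={INTERVENTION: c1, COMPARATOR: c0},
        qaly={INTERVENTION: q1, COMPARATOR: q0},
        ly={INTERVENTION: ly1, COMPARATOR: ly0},
        wtp=wtp,
    )


class CEModel:
    """The full cost-effectiveness model with survival curves frozen.

    State occupancy depends only on the fitted curves and the cycle
    grid, so it is computed once; ``evaluate`` then recombines it with
    any cost/utility/discount parameter overrides, which keeps one-way
    and probabilistic sensitivity analysis cheap.
    """

    def __init__(self, curves: dict, params: Parameters,
                 settings: ModelSettings | None = None):
        """``curves`` maps arm -> (S_pfs, S_os) callables over months."""
        self.params = params
        self.settings = settings or ModelSettings(
            discount_annual=params["discount_rate"]["value"])
        n = self.settings.n_cycles
        self._occ_bar = {}
        self._new_deaths = {}
        self.occupancy = {}
        for arm in ARMS:
            s_pfs, s_os = curves[arm]
            mats = transitions_from_curves(s_pfs, s_os, self.settings)
            occ = np.zeros((n + 1, 3))
            occ[0] = (1.0, 0.0, 0.0)
            for i in range(n):
                occ[i + 1] = occ[i] @ mats[i]
            self.occupancy[arm] = occ
            if self.settings.half_cycle_correction:
                self._occ_bar[arm] = 0.5 * (occ[:-1] + occ[1:])
            else:
                self._occ_bar[arm] = occ[:-1]
            self._new_deaths[arm] = occ[1:, 2] - occ[:-1, 2]

    def evaluate(self, overrides: dict[str, float] | None = None,
                 wtp: float | None = None) -> EconResult:
        """Discounted totals and incremental results under the base-case
        parameters with ``overrides`` (flat names: ``cost.<item>``,
        ``utility.pfs``, ``utility.pd``, ``discount_rate``) applied."""
        p = self.params.copy_with(overrides) if overrides else self.params
        rate = float(p["discount_rate"]["value"])
        n = self.settings.n_cycles
        cyc_years = self.settings.cycle_years
        df = (1.0 + rate) ** (-np.arange(n) * cyc_years)
        u_pfs = float(p["utilities"]["pfs"]["value"])
        u_pd = float(p["utilities"]["pd"]["value"])
        eol = float(p.get("end_of_life_cost", 0.0))

        cost, qaly, ly = {}, {}, {}
        for arm in ARMS:
            ob = self._occ_bar[arm]
            c_pfs = pfs_cycle_cost(arm, p)
            c_pd = pd_cycle_cost(arm, p)
            per_cycle_cost = ob[:, 0] * c_pfs + ob[:, 1] * c_pd \
                + eol * self._new_deaths[arm]
            cost[arm] = float(per_cycle_cost @ df + ae_cost(arm, p))
            qaly[arm] = float(((u_pfs * ob[:, 0] + u_pd * ob[:, 1]) * cyc_years) @ df)
            ly[arm] = float(((ob[:, 0] + ob[:, 1]) * cyc_years) @ df)
        return EconResult(cost=cost, qaly=qaly, ly=ly,
                          wtp=wtp if wtp is not None else p.get(
                              "wtp_usd_per_qaly", DEFAULT_WTP))

    def evaluate_at_price(self, rez_price: float, wtp: float | None = None) -> EconResult:
        return self.evaluate({"cost.rezvilutamide": rez_price}, wtp=wtp)


def threshold_price(model, wtp: float = DEFAULT_WTP,
                    price_bounds: tuple[float, float] = (0.0, 2000.0),
                    tol: float = 0.01) -> float:
    """Per-cycle intervention drug price at which the strategy is exactly
    cost-effective (ICER = wtp), by bisection to ``tol`` USD.

    ``model`` maps a per-cycle price to an :class:`EconResult`.  The net
    monetary benefit is strictly decreasing in the price (total cost is
    affine-increasing in it, effectiveness unchanged), so the solve is a
    monotone root find of NMB(price) = 0 — equivalent to ICER = wtp
    whenever dQ > 0, and well-defined even where the low bound makes the
    intervention cost-saving (dominant).
    """
    lo, hi = price_bounds
    if not lo < hi:
        raise ValueError("price bounds must satisfy lo < hi")

    def nmb_at(p: float) -> float:
        r = model(p)
        return wtp * r.delta_qaly - r.delta_cost

    f_lo, f_hi = nmb_at(lo), nmb_at(hi)
    if f_lo < f_hi:
        raise ValueError("NMB is not decreasing in price; model miswired")
    if f_hi >= 0:
        return float(hi)  # cost-effective even at the top price
    if f_lo < 0:
        r_lo, r_hi = model(lo), model(hi)
        raise ValueError(
            "threshold price not bracketed: ICER at lower bound "
            f"{r_lo.icer if not r_lo.dominance else r_lo.dominance} and at upper bound "
            f"{r_hi.icer if not r_hi.dominance else r_hi.dominance} "
            f"do not straddle wtp={wtp}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if nmb_at(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def price_reduction_pct(base_price: float, threshold: float) -> float:
    """Percentage reduction from the list price to the threshold price."""
    return (base_price - threshold) / base_price * 100.0
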
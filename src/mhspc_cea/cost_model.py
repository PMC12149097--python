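"""Per-cycle, per-state, per-arm cost assembly and health-state utilities.

Costs come from a declarative parameter file (``data/params.yaml``,
2024 USD): drug acquisition per 28-day cycle, the ADT backbone,
monitoring tests, one-time grade>=3 adverse-event management at model
entry, and the progressed-disease mix of active subsequent therapy
versus supportive care.  Everything is configurable; the shipped file
carries the published base-case values and one-way ranges (costs +/-20%,
utilities +/-10%).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

ARMS = ("rezvilutamide", "bicalutamide")

_BASKET_TOL = 1e-9


class Parameters(dict):
    """The parsed parameter file; a plain nested dict with helpers."""

    def copy_with(self, overrides: dict[str, float] | None = None) -> "Parameters":
        """Deep copy with flat overrides applied (see ``set_flat``)."""
        out = Parameters(copy.deepcopy(dict(self)))
        for key, val in (overrides or {}).items():
            out.set_flat(key, val)
        return out

    # flat parameter names used by the sensitivity machinery:
    #   cost.<item>, utility.pfs, utility.pd, discount_rate
    def get_flat(self, key: str) -> float:
        grp, _, item = key.partition(".")
        if grp == "cost":
            return float(self["costs"][item]["value"])
        if grp == "utility":
            return float(self["utilities"][item]["value"])
        if key == "discount_rate":
            return float(self["discount_rate"]["value"])
        raise KeyError(key)

    def set_flat(self, key: str, value: float) -> None:
        grp, _, item = key.partition(".")
        if grp == "cost":
            self["costs"][item]["value"] = float(value)
        elif grp == "utility":
            self["utilities"][item]["value"] = float(value)
        elif key == "discount_rate":
            self["discount_rate"]["value"] = float(value)
        else:
            raise KeyError(key)


def load_parameters(path: str | Path | None = None) -> Parameters:
    """Load the parameter file; defaults to the packaged base case."""
    if path is None:
        text = resources.files("mhspc_cea").joinpath("data/params.yaml").read_text()
    else:
        text = Path(path).read_text()
    params = Parameters(yaml.safe_load(text))
    _validate(params)
    return params


def _validate(p: Parameters) -> None:
    for name, item in p["costs"].items():
        if item["value"] < 0:
            raise ValueError(f"cost {name} is negative")
    for state, item in p["utilities"].items():
        if not 0 <= item["value"] <= 1:
            raise ValueError(f"utility {state} outside [0, 1]")
    if p["utilities"]["pd"]["value"] > p["utilities"]["pfs"]["value"]:
        raise ValueError("PD utility exceeds PFS utility")
    for arm, inc in p["ae_incidence"].items():
        for ae, v in inc.items():
            if not 0 <= v <= 1:
                raise ValueError(f"AE incidence {arm}/{ae} outside [0, 1]")
    for arm, v in p["subsequent_uptake"].items():
        if not 0 <= v <= 1:
            raise ValueError(f"subsequent uptake for {arm} outside [0, 1]")


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def pfs_cycle_cost(arm: str, params: Parameters,
                   include_adt: bool | None = None,
                   monitoring: bool = True) -> float:
    """USD per cycle in the progression-free state: first-line drug +
    ADT backbone + scheduled monitoring tests."""
    _check_arm(arm)
    costs = params["costs"]
    total = costs[arm]["value"]
    if include_adt is None:
        include_adt = bool(params.get("include_adt_in_pfs", True))
    if include_adt:
        total += costs["adt_average"]["value"]
    if monitoring:
        for item, units in params.get("monitoring", {}).get("pfs", {}).items():
            total += units * costs[item]["value"]
    return float(total)


def pd_cycle_cost(arm: str, params: Parameters, monitoring: bool = True) -> float:
    """USD per cycle in the progressed state: uptake-weighted subsequent
    therapy basket, supportive care for the remainder, plus follow-up."""
    _check_arm(arm)
    costs = params["costs"]
    basket = params["subsequent_basket"]
    wsum = sum(basket.values())
    if abs(wsum - 1.0) > _BASKET_TOL:
        raise ValueError(f"subsequent-basket weights sum to {wsum}, not 1")
    basket_cost = 0.0
    for drug, w in basket.items():
        c = costs[drug]["value"]
        if drug == "abiraterone" and params.get("abiraterone_includes_prednisone", False):
            c += costs["prednisone"]["value"]
        basket_cost += w * c
    uptake = params["subsequent_uptake"][arm]
    total = uptake * basket_cost + (1.0 - uptake) * costs["supportive_care"]["value"]
    if monitoring:
        for item, units in params.get("monitoring", {}).get("pd", {}).items():
            total += units * costs[item]["value"]
    return float(total)


def ae_cost(arm: str, params: Parameters) -> float:
    """One-time adverse-event management cost at model entry:
    sum over grade>=3 AEs of incidence(arm) x unit cost."""
    _check_arm(arm)
    inc = params["ae_incidence"][arm]
    costs = params["costs"]
    return float(sum(p * costs[f"ae_{ae}"]["value"] for ae, p in inc.items()))


@dataclass(frozen=True)
class UtilityInputs:
    u_pfs: float
    u_pd: float

    def __post_init__(self):
        if not 0 <= self.u_pd <= self.u_pfs <= 1:
            raise ValueError("need 0 <= u_pd <= u_pfs <= 1")


def utilities(params: Parameters) -> UtilityInputs:
    return UtilityInputs(params["utilities"]["pfs"]["value"],
                         params["utilities"]["pd"]["value"])


def cny_to_usd(cny: float, params: Parameters) -> float:
    return cny / params["exchange_rate_cny_per_usd"]


def usd_to_cny(usd: float, params: Parameters) -> float:
    return usd * params["exchange_rate_cny_per_usd"]
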
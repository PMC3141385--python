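"""Cost rewards: fracture management costs, drug accrual, discounting, and
the DRG weighted-average hospital-costing method.

All amounts are euros (2010).  A fracture is charged once, in full, in the
cycle of the event (the management costs already bundle hospitalisation and
rehabilitation).  Drug cost accrues at the end of each cycle for every woman
alive at its start and is discounted with the same end-of-cycle factor as
that cycle's fracture costs.  Only clinically diagnosed (symptomatic)
vertebral fractures consume resources; morphometric ones carry no cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import CostParams, Site
from .synthetic import DRGCostTable


def discount(amount: float, cycle: int, rate: float) -> float:
    """Present value of ``amount`` incurred at the end of year ``cycle``."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return amount / (1.0 + rate) ** cycle


def annual_drug_cost(price_per_12_weeks: float, weeks_per_year: float = 52.0) -> float:
    """Annual drug cost from a 12-week pack price (52-week year by default)."""
    if price_per_12_weeks < 0:
        raise ValueError("price must be >= 0")
    return price_per_12_weeks * weeks_per_year / 12.0


def fracture_event_cost(site: Site, symptomatic: bool, params: CostParams) -> float:
    """Management cost charged for one fracture event.

    Vertebral fractures cost only when symptomatic; hip and wrist always.
    """
    site = Site(site)
    if site is Site.VERTEBRA and not symptomatic:
        return 0.0
    return params.management_cost[site]


def weighted_average_drg_cost(table: DRGCostTable | pd.DataFrame) -> float:
    """Per-stay cost as the stay-count-weighted average over DRG rows."""
    if isinstance(table, pd.DataFrame):
        counts, costs = table["count"], table["unit_cost"]
        total_stays = int(counts.sum())
        total_cost = float((counts * costs).sum())
    else:
        total_stays, total_cost = table.total_stays, table.total_cost
    if total_stays <= 0:
        raise ValueError("DRG table has no stays")
    return total_cost / total_stays


@dataclass
class CostLedger:
    """Per-patient running cost account, split drug vs fracture.

    Used by the per-patient trace/API surface; the vectorized engine keeps
    the same quantities in arrays.
    """

    rate: float
    drug_by_cycle: dict[int, float] = field(default_factory=dict)
    fracture_by_cycle: dict[int, float] = field(default_factory=dict)

    def add_drug(self, cycle: int, amount: float) -> None:
        self.drug_by_cycle[cycle] = self.drug_by_cycle.get(cycle, 0.0) + _checked(amount)

    def add_fracture(self, cycle: int, amount: float) -> None:
        self.fracture_by_cycle[cycle] = self.fracture_by_cycle.get(cycle, 0.0) + _checked(amount)

    @property
    def drug_total(self) -> float:
        return sum(self.drug_by_cycle.values())

    @property
    def fracture_total(self) -> float:
        return sum(self.fracture_by_cycle.values())

    @property
    def total(self) -> float:
        return self.drug_total + self.fracture_total

    @property
    def drug_total_discounted(self) -> float:
        return sum(discount(a, c, self.rate) for c, a in self.drug_by_cycle.items())

    @property
    def fracture_total_discounted(self) -> float:
        return sum(discount(a, c, self.rate) for c, a in self.fracture_by_cycle.items())

    @property
    def total_discounted(self) -> float:
        return self.drug_total_discounted + self.fracture_total_discounted


def _checked(amount: float) -> float:
    if amount < 0:
        raise ValueError("cost amounts must be >= 0")
    return amount
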
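"""Population-weighted income-deprivation quintiles.

Zones are ranked by income-deprivation rate (highest first) and allocated to
quintiles by cumulative population, so each quintile holds as close to 20% of
the total population as the zone sizes allow.  Quintile 1 is the most
deprived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import Datazone


@dataclass(frozen=True)
class QuintileAssignment:
    quintile: dict[str, int]  # zone_id -> 1..5, 1 = most deprived
    population_share: dict[int, float]  # quintile -> fraction of total population

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zone_id": list(self.quintile), "quintile": list(self.quintile.values())}
        )


def assign_quintiles(zones: Sequence["Datazone"]) -> QuintileAssignment:
    """Allocate zones to population-weighted deprivation quintiles.

    Zones are sorted by income rate descending (ties broken by zone id, so
    the assignment never depends on input order).  A zone whose population
    block straddles a 20% boundary goes to the quintile containing its
    population midpoint: quintile = ceil(5 * cum_mid / total), which keeps
    each quintile's population share within one zone of 20%.
    """
    if len(zones) < 5:
        raise ValueError("need at least 5 zones to form quintiles")
    total = sum(z.base_population for z in zones)
    if total <= 0:
        raise ValueError("total population is zero")
    ordered = sorted(zones, key=lambda z: (-z.income_rate, z.zone_id))
    quintile: dict[str, int] = {}
    pop_in_q = dict.fromkeys(range(1, 6), 0)
    cum = 0
    for z in ordered:
        mid = cum + z.base_population / 2.0
        q = _ceil_div_midpoint(mid, total)
        quintile[z.zone_id] = q
        pop_in_q[q] += z.base_population
        cum += z.base_population
    share = {q: pop_in_q[q] / total for q in range(1, 6)}
    return QuintileAssignment(quintile=quintile, population_share=share)


def _ceil_div_midpoint(mid: float, total: int) -> int:
    """ceil(5 * mid / total), clamped to 1..5, exact for half-integer mid."""
    # mid is a multiple of 0.5; work in doubled integers to avoid float error
    num = int(round(10 * mid))  # 5 * (2 * mid)
    den = 2 * total
    q = -(-num // den)
    return min(5, max(1, q))
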
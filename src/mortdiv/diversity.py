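"""Hill-number diversity of cause-of-mortality distributions.

The effective number of causes at viewpoint q is

    D_q(p) = (sum_i p_i^q)^(1/(1-q))          for q != 1
    D_1(p) = exp(-sum_i p_i ln p_i)           (exponential of Shannon entropy)

computed over the relative prevalences p_i of an abundance vector.  q = 0
counts the causes present (richness); q = 1 weights each cause exactly by
its prevalence; larger q emphasises dominant causes.  Values range from 1
(all deaths from one cause) to the number of causes present (all equally
prevalent).  Abundances may be real-valued: life-table decrements are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


def hill_diversity(abundances, q: float) -> float:
    """Effective number of causes of an abundance vector at viewpoint q.

    ``abundances`` is any mapping, Series or array of non-negative masses;
    zero-abundance causes are excluded from the sums (0 log 0 := 0).
    """
    if q < 0:
        raise ValueError(f"viewpoint q must be >= 0, got {q}")
    if isinstance(abundances, Mapping):
        n = np.asarray(list(abundances.values()), dtype=float)
    else:
        n = np.asarray(abundances, dtype=float)
    if n.ndim != 1:
        raise ValueError("abundances must be one-dimensional")
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    n = n[n > 0]
    if n.size == 0:
        raise ValueError("distribution has no positive abundance")
    p = n / n.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


@dataclass(frozen=True)
class DiversityResult:
    label: tuple
    q: float
    value: float


def diversity_series(
    distributions: Mapping[tuple, "pd.Series | Mapping | np.ndarray"],
    q_values: tuple[float, ...] = (0.0, 1.0),
) -> pd.DataFrame:
    """Effective numbers for a set of labelled cause distributions.

    ``distributions`` maps a subcommunity label (e.g. (year, sex, quintile,
    age_range)) to its cause abundances — life-table decrements or raw
    observed counts.  Returns one row per (label, q).
    """
    rows = []
    for label, dist in distributions.items():
        for q in q_values:
            rows.append((*label, q, hill_diversity(dist, q)))
    if not rows:
        raise ValueError("no distributions supplied")
    width = len(rows[0]) - 2
    cols = [f"key{i}" for i in range(width)] + ["q", "value"]
    return pd.DataFrame(rows, columns=cols)
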
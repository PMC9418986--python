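"""Direct age standardisation to the 2013 European Standard Population.

ASMRs are weighted averages of age-band-specific death rates, with weights
taken from the ESP 2013 table (100,000 standard persons over 5-year bands
0-4 ... 85-89 and 90+).  Age-restricted ASMRs (e.g. premature mortality,
ages 0-74) renormalise by the weight sum of the included bands, so a 0-74
ASMR is per 100,000 of the 0-74 standard population and the full-range ASMR
is the weight-sum-weighted combination of the restricted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StandardPopulation:
    """Ordered 5-year age bands and their standard-person weights."""

    labels: tuple[str, ...]
    lower: tuple[int, ...]  # inclusive lower age of each band
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 100_000) > 1e-9:
            raise ValueError(f"standard weights must sum to 100,000, got {sum(self.weights)}")

    def band_index(self, ages: np.ndarray) -> np.ndarray:
        """Index of the band containing each age (terminal band open-ended)."""
        return np.searchsorted(np.asarray(self.lower), ages, side="right") - 1

    def bands_for_range(self, age_range: tuple[int, int]) -> np.ndarray:
        """Indices of the bands exactly covering an inclusive age range.

        The range must start on a band boundary and end either on the age
        just below a boundary or inside the open terminal band.
        """
        lo, hi = age_range
        lower = np.asarray(self.lower)
        if lo not in lower:
            raise ValueError(f"age range start {lo} does not align with band boundaries")
        i0 = int(np.searchsorted(lower, lo))
        i1 = int(np.searchsorted(lower, hi, side="right") - 1)
        if i1 < len(lower) - 1 and hi != lower[i1 + 1] - 1:
            raise ValueError(f"age range end {hi} does not align with band boundaries")
        return np.arange(i0, i1 + 1)


def load_esp2013() -> StandardPopulation:
    """The 2013 European Standard Population, 0-4 ... 85-89 and 90+."""
    with resources.files("mortdiv.data").joinpath("esp2013.csv").open() as fh:
        tab = pd.read_csv(fh)
    labels = tuple(tab["band"])
    lower = tuple(int(b.split("-")[0].rstrip("+")) for b in tab["band"])
    return StandardPopulation(labels=labels, lower=lower, weights=tuple(tab["weight"].astype(float)))


def asmr(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    standard: StandardPopulation,
    age_range: tuple[int, int] = (0, 110),
    cause_filter: set[str] | None = None,
) -> float:
    """Directly age-standardised mortality rate, per 100,000 per year.

    ``deaths`` and ``population`` are taken as already restricted to one
    stratum (e.g. a year/sex/quintile); only their ``age`` (and for deaths
    optionally ``cause``) columns are used here.  Bands with zero population
    and zero deaths contribute a zero rate; zero population with deaths is
    an error.
    """
    bands = standard.bands_for_range(age_range)
    weights = np.asarray(standard.weights)[bands]

    if cause_filter is not None:
        deaths = deaths[deaths["cause"].isin(cause_filter)]
    lo, hi = age_range
    deaths = deaths[(deaths["age"] >= lo) & (deaths["age"] <= hi)]
    population = population[(population["age"] >= lo) & (population["age"] <= hi)]

    d_band = np.zeros(len(bands))
    if len(deaths):
        idx = standard.band_index(deaths["age"].to_numpy()) - bands[0]
        np.add.at(d_band, idx, 1)
    p_band = np.zeros(len(bands))
    if len(population):
        idx = standard.band_index(population["age"].to_numpy()) - bands[0]
        np.add.at(p_band, idx, population["count"].to_numpy(dtype=float))

    rates = np.zeros(len(bands))
    for i in range(len(bands)):
        if p_band[i] == 0:
            if d_band[i] > 0:
                raise ValueError(
                    f"band {standard.labels[bands[i]]} has deaths but zero population"
                )
            rates[i] = 0.0
        else:
            rates[i] = d_band[i] / p_band[i]
    return float(100_000 * np.sum(weights * rates) / np.sum(weights))


def percent_change(rate_start: float, rate_end: float) -> int:
    """Whole-percent reduction from ``rate_start`` to ``rate_end``.

    Positive for a fall, negative for a rise; rounded to the nearest
    integer, halves away from zero.
    """
    if rate_start <= 0:
        raise ValueError(f"rate_start must be positive, got {rate_start}")
    pct = 100.0 * (rate_start - rate_end) / rate_start
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))
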
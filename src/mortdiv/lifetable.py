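"""Period life tables with old-age extrapolation and cause decrements.

Single-year-of-age life tables 0-110+ are built from observed death counts
and mid-year exposures for ages 0-89; rates for ages 90-110 come from a
Kannisto-Makeham logistic hazard fitted to the old-age window (default ages
70-89) by Poisson maximum likelihood.  The terminal age 110 is an open
interval with q = 1.  Life-table decrements are then split across causes of
death in proportion to the observed cause mix at each age, giving a
multiple-decrement table whose per-age cause distributions feed the
diversity calculations.

The hazard law is::

    mu(x) = c + a * exp(b * (x - x0)) / (1 + a * exp(b * (x - x0)))

an age-independent background term plus a logistic old-age term that
plateaus below c + 1; ``x0`` is the lower end of the fit window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

MAX_AGE = 110
RADIX = 100_000.0

DEFAULT_FIT_AGES = (70, 89)
EXTRAP_AGES = (90, MAX_AGE)


@dataclass
class AgeRateSchedule:
    """Observed deaths, person-year exposures and central rates by age."""

    ages: np.ndarray
    deaths: np.ndarray
    exposure: np.ndarray

    @property
    def m(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(self.exposure > 0, self.deaths / self.exposure, 0.0)
        return rates


@dataclass
class KannistoMakehamParams:
    a: float
    b: float
    c: float
    age_offset: float
    converged: bool = True
    fallback_pure_kannisto: bool = False

    def hazard(self, x: np.ndarray | float) -> np.ndarray | float:
        with np.errstate(over="ignore"):
            z = self.a * np.exp(self.b * (np.asarray(x, dtype=float) - self.age_offset))
            logistic = np.where(np.isfinite(z), z / (1.0 + np.where(np.isfinite(z), z, 0.0)), 1.0)
        return self.c + logistic


@dataclass
class LifeTable:
    """Columns of a closed period life table, ages 0..110."""

    age: np.ndarray
    m: np.ndarray
    a: np.ndarray  # mean fraction of the interval lived by those dying in it
    q: np.ndarray
    l: np.ndarray  # survivors at exact age x, radix 100,000
    d: np.ndarray  # deaths in [x, x+1)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age, "m": self.m, "a": self.a, "q": self.q, "l": self.l, "d": self.d}
        )


@dataclass
class MultiDecrementLifeTable:
    table: LifeTable
    causes: list[str]
    decrements: np.ndarray  # shape (ages, causes); rows sum to d_x

    def frame(self) -> pd.DataFrame:
        ages = np.repeat(self.table.age, len(self.causes))
        return pd.DataFrame(
            {
                "age": ages,
                "cause": np.tile(np.asarray(self.causes, dtype=object), len(self.table.age)),
                "d": self.decrements.ravel(),
            }
        )


def estimate_rates(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    max_age: int = 89,
) -> AgeRateSchedule:
    """Central death rates m_x = D_x / E_x for ages 0..``max_age``.

    Both tables are taken as already restricted to one stratum (year, sex,
    quintile-or-all); zones are aggregated here.  A positive death count
    with zero exposure is an error; zero deaths with zero exposure records
    m_x = 0 with a warning.
    """
    ages = np.arange(max_age + 1)
    d = np.zeros(len(ages))
    sub = deaths[deaths["age"] <= max_age]
    if len(sub):
        np.add.at(d, sub["age"].to_numpy(), 1)
    e = np.zeros(len(ages))
    subp = population[population["age"] <= max_age]
    if len(subp):
        np.add.at(e, subp["age"].to_numpy(), subp["count"].to_numpy(dtype=float))
    bad = (e == 0) & (d > 0)
    if bad.any():
        raise ValueError(f"deaths with zero exposure at ages {ages[bad].tolist()}")
    empty = (e == 0) & (d == 0)
    if empty.any():
        logger.warning("zero exposure and zero deaths at ages %s; m_x set to 0", ages[empty].tolist())
    return AgeRateSchedule(ages=ages, deaths=d, exposure=e)


def _neg_loglik(theta: np.ndarray, x: np.ndarray, d: np.ndarray, e: np.ndarray) -> float:
    # extreme trial points overflow exp harmlessly; they are rejected as inf
    with np.errstate(over="ignore", invalid="ignore"):
        a, b, c = np.exp(theta)
        z = a * np.exp(b * x)
        mu = c + np.where(np.isfinite(z), z / (1.0 + z), 1.0)
        if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
            return np.inf
        nll = -(np.sum(d * np.log(mu) - e * mu))
    return float(nll) if np.isfinite(nll) else np.inf


def fit_kannisto_makeham(
    schedule: AgeRateSchedule,
    fit_ages: tuple[int, int] = DEFAULT_FIT_AGES,
) -> KannistoMakehamParams:
    """Fit the logistic hazard law by Poisson maximum likelihood.

    Maximises sum_x [D_x log mu(x + 0.5) - E_x mu(x + 0.5)] over
    (log a, log b, log c), with the age offset at the lower end of the fit
    window; multi-start from a small parameter grid, keeping the best
    optimum.  If no start converges the fit falls back to a pure Kannisto
    law (c = 0) and flags the result.
    """
    lo, hi = fit_ages
    mask = (schedule.ages >= lo) & (schedule.ages <= hi) & (schedule.exposure > 0)
    if mask.sum() < 5:
        raise ValueError("fit window must contain at least 5 ages with exposure")
    d = schedule.deaths[mask]
    e = schedule.exposure[mask]
    if d.sum() == 0:
        raise ValueError("no deaths in the fit window; hazard law unidentifiable")
    x = schedule.ages[mask] + 0.5 - lo  # mid-interval, offset at window start

    starts = [
        np.log([a0, b0, c0])
        for a0 in (0.005, 0.05, 0.3)
        for b0 in (0.05, 0.13)
        for c0 in (1e-4, 1e-2)
    ]
    best = None
    with warnings.catch_warnings():
        # finite differences at rejected (inf) trial points emit NaN warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        for theta0 in starts:
            res = optimize.minimize(
                _neg_loglik,
                theta0,
                args=(x, d, e),
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        logger.warning("Kannisto-Makeham fit failed from every start; using pure Kannisto")
        return _fit_pure_kannisto(x, d, e, age_offset=lo)
    a, b, c = np.exp(best.x)
    return KannistoMakehamParams(a=float(a), b=float(b), c=float(c), age_offset=float(lo),
                                 converged=bool(best.success))


def _fit_pure_kannisto(x: np.ndarray, d: np.ndarray, e: np.ndarray, age_offset: float) -> KannistoMakehamParams:
    def nll(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            a, b = np.exp(theta)
            z = a * np.exp(b * x)
            mu = np.where(np.isfinite(z), z / (1.0 + z), 1.0)
            if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
                return np.inf
            val = -(np.sum(d * np.log(mu) - e * mu))
        return float(val) if np.isfinite(val) else np.inf

    best = None
    for theta0 in [np.log([a0, b0]) for a0 in (0.01, 0.1) for b0 in (0.05, 0.13)]:
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("old-age hazard fit failed in both parameterisations")
    a, b = np.exp(best.x)
    return KannistoMakehamParams(a=float(a), b=float(b), c=0.0, age_offset=age_offset,
                                 converged=False, fallback_pure_kannisto=True)


def poisson_loglik(params: KannistoMakehamParams, schedule: AgeRateSchedule,
                   fit_ages: tuple[int, int] = DEFAULT_FIT_AGES) -> float:
    """Poisson log-likelihood of a parameter set over the fit window."""
    lo, hi = fit_ages
    mask = (schedule.ages >= lo) & (schedule.ages <= hi) & (schedule.exposure > 0)
    mu = params.hazard(schedule.ages[mask] + 0.5)
    return float(np.sum(schedule.deaths[mask] * np.log(mu) - schedule.exposure[mask] * mu))


def extrapolate_rates(
    params: KannistoMakehamParams,
    ages: tuple[int, int] = EXTRAP_AGES,
) -> AgeRateSchedule:
    """Hazard-law rates m_x = mu(x + 0.5) for the extrapolation ages."""
    xs = np.arange(ages[0], ages[1] + 1)
    m = np.asarray(params.hazard(xs + 0.5), dtype=float)
    # schedule carries the rates directly: exposure 1, deaths m
    return AgeRateSchedule(ages=xs, deaths=m, exposure=np.ones_like(m))


def combine_rates(observed: AgeRateSchedule, extension: AgeRateSchedule) -> np.ndarray:
    """Full m_x vector 0..110 from an observed schedule plus its extension."""
    m = np.empty(MAX_AGE + 1)
    m[observed.ages] = observed.m
    m[extension.ages] = extension.m
    return m


def build_lifetable(
    m: np.ndarray,
    a0: float = 0.1,
    ax: float = 0.5,
) -> LifeTable:
    """Closed life table from central rates for every age 0..110.

    q_x = m_x / (1 + (1 - a_x) m_x) capped at 1, with a_x = 0.5 at all ages
    except a_0 (infant deaths cluster early in the first year, default 0.1);
    the terminal age is open with q = 1.  l and d follow recursively from
    the radix 100,000, so the d column always sums to the radix.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (MAX_AGE + 1,):
        raise ValueError(f"need rates for every age 0..{MAX_AGE}")
    if np.any(m < 0):
        raise ValueError("negative central rates")
    ages = np.arange(MAX_AGE + 1)
    a = np.full(MAX_AGE + 1, ax)
    a[0] = a0
    q = np.minimum(m / (1.0 + (1.0 - a) * m), 1.0)
    q[-1] = 1.0  # open terminal interval
    l = np.empty(MAX_AGE + 1)
    d = np.empty(MAX_AGE + 1)
    l[0] = RADIX
    for x in range(MAX_AGE):
        d[x] = l[x] * q[x]
        l[x + 1] = l[x] - d[x]
    d[-1] = l[-1]
    return LifeTable(age=ages, m=m, a=a, q=q, l=l, d=d)


def _cause_matrix(observed: pd.DataFrame, causes: list[str]) -> np.ndarray:
    """Per-age observed cause counts, shape (111, n_causes)."""
    mat = np.zeros((MAX_AGE + 1, len(causes)))
    cidx = {c: i for i, c in enumerate(causes)}
    ages = observed["age"].to_numpy()
    cs = observed["cause"].map(cidx).to_numpy()
    np.add.at(mat, (ages, cs), 1)
    return mat


def build_multidecrement(
    lt: LifeTable,
    observed_deaths: pd.DataFrame,
    pool_from_age: int = 90,
) -> MultiDecrementLifeTable:
    """Split life-table decrements across causes by the observed cause mix.

    d_{x,i} = d_x * D_{x,i} / D_x.  Ages at or above ``pool_from_age`` — the
    extrapolation region, where single-year splits are no longer anchored to
    the fitted rates — all use the pooled cause mix of observed deaths at
    those ages.  A younger age with no observed deaths borrows the pooled
    mix of ages x-2..x+2, widening the window until it is non-empty.
    """
    if not len(observed_deaths):
        raise ValueError("no observed deaths in the stratum")
    causes = sorted(observed_deaths["cause"].unique())
    mat = _cause_matrix(observed_deaths, causes)
    totals = mat.sum(axis=1)

    pooled_old = mat[pool_from_age:].sum(axis=0)
    dec = np.zeros_like(mat)
    for x in range(MAX_AGE + 1):
        if x >= pool_from_age:
            mix = pooled_old
            if mix.sum() == 0:  # no observed deaths that old: widen downwards
                mix = _widening_mix(mat, x)
        elif totals[x] > 0:
            mix = mat[x]
        else:
            mix = _widening_mix(mat, x)
        dec[x] = lt.d[x] * mix / mix.sum()
    return MultiDecrementLifeTable(table=lt, causes=causes, decrements=dec)


def _widening_mix(mat: np.ndarray, x: int) -> np.ndarray:
    for half in range(2, MAX_AGE + 1):
        lo = max(0, x - half)
        hi = min(MAX_AGE, x + half)
        mix = mat[lo : hi + 1].sum(axis=0)
        if mix.sum() > 0:
            return mix
    raise ValueError("no observed deaths at any age")


def cause_distribution(
    mdlt: MultiDecrementLifeTable,
    age_range: tuple[int, int] = (0, MAX_AGE),
) -> pd.Series:
    """Cause abundances n_i summed over an inclusive age range.

    Returns a Series indexed by cause, dropping causes with zero mass; over
    the full range the values sum to the 100,000 radix.
    """
    lo, hi = age_range
    if lo > hi or lo < 0 or hi > MAX_AGE:
        raise ValueError(f"invalid age range ({lo}, {hi})")
    n = mdlt.decrements[lo : hi + 1].sum(axis=0)
    s = pd.Series(n, index=pd.Index(mdlt.causes, name="cause"), name="n")
    return s[s > 0]


def stratum_lifetable(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    fit_ages: tuple[int, int] = DEFAULT_FIT_AGES,
    a0: float = 0.1,
) -> tuple[MultiDecrementLifeTable, KannistoMakehamParams]:
    """Observed rates -> fitted extrapolation -> multiple-decrement table."""
    schedule = estimate_rates(deaths, population)
    params = fit_kannisto_makeham(schedule, fit_ages=fit_ages)
    extension = extrapolate_rates(params)
    m = combine_rates(schedule, extension)
    lt = build_lifetable(m, a0=a0)
    mdlt = build_multidecrement(lt, deaths)
    return mdlt, params
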
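# Methods

## Synthetic registry model

The generator emulates a national vital-events registry at the small-area
level. Its components, and the defaults that define the reference scenario:

**Zones.** `n_zones` areas with income-deprivation rates drawn from a
right-skewed Beta(2, 6) on (0, 1) and populations log-normal (σ = 0.35)
around `mean_zone_population` (default 783 persons, a typical small-area
geography mean), floored at 50.

**Population.** Each zone's population is spread over single ages 0–110 by
a stylised pyramid — flat to age 50, then exponentially declining with a
12-year e-folding — and split evenly between sexes. Integerisation uses the
largest-remainder method, so zone-year totals are conserved exactly. The
population is held constant over calendar years; realistic demographic
change (migration, cohort waves) is deliberately not modelled.

**Deaths.** Cell-level counts for each (year, age, sex, zone) are Poisson
with mean `count × μ`, where

    μ = (c + A·e^{B·age}) × s_sex × g^{5−quintile} × e^{−δ·(year−year₀)}

with defaults `c = 1e-4` (background hazard), `A = 3e-5`, `B = 0.095`
(Gompertz senescence, giving a crude death rate near 1%/year with most
deaths above 75), `s_male = 1.5`, deprivation gradient `g = 1.2` per
quintile step (most-deprived ≈ 2× least-deprived), and improvement rate
`δ = 0.015`/year (≈ 25% hazard decline over 19 years, the order of observed
national ASMR falls). The sex, deprivation and improvement multipliers act
on the whole Makeham-plus-Gompertz hazard, not the senescent term alone:
the declines being emulated are all-cause. If `μ > 1` the Poisson mean is
clipped at the cell count and a warning logged. Each death draws a cause
from an age-group-specific categorical distribution (groups 0–14, 15–44,
45–74, 75+, each with its own gamma-drawn base weights over `n_causes = 60`
letter+two-digit codes); the summed probability of the `k = 5` leading
causes interpolates linearly from 40% in the first year to 25% in the last,
with the remaining mass spread over the other causes proportionally. That
linear evening-out is the diversification mechanism the analysis is meant
to detect.

All draws descend from one integer seed and are ordered deterministically
by (year, age, sex, zone), so identical configurations yield byte-identical
tables.

**What passing tests show.** The generator produces clean, complete,
single-vintage records with independent Poisson cells. Real registries have
coding-practice changes, geography revisions, migration, correlated shocks
(epidemics, cold winters) and cause-assignment error; results on synthetic
data certify the pipeline's arithmetic and its ability to recover known
structure, not robustness to those artefacts.

## Deprivation quintiles

Zones sorted by income rate descending (ties broken by zone id), cumulative
population accumulated, and each zone assigned `ceil(5·mid/total)` where
`mid` is the zone's population midpoint. This keeps every quintile's share
within (largest zone population)/(total) of 20% and is order-independent.
The boundary arithmetic is done in doubled integers, so exact half-integer
midpoints never fall prey to float rounding. Weighting is by total (not
adult) population. A single deprivation vintage is used per run.

## Age standardisation

The 2013 European Standard Population is shipped as package data with the
first band pooled to 0–4 and the last to 90+ (weights 5000 … 1000, asserted
to total 100 000 at load). Age-restricted ASMRs renormalise by the weight
sum of the included bands — a 0–74 ASMR is per 100 000 of the 0–74 standard
population — which makes the full-range ASMR the weight-sum-weighted
combination of the 0–74 and 75+ restricted rates. Percent changes are
rounded to whole percent, halves away from zero. A band with zero
population and zero deaths contributes a zero rate; zero population with
deaths is an error naming the band.

## Life tables

Rates `m_x = D_x/E_x` are estimated from ages 0–89 with mid-year counts as
exposure. Ages 90–110 use the Kannisto–Makeham law fitted by Poisson
maximum likelihood over ages 70–89 (the widest old-age window wholly below
the extrapolation region; configurable), with the hazard evaluated at
mid-interval ages x + 0.5 and the age offset at the window's lower end.
Optimisation is L-BFGS-B over (log a, log b, log c) from a 12-point start
grid, keeping the best optimum; if every start fails, a pure Kannisto law
(c = 0) is fitted and the result flagged. The Makeham constant c is nearly
collinear with the logistic level over a 20-age window: at exposures of
10⁶ person-years per age its maximum-likelihood sampling error is ≈ 8%
relative (vs < 1% for a and b), so c should be read as a nuisance
parameter; the fitted hazard curve itself, and hence the extrapolated
rates, are tight (within 2% of a generating law at ages 90–110 in the
parameter-recovery tests).

Conversion uses `q_x = m_x/(1 + (1−a_x)m_x)` capped at 1, with a_x = 0.5
everywhere except a₀ = 0.1 (infant deaths cluster early in the first year);
both are configurable arguments of `build_lifetable`. Age 110 is an open
interval with q = 1, so `Σ d_x = l₀` identically.

Cause splits: `d_{x,i} = d_x · D_{x,i}/D_x`. Ages ≥ 90 all use the pooled
observed cause mix of deaths at 90+, keeping extrapolated-age cause totals
anchored to data rather than to unobserved single-year splits; a younger
age with no deaths borrows the pooled mix of ages x−2…x+2, widening
symmetrically until non-empty. Life expectancy columns and abridged tables
are out of scope.

## Diversity

Hill numbers on the decrement distribution (real-valued abundances, no
rounding), with zero-mass causes dropped (0·log 0 := 0). q = 1 uses the
exact exponential-of-Shannon form rather than a numerical limit. Only
per-subcommunity (normalised alpha) values are computed; metacommunity
aggregation and similarity-sensitive diversity are out of scope. Both
life-table and raw observed-count sources are reported, since the two give
qualitatively similar trends but the life-table source removes
population-structure effects.

## Trends and pipeline

OLS by the closed-form normal equations with R² = 1 − SSE/SST (R² defined
as 0 when the response is constant); no standard errors — the lines are
descriptive. The subcommunity grid composes independently switchable sex
and quintile groupings over years and age ranges (defaults 0–74 and 75+,
q ∈ {0, 1}); life tables are fitted sex-specific within each quintile. A
manifest (configuration, package version, per-stage row counts) is written
with every run directory, and outputs are byte-stable under a fixed seed.

## Problem sizes

The analysis scripts use a ~540 000-person scenario (100 zones × mean
5 000); the replicated trend-direction checks use twenty seeds of a
1 000 000-person scenario, each fitting 38 hazard laws (19 years × 2
sexes). These sizes keep a full run to minutes on a single core while
leaving per-stratum death counts (hundreds to thousands per year) large
enough that sampling noise does not mask the trends being measured.

## Known limitations

- The generator's cause distributions shift only through the leading-share
  interpolation; real cause-specific dynamics (new causes appearing, coding
  changes) are not represented.
- Quintile assignments are static within a run; studies spanning index
  revisions would re-assign part-way (the pipeline accepts any zones table,
  so this is a matter of running twice and splicing).
- ASMR uncertainty intervals are not computed.
- The Kannisto–Makeham c parameter is weakly identified from 20 ages of
  data, as quantified above.
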
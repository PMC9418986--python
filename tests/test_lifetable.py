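"""Life-table construction, hazard-law fitting and cause decrements."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mortdiv.lifetable import (
    MAX_AGE,
    RADIX,
    AgeRateSchedule,
    KannistoMakehamParams,
    build_lifetable,
    build_multidecrement,
    cause_distribution,
    combine_rates,
    estimate_rates,
    extrapolate_rates,
    fit_kannisto_makeham,
    poisson_loglik,
)

TRUE = dict(a=0.08, b=0.11, c=0.01)


def km_schedule(rng, exposure=1e6, true=TRUE, ages=(70, 89)):
    """Poisson death counts from a known Kannisto-Makeham law."""
    lo, hi = ages
    xs = np.arange(MAX_AGE + 1)
    params = KannistoMakehamParams(age_offset=lo, **true)
    mu = np.asarray(params.hazard(xs + 0.5))
    E = np.zeros(MAX_AGE + 1)
    E[lo : hi + 1] = exposure
    D = np.zeros(MAX_AGE + 1)
    D[lo : hi + 1] = rng.poisson(E[lo : hi + 1] * mu[lo : hi + 1])
    return AgeRateSchedule(ages=xs, deaths=D, exposure=E), params


class TestEstimateRates:
    def test_simple_ratio_and_scale_invariance(self):
        deaths = pd.DataFrame({"age": [40] * 10, "cause": ["C00"] * 10})
        pop = pd.DataFrame({"age": np.arange(90), "count": 1000})
        sched = estimate_rates(deaths, pop)
        assert sched.m[40] == pytest.approx(0.01)
        pop2 = pop.assign(count=pop["count"] * 2)
        deaths2 = pd.concat([deaths] * 2, ignore_index=True)
        assert estimate_rates(deaths2, pop2).m[40] == pytest.approx(0.01)

    def test_zero_deaths_gives_zero_rates(self):
        deaths = pd.DataFrame({"age": [], "cause": []})
        pop = pd.DataFrame({"age": np.arange(90), "count": 100})
        assert (estimate_rates(deaths, pop).m == 0).all()

    def test_deaths_without_exposure_rejected(self):
        deaths = pd.DataFrame({"age": [40], "cause": ["C00"]})
        pop = pd.DataFrame({"age": [0], "count": [100]})
        with pytest.raises(ValueError, match="zero exposure"):
            estimate_rates(deaths, pop)


class TestKannistoMakehamFit:
    def test_parameter_recovery(self, rng):
        sched, _ = km_schedule(rng)
        fit = fit_kannisto_makeham(sched)
        for name in ("a", "b", "c"):
            assert abs(getattr(fit, name) - TRUE[name]) / TRUE[name] < 0.10

    def test_makeham_only_limit(self, rng):
        """Constant-hazard data: fitted hazard within 1% of c over the window."""
        c = 0.02
        xs = np.arange(MAX_AGE + 1)
        E = np.zeros(MAX_AGE + 1)
        E[70:90] = 1e7
        D = np.zeros(MAX_AGE + 1)
        D[70:90] = rng.poisson(E[70:90] * c)
        sched = AgeRateSchedule(ages=xs, deaths=D, exposure=E)
        fit = fit_kannisto_makeham(sched)
        mu = np.asarray(fit.hazard(np.arange(70, 90) + 0.5))
        assert np.all(np.abs(mu - c) / c < 0.01)

    def test_fit_beats_every_grid_start(self, rng):
        sched, _ = km_schedule(rng, exposure=1e4)
        fit = fit_kannisto_makeham(sched)
        ll_fit = poisson_loglik(fit, sched)
        for a0 in (0.005, 0.05, 0.3):
            for b0 in (0.05, 0.13):
                for c0 in (1e-4, 1e-2):
                    start = KannistoMakehamParams(a=a0, b=b0, c=c0, age_offset=70)
                    assert ll_fit >= poisson_loglik(start, sched) - 1e-6

    def test_all_zero_deaths_rejected(self):
        xs = np.arange(MAX_AGE + 1)
        E = np.zeros(MAX_AGE + 1)
        E[70:90] = 1000
        sched = AgeRateSchedule(ages=xs, deaths=np.zeros(MAX_AGE + 1), exposure=E)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_kannisto_makeham(sched)


class TestExtrapolation:
    def test_constant_when_logistic_term_absent(self):
        p = KannistoMakehamParams(a=0.0, b=0.1, c=0.05, age_offset=70)
        ext = extrapolate_rates(p)
        assert np.allclose(ext.m, 0.05)

    def test_monotone_and_bounded(self):
        p = KannistoMakehamParams(a=0.05, b=0.12, c=0.01, age_offset=70)
        ext = extrapolate_rates(p)
        assert np.all(np.diff(ext.m) >= 0)
        assert np.all((ext.m >= p.c) & (ext.m < p.c + 1))
        assert ext.m[-1] > ext.m[0]

    def test_logistic_asymptote(self):
        p = KannistoMakehamParams(a=0.05, b=0.12, c=0.01, age_offset=70)
        assert p.hazard(10_000.0) == pytest.approx(p.c + 1.0, rel=1e-12)

    def test_fit_then_extrapolate_tracks_true_law(self, rng):
        """Extrapolated rates within 2% of the generating hazard at 90-110."""
        sched, true_params = km_schedule(rng)
        fit = fit_kannisto_makeham(sched)
        ext = extrapolate_rates(fit)
        truth = np.asarray(true_params.hazard(ext.ages + 0.5))
        assert np.all(np.abs(ext.m - truth) / truth < 0.02)


class TestLifeTable:
    def test_no_mortality_until_closure(self):
        lt = build_lifetable(np.zeros(MAX_AGE + 1))
        assert np.all(lt.l == RADIX)
        assert lt.d[:-1].sum() == 0
        assert lt.d[-1] == RADIX

    def test_q_conversion_hand_value(self):
        m = np.full(MAX_AGE + 1, 0.1)
        lt = build_lifetable(m, a0=0.5)
        assert lt.q[50] == pytest.approx(0.1 / 1.05)
        assert lt.q[50] == pytest.approx(0.095238, abs=1e-6)

    def test_constant_hazard_closed_form(self):
        m = np.full(MAX_AGE + 1, 0.03)
        lt = build_lifetable(m, a0=0.5)
        q = 0.03 / (1 + 0.5 * 0.03)
        expect = RADIX * (1 - q) ** np.arange(MAX_AGE + 1)
        assert np.allclose(lt.l, expect, rtol=1e-12)

    def test_negative_rates_rejected(self):
        m = np.zeros(MAX_AGE + 1)
        m[3] = -0.1
        with pytest.raises(ValueError, match="negative"):
            build_lifetable(m)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_for_random_schedules(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 0.5, MAX_AGE + 1)
        lt = build_lifetable(m)
        assert lt.d.sum() == pytest.approx(RADIX, rel=1e-6)
        assert np.all(np.diff(lt.l) <= 1e-9)
        assert np.all((lt.q >= 0) & (lt.q <= 1))


class TestMultiDecrement:
    @staticmethod
    def lifetable():
        return build_lifetable(np.full(MAX_AGE + 1, 0.05))

    def test_single_cause_takes_all(self):
        lt = self.lifetable()
        deaths = pd.DataFrame({"age": np.arange(0, 111, 5), "cause": "C00"})
        mdlt = build_multidecrement(lt, deaths)
        assert np.allclose(mdlt.decrements[:, 0], lt.d)

    def test_equal_causes_split_evenly(self):
        lt = self.lifetable()
        ages = np.repeat(np.arange(MAX_AGE + 1), 2)
        deaths = pd.DataFrame({"age": ages, "cause": ["A00", "B00"] * (MAX_AGE + 1)})
        mdlt = build_multidecrement(lt, deaths)
        assert np.allclose(mdlt.decrements[:, 0], mdlt.decrements[:, 1])
        assert np.allclose(mdlt.decrements.sum(axis=1), lt.d, rtol=1e-9)

    def test_decrement_conservation(self, rng):
        lt = self.lifetable()
        n = 5000
        deaths = pd.DataFrame(
            {"age": rng.integers(0, 111, n),
             "cause": rng.choice(["A00", "B01", "C02", "D03"], n)}
        )
        mdlt = build_multidecrement(lt, deaths)
        assert np.allclose(mdlt.decrements.sum(axis=1), lt.d, rtol=1e-9)
        assert mdlt.decrements.sum() == pytest.approx(RADIX, rel=1e-6)
        assert np.all(mdlt.decrements >= 0)

    def test_old_ages_use_pooled_mix(self, rng):
        """Above the pooling age every cause split equals the pooled 90+ mix."""
        lt = self.lifetable()
        young = pd.DataFrame({"age": rng.integers(0, 90, 2000),
                              "cause": rng.choice(["A00", "B01"], 2000)})
        old = pd.DataFrame({"age": rng.integers(90, 111, 900),
                            "cause": rng.choice(["A00", "B01"], 900, p=[0.8, 0.2])})
        deaths = pd.concat([young, old], ignore_index=True)
        mdlt = build_multidecrement(lt, deaths)
        pooled = old["cause"].value_counts(normalize=True)
        for x in range(90, MAX_AGE + 1):
            frac = mdlt.decrements[x, mdlt.causes.index("A00")] / lt.d[x]
            assert frac == pytest.approx(pooled["A00"])

    def test_empty_ages_borrow_neighbours(self):
        lt = self.lifetable()
        deaths = pd.DataFrame({"age": [40, 44], "cause": ["A00", "B01"]})
        mdlt = build_multidecrement(lt, deaths)
        # age 42 has no deaths: borrows the 40-44 pooled 50/50 mix
        assert mdlt.decrements[42, 0] == pytest.approx(mdlt.decrements[42, 1])

    def test_no_deaths_rejected(self):
        with pytest.raises(ValueError, match="no observed deaths"):
            build_multidecrement(self.lifetable(), pd.DataFrame({"age": [], "cause": []}))


class TestCauseDistribution:
    @staticmethod
    def mdlt(rng):
        lt = build_lifetable(np.full(MAX_AGE + 1, 0.05))
        deaths = pd.DataFrame(
            {"age": rng.integers(0, 111, 4000),
             "cause": rng.choice(["A00", "B01", "C02"], 4000)}
        )
        return build_multidecrement(lt, deaths)

    def test_full_range_mass_is_radix(self, rng):
        dist = cause_distribution(self.mdlt(rng))
        assert dist.sum() == pytest.approx(RADIX, rel=1e-6)

    def test_disjoint_ranges_are_additive(self, rng):
        mdlt = self.mdlt(rng)
        full = cause_distribution(mdlt, (0, 110))
        young = cause_distribution(mdlt, (0, 74))
        old = cause_distribution(mdlt, (75, 110))
        combined = young.add(old, fill_value=0.0)
        pd.testing.assert_series_equal(full, combined, check_names=False)

    def test_invalid_range_rejected(self, rng):
        with pytest.raises(ValueError):
            cause_distribution(self.mdlt(rng), (80, 20))
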
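"""End-to-end orchestration: registry tables to diversity and trend tables.

The subcommunity grid is years x sexes x quintiles x age ranges, with sexes
and quintiles switchable independently: the default analyses are by sex for
the whole population and, when quintiles are switched on, by sex within
each deprivation quintile.  Every stage is deterministic given the scenario
seed; a manifest records the configuration and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import __version__
from .deprivation import QuintileAssignment, assign_quintiles
from .diversity import hill_diversity
from .lifetable import DEFAULT_FIT_AGES, MAX_AGE, stratum_lifetable, cause_distribution
from .standardise import asmr, load_esp2013
from .synthetic import Datazone, ScenarioConfig, generate_scenario, zones_frame
from .trends import fit_trend

logger = logging.getLogger(__name__)

AGE_RANGE_LABELS = {(0, 74): "0-74", (75, MAX_AGE): "75+", (0, MAX_AGE): "0-110"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenario: ScenarioConfig | None = None  # simulate when set
    input_dir: Path | None = None  # otherwise read zones/population/deaths CSVs
    q_values: tuple[float, ...] = (0.0, 1.0)
    age_ranges: tuple[tuple[int, int], ...] = ((0, 74), (75, MAX_AGE))
    by_sex: bool = True
    by_quintile: bool = False
    fit_ages: tuple[int, int] = DEFAULT_FIT_AGES
    out_dir: Path | None = None
    write_lifetables: bool = False

    def __post_init__(self) -> None:
        if not self.q_values:
            raise ValueError("at least one viewpoint q is required")
        for (lo1, hi1) in self.age_ranges:
            for (lo2, hi2) in self.age_ranges:
                if (lo1, hi1) < (lo2, hi2) and hi1 >= lo2 and hi2 >= lo1:
                    raise ValueError(f"age ranges overlap: ({lo1},{hi1}) and ({lo2},{hi2})")
        if self.scenario is None and self.input_dir is None:
            raise ValueError("either a scenario or an input directory is required")


@dataclass
class PipelineResult:
    zones: list[Datazone]
    population: pd.DataFrame
    deaths: pd.DataFrame
    quintiles: QuintileAssignment
    asmr: pd.DataFrame  # year, sex, quintile, age_range, cause, asmr
    diversity: pd.DataFrame  # year, sex, quintile, age_range, q, value, source
    trends: pd.DataFrame  # subcommunity, predictor, slope, intercept, r_squared, n_points
    lifetables: dict  # (year, sex, quintile) -> MultiDecrementLifeTable
    manifest: dict


def _load_inputs(input_dir: Path) -> tuple[list[Datazone], pd.DataFrame, pd.DataFrame]:
    zt = pd.read_csv(input_dir / "zones.csv")
    zones = [
        Datazone(zone_id=str(r.zone_id), income_rate=float(r.income_rate),
                 base_population=int(r.base_population))
        for r in zt.itertuples()
    ]
    population = pd.read_csv(input_dir / "population.csv")
    deaths = pd.read_csv(input_dir / "deaths.csv")
    return zones, population, deaths


def _age_label(age_range: tuple[int, int]) -> str:
    return AGE_RANGE_LABELS.get(tuple(age_range), f"{age_range[0]}-{age_range[1]}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute simulate -> quintiles -> ASMR -> life tables -> diversity -> trends."""
    if config.scenario is not None:
        zones, population, deaths = generate_scenario(config.scenario)
    else:
        zones, population, deaths = _load_inputs(Path(config.input_dir))

    try:
        quintiles = assign_quintiles(zones)
    except ValueError as err:
        raise RuntimeError(f"stage quintiles failed: {err}") from err
    zone_q = quintiles.quintile
    deaths = deaths.assign(quintile=deaths["zone_id"].map(zone_q))
    population = population.assign(quintile=population["zone_id"].map(zone_q))

    sexes: list[str] = ["female", "male"] if config.by_sex else ["all"]
    qgroups: list = [1, 2, 3, 4, 5] if config.by_quintile else ["all"]
    years = sorted(population["year"].unique())
    standard = load_esp2013()

    asmr_rows = []
    div_rows = []
    lifetables = {}
    for qg in qgroups:
        d_q = deaths if qg == "all" else deaths[deaths["quintile"] == qg]
        p_q = population if qg == "all" else population[population["quintile"] == qg]
        for sex in sexes:
            d_s = d_q if sex == "all" else d_q[d_q["sex"] == sex]
            p_s = p_q if sex == "all" else p_q[p_q["sex"] == sex]
            for year in years:
                d = d_s[d_s["year"] == year]
                p = p_s[p_s["year"] == year]
                stratum = (int(year), sex, qg)
                try:
                    mdlt, params = stratum_lifetable(d, p, fit_ages=config.fit_ages)
                except (ValueError, RuntimeError) as err:
                    raise RuntimeError(f"stage lifetable failed for stratum {stratum}: {err}") from err
                lifetables[stratum] = mdlt
                for age_range in config.age_ranges:
                    label = _age_label(age_range)
                    try:
                        rate = asmr(d, p, standard, age_range=age_range)
                    except ValueError as err:
                        raise RuntimeError(f"stage asmr failed for stratum {stratum}: {err}") from err
                    asmr_rows.append((year, sex, qg, label, "all", rate))
                    lt_dist = cause_distribution(mdlt, age_range)
                    lo, hi = age_range
                    obs = d[(d["age"] >= lo) & (d["age"] <= hi)]["cause"].value_counts()
                    for q in config.q_values:
                        div_rows.append((year, sex, qg, label, q,
                                         hill_diversity(lt_dist, q), "lifetable"))
                        if len(obs):
                            div_rows.append((year, sex, qg, label, q,
                                             hill_diversity(obs, q), "observed"))

    asmr_tab = pd.DataFrame(
        asmr_rows, columns=["year", "sex", "quintile", "age_range", "cause", "asmr"]
    )
    div_tab = pd.DataFrame(
        div_rows, columns=["year", "sex", "quintile", "age_range", "q", "value", "source"]
    )

    trend_rows = []
    lt_div = div_tab[div_tab["source"] == "lifetable"]
    for (sex, qg, label, q), grp in lt_div.groupby(["sex", "quintile", "age_range", "q"], sort=True):
        grp = grp.sort_values("year")
        if len(grp) < 3:
            continue
        sub = f"{sex}|quintile={qg}|ages={label}|q={q:g}"
        t = fit_trend(grp["year"], grp["value"], predictor="year")
        trend_rows.append((sub, "year", t.slope, t.intercept, t.r_squared, t.n_points))
        rates = asmr_tab[
            (asmr_tab["sex"] == sex) & (asmr_tab["quintile"] == qg)
            & (asmr_tab["age_range"] == label) & (asmr_tab["cause"] == "all")
        ].sort_values("year")
        merged = grp.merge(rates[["year", "asmr"]], on="year")
        t = fit_trend(merged["asmr"], merged["value"], predictor="asmr")
        trend_rows.append((sub, "asmr", t.slope, t.intercept, t.r_squared, t.n_points))
    trend_tab = pd.DataFrame(
        trend_rows,
        columns=["subcommunity", "predictor", "slope", "intercept", "r_squared", "n_points"],
    )

    manifest = {
        "package_version": __version__,
        "config": _manifest_config(config),
        "rows": {
            "zones": len(zones),
            "population": int(len(population)),
            "deaths": int(len(deaths)),
            "asmr": int(len(asmr_tab)),
            "diversity": int(len(div_tab)),
            "trends": int(len(trend_tab)),
        },
    }

    result = PipelineResult(
        zones=zones, population=population, deaths=deaths, quintiles=quintiles,
        asmr=asmr_tab, diversity=div_tab, trends=trend_tab,
        lifetables=lifetables, manifest=manifest,
    )
    if config.out_dir is not None:
        write_outputs(result, Path(config.out_dir), config)
    return result


def _manifest_config(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    if out.get("scenario"):
        out["scenario"] = dataclasses.asdict(config.scenario)
    for key in ("input_dir", "out_dir"):
        if out.get(key) is not None:
            out[key] = str(out[key])
    out["age_ranges"] = [list(r) for r in config.age_ranges]
    out["q_values"] = list(config.q_values)
    out["fit_ages"] = list(config.fit_ages)
    return out


def write_outputs(result: PipelineResult, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    zones_frame(result.zones).to_csv(out_dir / "zones.csv", index=False)
    result.population.drop(columns=["quintile"]).to_csv(out_dir / "population.csv", index=False)
    result.deaths.drop(columns=["quintile"]).to_csv(out_dir / "deaths.csv", index=False)
    result.quintiles.frame().to_csv(out_dir / "quintiles.csv", index=False)
    result.asmr.to_csv(out_dir / "asmr.csv", index=False)
    result.diversity.to_csv(out_dir / "diversity.csv", index=False)
    result.trends.to_csv(out_dir / "trends.csv", index=False)
    if config.write_lifetables:
        lt_dir = out_dir / "lifetables"
        lt_dir.mkdir(exist_ok=True)
        for (year, sex, qg), mdlt in result.lifetables.items():
            stem = f"{year}_{sex}_q{qg}"
            mdlt.table.frame().to_csv(lt_dir / f"lifetable_{stem}.csv", index=False)
            mdlt.frame().to_csv(lt_dir / f"decrements_{stem}.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
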
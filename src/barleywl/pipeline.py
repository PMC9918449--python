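"""Genotype x environment x management x climate factorial pipeline.

Runs every design cell (site, genotype, sowing, scenario, realisation,
season-year) through the simulator in paired modes — waterlogging
physiology on and off on identical inputs — and derives the analysis
quantities:

* **yield loss** (%) between a control and a waterlogged treatment,
  100 * (Yield_ck - Yield_wl) / Yield_ck;
* **yield penalty** (%) attributable to waterlogging physiology,
  100 * (Yield_default - Yield_wl) / Yield_default, zero on any season
  without saturated days;
* the k-means stress typology over the pooled waterlogging-mode
  trajectories, with per-period pattern recurrence frequencies and a
  one-way ANOVA + LSD test of frequency shifts between climate periods;
* the yield benefit of waterlogging-tolerant over susceptible genotypes,
  evaluated in wet season-years (growing-season rainfall above a
  percentile, default the 90th) and, as a check that tolerance carries no
  cost, in the remaining drier years.

Climate projection spread is represented by independent stochastic weather
realisations (default 27, standing in for a 27-member GCM ensemble), each
with a seed derived from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crop import Genotype, Management, SeasonResult, simulate_season
from .soil import SoilProfile, generate_soil
from .typology import (
    DEFAULT_BINS,
    StressTypology,
    fit_typology,
    label_clusters,
    pattern_frequencies,
    phase_stress_vector,
)
from .weather import (
    ClimateDeltas,
    WeatherGenParams,
    WeatherSeries,
    apply_climate_deltas,
    co2_for_year,
    generate_weather,
)

__all__ = [
    "Site",
    "Scenario",
    "FactorialDesign",
    "FactorialResult",
    "yield_loss_pct",
    "yield_penalty_pct",
    "run_factorial",
    "frequency_shift_test",
    "tolerance_benefit",
]


def yield_loss_pct(yield_ck: float, yield_wl: float) -> float:
    """Percentage yield loss of a waterlogged treatment against its
    control: 100 * (Yield_ck - Yield_wl) / Yield_ck. Negative if the
    waterlogged run out-yields the control; undefined for a zero control."""
    if not yield_ck > 0:
        raise ValueError("yield_ck must be > 0")
    return 100.0 * (yield_ck - yield_wl) / yield_ck


def yield_penalty_pct(yield_default: float, yield_wl: float) -> float:
    """Percentage yield difference between the no-waterlogging-physics run
    and the waterlogging-enabled run on identical inputs:
    100 * (Yield_default - Yield_wl) / Yield_default."""
    if not yield_default > 0:
        raise ValueError("yield_default must be > 0")
    return 100.0 * (yield_default - yield_wl) / yield_default


@dataclass(frozen=True)
class Site:
    name: str
    soil_archetype: str
    weather_params: WeatherGenParams
    latitude: float = -41.0


@dataclass(frozen=True)
class Scenario:
    """A climate period: delta-change factors plus a CO2 horizon offset
    (years added to each simulation year before evaluating the CO2 curve)."""

    name: str = "baseline"
    deltas: ClimateDeltas = field(default_factory=ClimateDeltas)
    co2_year_offset: int = 0


@dataclass
class FactorialDesign:
    sites: list[Site]
    genotypes: list[Genotype]
    sowing_doys: dict[str, int]  # tag (ES/LS) -> day of year
    scenarios: list[Scenario]
    n_realisations: int = 27
    n_years: int = 10
    start_year: int = 1990
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_realisations < 1 or self.n_years < 1:
            raise ValueError("n_realisations and n_years must be >= 1")
        if not (self.sites and self.genotypes and self.sowing_doys and self.scenarios):
            raise ValueError("every factorial dimension needs at least one level")


@dataclass
class FactorialResult:
    table: pd.DataFrame  # one row per (site, genotype, sowing, scenario, realisation, year)
    typologies: dict[str, StressTypology]  # per maturity class
    design: FactorialDesign


def _realisation_seed(master_seed: int, site_idx: int, real_idx: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(site_idx, real_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def run_factorial(design: FactorialDesign) -> FactorialResult:
    """Simulate the full factorial and fit the stress typology.

    For every cell and season-year three runs share identical weather:
    the default mode (waterlogging functions pinned to 1), the
    waterlogging mode on the cell's soil, and the waterlogging mode on a
    freely drained control soil (the simulation analogue of a drained
    control treatment). Incomplete seasons are kept in the table flagged
    ``complete=False`` and excluded from clustering. Fully reproducible
    from the master seed.
    """
    rows = []
    trajectories: dict[str, list[np.ndarray]] = {"spring": [], "winter": []}
    traj_keys: dict[str, list[int]] = {"spring": [], "winter": []}
    control_soils: dict[str, SoilProfile] = {}

    for s_idx, site in enumerate(design.sites):
        soil = generate_soil(site.soil_archetype, seed=_realisation_seed(design.master_seed, s_idx, 10_000))
        control_soils[site.name] = generate_soil(
            "freely_drained", seed=_realisation_seed(design.master_seed, s_idx, 20_000)
        )
        for r_idx in range(design.n_realisations):
            seed = _realisation_seed(design.master_seed, s_idx, r_idx)
            params = WeatherGenParams(**{**site.weather_params.__dict__, "seed": seed})
            base = generate_weather(
                params, design.n_years + 1, design.start_year,
                site_id=site.name, latitude=site.latitude,
            )
            for scenario in design.scenarios:
                co2_map = {
                    y: co2_for_year(
                        int(np.clip(y + scenario.co2_year_offset, 1900, 2100))
                    )
                    for y in base.co2_ppm_by_year
                }
                wx = apply_climate_deltas(
                    base, scenario.deltas, scenario.name, co2_ppm_by_year=co2_map
                )
                for geno in design.genotypes:
                    for sow_tag, sow_doy in design.sowing_doys.items():
                        mgmt = Management(sowing_doy=sow_doy, sowing_window_tag=sow_tag)
                        for year in range(
                            design.start_year, design.start_year + design.n_years
                        ):
                            res_def = simulate_season(
                                wx, soil, geno, mgmt, sowing_year=year,
                                waterlogging_on=False,
                            )
                            res_wl = simulate_season(
                                wx, soil, geno, mgmt, sowing_year=year,
                                waterlogging_on=True,
                            )
                            res_ck = simulate_season(
                                wx, control_soils[site.name], geno, mgmt,
                                sowing_year=year, waterlogging_on=True,
                            )
                            row = {
                                "site": site.name,
                                "genotype": geno.name,
                                "maturity_class": geno.maturity_class,
                                "photo_floor": geno.photo_floor,
                                "sowing": sow_tag,
                                "scenario": scenario.name,
                                "realisation": r_idx,
                                "year": year,
                                "yield_default": res_def.yield_kg_ha,
                                "yield_wl": res_wl.yield_kg_ha,
                                "yield_ck": res_ck.yield_kg_ha,
                                "waterlogged_days": res_wl.waterlogged_days,
                                "growing_season_rain": res_def.growing_season_rain,
                                "complete": bool(res_def.complete and res_wl.complete),
                                "flowering_doy": res_wl.flowering_doy,
                            }
                            if row["complete"] and row["yield_default"] > 0:
                                row["yield_penalty_pct"] = yield_penalty_pct(
                                    row["yield_default"], row["yield_wl"]
                                )
                            else:
                                row["yield_penalty_pct"] = np.nan
                            if (
                                row["complete"]
                                and res_ck.complete
                                and row["yield_ck"] > 0
                            ):
                                row["yield_loss_pct"] = yield_loss_pct(
                                    row["yield_ck"], row["yield_wl"]
                                )
                            else:
                                row["yield_loss_pct"] = np.nan
                            rows.append(row)
                            if res_wl.complete:
                                vec, _ = phase_stress_vector(res_wl.daily)
                                if not np.isnan(vec).any():
                                    trajectories[geno.maturity_class].append(vec)
                                    traj_keys[geno.maturity_class].append(len(rows) - 1)

    table = pd.DataFrame(rows)
    table["pattern"] = pd.NA
    typologies: dict[str, StressTypology] = {}
    for mat_class, vecs in trajectories.items():
        if len(vecs) >= 4:
            typ = fit_typology(np.array(vecs), k=4, seed=design.master_seed)
            label_clusters(typ, mat_class)
            typologies[mat_class] = typ
            labels = typ.labelled_assignments()
            table.loc[traj_keys[mat_class], "pattern"] = labels
    return FactorialResult(table=table, typologies=typologies, design=design)


def frequency_shift_test(
    freqs: pd.DataFrame,
    period_col: str = "scenario",
    value_col: str = "percent",
    pattern_col: str = "pattern",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of pattern frequencies across climate periods with an
    LSD post-hoc grouping.

    ``freqs`` carries one frequency value per (pattern, period,
    realisation). For each pattern, periods are compared by ANOVA with
    realisations as replicates, then grouped by least-significant-
    difference letters (descending means; periods sharing a letter do not
    differ at ``alpha``). Patterns with zero variance everywhere are
    flagged skipped.
    """
    out = []
    for pattern, grp in freqs.groupby(pattern_col):
        groups = [g[value_col].to_numpy(dtype=float) for _, g in grp.groupby(period_col)]
        period_names = [name for name, _ in grp.groupby(period_col)]
        means = [float(np.mean(g)) for g in groups]
        if len(groups) < 2 or min(len(g) for g in groups) < 2:
            raise ValueError("need >= 2 periods with >= 2 replicates each")
        if all(np.allclose(g, g[0]) for g in groups) and np.allclose(means, means[0]):
            out.append(
                {pattern_col: pattern, "F": np.nan, "p": np.nan, "skipped": True,
                 "letters": {p: "a" for p in period_names}}
            )
            continue
        F, p = stats.f_oneway(*groups)
        letters = _lsd_letters(groups, period_names, alpha)
        out.append(
            {pattern_col: pattern, "F": float(F), "p": float(p), "skipped": False,
             "letters": letters}
        )
    return pd.DataFrame(out)


def _lsd_letters(
    groups: list[np.ndarray], names: list[str], alpha: float
) -> dict[str, str]:
    """Letter display from pairwise LSD tests on the pooled error term."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df_err = n_total - k
    means = np.array([np.mean(g) for g in groups])
    mse = (
        sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err if df_err > 0 else 0.0
    )
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_err) if df_err > 0 else np.inf

    def differ(i: int, j: int) -> bool:
        lsd = tcrit * np.sqrt(mse * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        return abs(means[i] - means[j]) > lsd

    order = np.argsort(-means)  # descending means
    # standard insert-and-absorb letter assignment
    groups_of: list[set[int]] = []
    for idx in order:
        placed = False
        for g in groups_of:
            if all(not differ(idx, other) for other in g):
                g.add(int(idx))
                placed = True
        if not placed:
            groups_of.append({int(idx)})
    # drop letter-groups fully contained in another
    groups_of = [
        g for g in groups_of
        if not any(g < h for h in groups_of)
    ]
    letters: dict[str, str] = {n: "" for n in names}
    for li, g in enumerate(groups_of):
        ch = chr(ord("a") + li)
        for idx in sorted(g):
            letters[names[idx]] += ch
    return letters


def tolerance_benefit(
    table: pd.DataFrame,
    tolerant: str,
    susceptible: str,
    rainfall_percentile: float = 90.0,
) -> pd.DataFrame:
    """Yield benefit of a tolerant genotype over its susceptible pair.

    Season-years are matched on (site, sowing, scenario, realisation,
    year); within each (site, sowing, scenario) cell the growing-season
    rainfall percentile splits wet from drier years. Reports mean +/- SEM
    benefit (kg/ha and % of the susceptible yield) for wet years, drier
    years and all years. A 100th-percentile threshold leaves the wet set
    empty; such cells are flagged rather than dropped.
    """
    keys = ["site", "sowing", "scenario", "realisation", "year"]
    tol = table[(table["genotype"] == tolerant) & table["complete"]]
    sus = table[(table["genotype"] == susceptible) & table["complete"]]
    if len(tol) == 0 or len(sus) == 0:
        raise ValueError("tolerant/susceptible pair not found in results")
    merged = tol.merge(sus, on=keys, suffixes=("_tol", "_sus"))
    merged["benefit"] = merged["yield_wl_tol"] - merged["yield_wl_sus"]
    merged["benefit_pct"] = 100.0 * merged["benefit"] / merged["yield_wl_sus"]
    out = []
    for (site, sowing, scen), grp in merged.groupby(["site", "sowing", "scenario"]):
        thresh = np.percentile(grp["growing_season_rain_sus"], rainfall_percentile)
        wet = grp[grp["growing_season_rain_sus"] > thresh]
        dry = grp[grp["growing_season_rain_sus"] <= thresh]
        rec = {
            "site": site,
            "sowing": sowing,
            "scenario": scen,
            "rain_threshold_mm": float(thresh),
            "n_wet": len(wet),
            "n_dry": len(dry),
            "wet_empty": len(wet) == 0,
        }
        for tag, sub in (("wet", wet), ("dry", dry), ("all", grp)):
            if len(sub) == 0:
                rec[f"benefit_{tag}_kg_ha"] = np.nan
                rec[f"benefit_{tag}_sem"] = np.nan
                rec[f"benefit_{tag}_pct"] = np.nan
            else:
                rec[f"benefit_{tag}_kg_ha"] = float(sub["benefit"].mean())
                rec[f"benefit_{tag}_sem"] = float(
                    sub["benefit"].std(ddof=1) / np.sqrt(len(sub))
                ) if len(sub) > 1 else 0.0
                rec[f"benefit_{tag}_pct"] = float(sub["benefit_pct"].mean())
        out.append(rec)
    return pd.DataFrame(out)
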
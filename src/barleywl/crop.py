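"""Minimal daily barley simulator embedding the waterlogging stress model.

The season loop couples four sub-models:

* **Phenology** — thermal-time accumulation through eleven stages, gated
  pre-florally by vernalisation and photoperiod. On waterlogged days the
  daily thermal time is multiplied by an effective phenology factor built
  from the rtfr-driven index and the stage modifier: development slows
  before flowering and grain filling shortens after it.
* **Water balance** — tipping-bucket profile (see
  :mod:`barleywl.waterbalance`) giving per-layer saturation flags.
* **Waterlogging stress** — fraction of roots waterlogged drives the
  photosynthesis index through the three-stage response/adaptation model;
  root descent halts while the root zone is waterlogged.
* **Growth and yield** — radiation-use-efficiency biomass accumulation
  with a saturating CO2 fertilisation factor; yield is biomass at maturity
  times a potential harvest index discounted by mean photosynthetic stress
  over the reproductive window (kernel-set proxy).

The simulator can be run with the waterlogging functions pinned to 1
(``waterlogging_on=False``), reproducing a model without waterlogging
physiology on identical inputs; on a season with no saturated days the two
modes are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phenology as ph
from .phenology import PhaseTargets
from .soil import SoilProfile
from .stress import (
    DEFAULT_STRESS,
    StressParams,
    fraction_roots_waterlogged,
    oxdef_photo_factor,
    oxdef_pheno_factor,
    stage_modifier_pheno,
    stage_modifier_photo,
    three_stage_response,
)
from .waterbalance import potential_et, water_balance_step
from .weather import WeatherSeries

__all__ = [
    "Genotype",
    "Management",
    "SeasonResult",
    "daily_growth",
    "f_co2",
    "simulate_season",
    "SPRING_GENOTYPES",
    "WINTER_GENOTYPES",
]

#: Reproductive window (stage codes) over which photosynthetic stress
#: discounts the harvest index.
REPRO_WINDOW = (5.0, 7.0)

ROOT_DESCENT_RATE = 30.0  # mm/day while descending
COVER_STAGES = (1.0, 3.0, 4.5, 7.0, 9.0, 11.0)
COVER_VALUES = (0.0, 0.05, 0.9, 0.95, 0.4, 0.0)


@dataclass(frozen=True)
class Genotype:
    """Barley genotype: phenology plus waterlogging-tolerance parameters.

    ``vern_sens`` and ``photop_sens`` range 0-5 (higher = more sensitive);
    spring types use 1/1/400 for vern_sens/photop_sens/tt_end_of_juvenile,
    winter types 2.5-4 / 2.5-4 / 400-750. ``photo_floor`` is the
    post-adaptation photosynthesis multiplier under sustained waterlogging
    (1 = fully tolerant); ``lag_days`` and ``adapt_days`` are the durations
    of response stages one and two-to-three.
    """

    name: str
    maturity_class: str = "spring"  # "spring" | "winter"
    vern_sens: float = 1.0
    photop_sens: float = 1.0
    tt_end_of_juvenile: float = 400.0
    photo_floor: float = 0.5
    lag_days: float = 3.0
    adapt_days: float = 10.0
    rue: float = 1.2  # g biomass per MJ intercepted
    harvest_index_potential: float = 0.48
    base_temp: float = 0.0
    opt_temp: float = 26.0
    max_temp: float = 34.0

    def __post_init__(self) -> None:
        if self.maturity_class not in ("spring", "winter"):
            raise ValueError("maturity_class must be 'spring' or 'winter'")
        for nm in ("vern_sens", "photop_sens"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 5.0:
                raise ValueError(f"{nm} must lie in [0, 5]")
        if not 0.0 <= self.photo_floor <= 1.0:
            raise ValueError("photo_floor must lie in [0, 1]")

    @property
    def cardinals(self) -> tuple[float, float, float]:
        return (self.base_temp, self.opt_temp, self.max_temp)


SPRING_GENOTYPES = {
    "spring_susceptible": Genotype("spring_susceptible", "spring", 1.0, 1.0, 400.0, 0.5),
    "spring_tolerant": Genotype("spring_tolerant", "spring", 1.0, 1.0, 400.0, 1.0),
}
WINTER_GENOTYPES = {
    "winter_susceptible": Genotype("winter_susceptible", "winter", 2.5, 2.5, 500.0, 0.5),
    "winter_tolerant": Genotype("winter_tolerant", "winter", 2.5, 2.5, 500.0, 1.0),
    "winter_strong": Genotype("winter_strong", "winter", 4.0, 4.0, 750.0, 0.5),
}


@dataclass(frozen=True)
class Management:
    """Sowing and stand management (defaults: 180 plants m-2, 20 mm depth,
    200 mm rows, 15 mm initial plant-available water, no nitrogen limit)."""

    sowing_doy: int = 135
    sowing_window_tag: str = "ES"
    sowing_density: float = 180.0
    sowing_depth: float = 20.0
    row_spacing: float = 200.0
    initial_plant_available_water: float = 15.0
    nitrogen_limiting: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.sowing_doy <= 366:
            raise ValueError("sowing_doy must lie in [1, 366]")
        if self.nitrogen_limiting:
            raise NotImplementedError("nitrogen dynamics are out of scope")


@dataclass
class SeasonResult:
    """Outcome of one simulated season."""

    yield_kg_ha: float
    flowering_doy: int | None
    maturity_doy: int | None
    flowering_das: int | None  # days after sowing
    maturity_das: int | None
    waterlogged_days: int
    complete: bool
    daily: pd.DataFrame
    genotype: str
    sowing_year: int
    sowing_doy: int
    scenario_tag: str = "baseline"
    growing_season_rain: float = 0.0

    def summary(self) -> dict:
        return {
            "yield_kg_ha": self.yield_kg_ha,
            "flowering_doy": self.flowering_doy,
            "maturity_doy": self.maturity_doy,
            "flowering_das": self.flowering_das,
            "maturity_das": self.maturity_das,
            "waterlogged_days": self.waterlogged_days,
            "complete": self.complete,
            "genotype": self.genotype,
            "sowing_year": self.sowing_year,
            "sowing_doy": self.sowing_doy,
            "scenario_tag": self.scenario_tag,
            "growing_season_rain": round(self.growing_season_rain, 3),
        }


def f_co2(co2_ppm: float, k_half: float = 175.0, ref_ppm: float = 350.0) -> float:
    """Saturating C3 CO2 fertilisation factor, normalised to 1 at 350 ppm
    (rectangular hyperbola; about 1.2 at 700 ppm with the default half
    saturation of 175 ppm)."""
    if co2_ppm <= 0:
        raise ValueError("co2_ppm must be > 0")
    return (co2_ppm / (co2_ppm + k_half)) / (ref_ppm / (ref_ppm + k_half))


def canopy_cover(stage: float) -> float:
    """Fraction of radiation intercepted, a stage-driven canopy curve."""
    return float(np.interp(stage, COVER_STAGES, COVER_VALUES))


def daily_growth(
    radn: float, cover: float, rue: float, co2_ppm: float, eff_photo_multiplier: float
) -> float:
    """Daily biomass increment (g m-2): intercepted radiation times RUE,
    scaled by CO2 fertilisation and the effective photosynthesis stress
    multiplier."""
    if min(radn, cover, rue, eff_photo_multiplier) < 0:
        raise ValueError("growth inputs must be >= 0")
    return radn * cover * rue * f_co2(co2_ppm) * eff_photo_multiplier


def _effective_pheno_multiplier(
    rtfr: float, stage: float, params: StressParams
) -> float:
    """Thermal-time multiplier on a waterlogged day.

    The stage modifier sets the full-saturation endpoint (0.65-0.95 delay
    pre-flowering, 1.0-1.5 truncation post-flowering) and the rtfr-driven
    phenology index sets how far towards that endpoint the day moves:
    severity = (1 - oxdef_pheno) / (1 - floor), 0 at the stress threshold
    and 1 at full saturation. Pre-flowering the multiplier is <= 1 (delay
    only); post-flowering it is >= 1 (truncation only).
    """
    pheno = oxdef_pheno_factor(rtfr, params)
    if pheno >= 1.0:
        return 1.0
    severity = (1.0 - pheno) / (1.0 - params.pheno_floor_at_saturation)
    m = stage_modifier_pheno(stage, params)
    if stage < 6.0:
        if m >= 1.0:
            return 1.0
        return 1.0 - (1.0 - m) * severity
    if m <= 1.0:
        return 1.0
    return 1.0 + (m - 1.0) * severity


def simulate_season(
    weather: WeatherSeries,
    soil: SoilProfile,
    genotype: Genotype,
    mgmt: Management,
    co2_ppm: float | None = None,
    sowing_year: int | None = None,
    waterlogging_on: bool = True,
    stress_params: StressParams = DEFAULT_STRESS,
    phase_targets: PhaseTargets | None = None,
    max_days: int = 360,
) -> SeasonResult:
    """Run the daily loop from sowing to maturity (or ``max_days``).

    The weather series must cover the sowing date and the following season;
    soil water is initialised at sowing (annual reset, lower limit plus the
    management's initial plant-available water filled top-down). A crop
    that fails to reach maturity inside the window is returned flagged
    incomplete with NaN yield rather than raising.
    """
    sowing_year = sowing_year if sowing_year is not None else weather.years[0]
    days = weather.year_slice(sowing_year, mgmt.sowing_doy, max_days)
    if len(days) < 2:
        raise ValueError("weather slice too short for a season")
    if co2_ppm is None:
        co2_ppm = weather.co2_ppm_by_year[int(sowing_year)]

    targets = (phase_targets or PhaseTargets(
        tt_end_of_juvenile=genotype.tt_end_of_juvenile
    )).targets(mgmt.sowing_depth)

    water = soil.initial_water(mgmt.initial_plant_available_water)
    thick = soil.thickness

    phase = 0  # 0-based: stage = phase + 1 + frac
    tt_in_phase = 0.0
    cum_tt = 0.0
    cum_vern = 0.0
    root_depth = 0.0
    biomass = 0.0
    spell_age = 0.0
    flowering_doy: int | None = None
    maturity_doy: int | None = None
    flowering_das: int | None = None
    maturity_das: int | None = None
    repro_stress: list[float] = []
    gs_rain = 0.0
    rows = []

    arr_year = days["year"].to_numpy(dtype=int)
    arr_doy = days["doy"].to_numpy(dtype=int)
    arr_radn = days["radn"].to_numpy(dtype=float)
    arr_maxt = days["maxt"].to_numpy(dtype=float)
    arr_mint = days["mint"].to_numpy(dtype=float)
    arr_rain = days["rain"].to_numpy(dtype=float)

    for i_day in range(len(days)):
        year, doy = int(arr_year[i_day]), int(arr_doy[i_day])
        radn, maxt, mint, rain_mm = (
            arr_radn[i_day], arr_maxt[i_day], arr_mint[i_day], arr_rain[i_day],
        )
        stage = ph.stage_from_progress(phase, tt_in_phase / targets[phase])
        gs_rain += rain_mm

        # --- water balance & saturation ---
        pet = potential_et(radn, maxt, mint)
        wb = water_balance_step(
            soil, water, rain_mm, pet, root_depth, stress_params
        )
        water = wb.layer_water
        rtfr = fraction_roots_waterlogged(root_depth, wb.saturation_flags, thick)

        # --- waterlogging stress indices ---
        if waterlogging_on:
            if rtfr >= stress_params.rtfr_threshold:
                spell_age += 1.0
            else:
                spell_age = 0.0
            raw = oxdef_photo_factor(rtfr, stress_params) * stage_modifier_photo(
                stage, stress_params
            )
            oxdef_photo = three_stage_response(
                spell_age, raw, genotype.lag_days, genotype.adapt_days,
                genotype.photo_floor,
            )
            # The phenology response passes through the same three stages:
            # no effect during the lag, full effect while oxygen-starved,
            # and after adaptation the residual effect scales with the
            # genotype's unrecovered fraction (a fully tolerant genotype
            # resumes normal development).
            m = _effective_pheno_multiplier(rtfr, stage, stress_params)
            if spell_age <= genotype.lag_days:
                tt_mult = 1.0
            elif spell_age <= genotype.lag_days + genotype.adapt_days:
                tt_mult = m
            else:
                tt_mult = 1.0 + (m - 1.0) * (1.0 - genotype.photo_floor)
        else:
            spell_age = 0.0
            oxdef_photo = 1.0
            tt_mult = 1.0

        # --- phenology ---
        dtt = ph.thermal_time(maxt, mint, genotype.cardinals)
        stage_lo, stage_hi = ph.VERN_PHOTOP_STAGES
        if stage_lo <= stage < stage_hi:
            cum_vern += ph.vernalisation_units(maxt, mint)
            fv = ph.vernalisation_factor(cum_vern, genotype.vern_sens)
            fp = ph.photoperiod_factor(weather.latitude, doy, genotype.photop_sens)
            dtt *= min(fv, fp)
        dtt *= tt_mult
        tt_in_phase += dtt
        cum_tt += dtt
        while phase < 9 and tt_in_phase >= targets[phase]:
            tt_in_phase -= targets[phase]
            phase += 1
            if phase + 1 == 6 and flowering_doy is None:  # reached stage 6
                flowering_doy = doy
                flowering_das = i_day
            if phase + 1 == 9 and maturity_doy is None:  # reached stage 9
                maturity_doy = doy
                maturity_das = i_day
        stage_after = ph.stage_from_progress(phase, tt_in_phase / targets[min(phase, 9)])

        # --- roots: descend after germination, halted while waterlogged ---
        if stage_after >= 2.0 and root_depth == 0.0:
            root_depth = mgmt.sowing_depth
        if (
            root_depth > 0.0
            and stage_after < 7.0
            and rtfr < stress_params.rtfr_threshold
        ):
            root_depth = min(root_depth + ROOT_DESCENT_RATE, soil.max_rooting_depth())

        # --- growth ---
        cover = canopy_cover(stage_after)
        biomass += daily_growth(
            radn, cover, genotype.rue, co2_ppm, oxdef_photo
        )
        if REPRO_WINDOW[0] <= stage_after <= REPRO_WINDOW[1]:
            repro_stress.append(oxdef_photo)

        rows.append(
            (year, doy, round(stage_after, 4), round(cum_tt, 3), round(rtfr, 4),
             round(oxdef_photo, 4), round(tt_mult, 4), round(spell_age, 1),
             round(biomass, 3), round(root_depth, 1), round(float(water.sum()), 3))
        )
        if maturity_doy is not None:
            break

    daily = pd.DataFrame(
        rows,
        columns=[
            "year", "doy", "stage", "cum_tt", "rtfr", "oxdef_photo",
            "oxdef_pheno", "wl_spell_age", "biomass", "root_depth", "soil_water",
        ],
    )
    complete = maturity_doy is not None
    if complete:
        penalty = float(np.mean(repro_stress)) if repro_stress else 1.0
        yield_kg_ha = biomass * genotype.harvest_index_potential * penalty * 10.0
    else:
        yield_kg_ha = float("nan")
    waterlogged_days = int((daily["oxdef_photo"] < 1.0).sum())
    return SeasonResult(
        yield_kg_ha=yield_kg_ha,
        flowering_doy=flowering_doy,
        maturity_doy=maturity_doy,
        flowering_das=flowering_das,
        maturity_das=maturity_das,
        waterlogged_days=waterlogged_days,
        complete=complete,
        daily=daily,
        genotype=genotype.name,
        sowing_year=int(sowing_year),
        sowing_doy=mgmt.sowing_doy,
        scenario_tag=weather.scenario_tag,
        growing_season_rain=gs_rain,
    )
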
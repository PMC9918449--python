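"""Synthetic daily weather, delta-change climate scenarios and the SSP585
CO2 trajectory.

The weather generator is a first-order two-state Markov chain for rainfall
occurrence (wet/dry day persistence) with gamma-distributed wet-day
amounts, sinusoidal seasonal cycles for temperature and radiation, AR(1)
day-to-day residuals, and fixed wet-day depressions of temperature and
radiation (rainy days are cooler and dimmer). That is enough structure to
produce realistic multi-day wet spells — the driver of soil saturation —
without reproducing a full downscaling chain.

Future variants are built by the delta-change method: monthly temperature
offsets and monthly rainfall/radiation factors applied to a baseline
series. Atmospheric CO2 for a calendar year follows an empirical SSP585
regression curve, with a table override for sensitivity analyses.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeatherGenParams",
    "WeatherSeries",
    "ClimateDeltas",
    "generate_weather",
    "apply_climate_deltas",
    "co2_for_year",
    "co2_table",
]

WEATHER_COLUMNS = ["year", "doy", "radn", "maxt", "mint", "rain"]


@dataclass(frozen=True)
class WeatherGenParams:
    """Parameters of the stochastic weather generator.

    Units: rainfall in mm, temperatures in degrees C, radiation in
    MJ m-2 day-1, phases in day-of-year. ``temp_phase`` is the day of peak
    mean temperature (late January for the north, late July for the south).
    """

    mean_annual_rain: float = 700.0
    rain_season_phase: float = 20.0  # doy of peak wet-day amounts
    rain_season_amplitude: float = 0.0  # relative amplitude in [0, 1)
    p_wet_given_wet: float = 0.55
    p_wet_given_dry: float = 0.25
    gamma_shape: float = 0.8
    temp_mean: float = 12.0
    temp_amplitude: float = 7.0
    temp_phase: float = 20.0
    diurnal_range: float = 9.0
    radn_mean: float = 15.0
    radn_amplitude: float = 8.0
    wet_day_temp_depression: float = 2.0
    wet_day_radn_depression: float = 4.0
    ar1_rho: float = 0.6
    ar1_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_wet_given_wet", "p_wet_given_dry"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.mean_annual_rain < 0:
            raise ValueError("mean_annual_rain must be >= 0")
        if not 0.0 <= self.rain_season_amplitude < 1.0:
            raise ValueError("rain_season_amplitude must lie in [0, 1)")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")

    @property
    def p_wet_stationary(self) -> float:
        """Stationary wet-day probability of the two-state Markov chain."""
        denom = 1.0 + self.p_wet_given_dry - self.p_wet_given_wet
        if denom <= 0:
            return 1.0
        return self.p_wet_given_dry / denom

    @property
    def gamma_scale(self) -> float:
        """Wet-day gamma scale chosen so the occurrence-amount model meets
        the target mean annual rainfall: E = 365 * P(wet) * shape * scale."""
        pw = self.p_wet_stationary
        if pw == 0 or self.mean_annual_rain == 0:
            return 1.0
        return self.mean_annual_rain / (365.0 * pw * self.gamma_shape)


@dataclass(frozen=True)
class ClimateDeltas:
    """Monthly delta-change factors: additive temperature offsets (degrees C)
    and multiplicative rainfall / radiation factors, one per calendar month."""

    monthly_temp_offset: tuple[float, ...] = (0.0,) * 12
    monthly_rain_factor: tuple[float, ...] = (1.0,) * 12
    monthly_radn_factor: tuple[float, ...] = (1.0,) * 12

    def __post_init__(self) -> None:
        for name, vals in (
            ("monthly_temp_offset", self.monthly_temp_offset),
            ("monthly_rain_factor", self.monthly_rain_factor),
            ("monthly_radn_factor", self.monthly_radn_factor),
        ):
            if len(vals) != 12:
                raise ValueError(f"{name} needs 12 values")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} must be finite")
        if min(self.monthly_rain_factor) < 0:
            raise ValueError("rain factors must be >= 0")
        if min(self.monthly_radn_factor) <= 0:
            raise ValueError("radiation factors must be > 0")

    @classmethod
    def uniform(
        cls, temp_offset: float = 0.0, rain_factor: float = 1.0, radn_factor: float = 1.0
    ) -> "ClimateDeltas":
        return cls((temp_offset,) * 12, (rain_factor,) * 12, (radn_factor,) * 12)


@dataclass
class WeatherSeries:
    """Daily weather for one site: contiguous (year, doy) records with the
    four driving variables, a per-year CO2 map and a scenario tag."""

    site_id: str
    latitude: float
    records: pd.DataFrame
    co2_ppm_by_year: dict[int, float]
    scenario_tag: str = "baseline"

    def __post_init__(self) -> None:
        self.records = self.records[WEATHER_COLUMNS].reset_index(drop=True)

    def validate(self) -> None:
        df = self.records
        if (df["maxt"] < df["mint"]).any():
            bad = df.index[df["maxt"] < df["mint"]][0]
            raise ValueError(f"maxt < mint at record {bad}")
        if (df["rain"] < 0).any():
            raise ValueError("negative rainfall")
        if (df["radn"] <= 0).any():
            raise ValueError("non-positive radiation")
        for year, grp in df.groupby("year"):
            n_days = 366 if calendar.isleap(int(year)) else 365
            expected = np.arange(1, n_days + 1)
            got = grp["doy"].to_numpy()
            if not np.array_equal(got, expected):
                missing = sorted(set(expected) - set(got))
                where = f"missing doy {missing[0]}" if missing else "misordered days"
                raise ValueError(
                    f"non-contiguous doy sequence in year {int(year)}: {where}"
                )
        missing = set(df["year"].unique().astype(int)) - set(self.co2_ppm_by_year)
        if missing:
            raise ValueError(f"years missing from co2_ppm_by_year: {sorted(missing)}")

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique().astype(int))

    def year_slice(self, year: int, start_doy: int, n_days: int) -> pd.DataFrame:
        """Records from (year, start_doy) for n_days, crossing year ends."""
        df = self.records
        start = df.index[(df["year"] == year) & (df["doy"] == start_doy)]
        if len(start) == 0:
            raise ValueError(f"({year}, {start_doy}) not in series")
        i = int(start[0])
        return df.iloc[i : i + n_days].reset_index(drop=True)

    def equals(self, other: "WeatherSeries") -> bool:
        return (
            self.site_id == other.site_id
            and self.latitude == other.latitude
            and self.scenario_tag == other.scenario_tag
            and self.co2_ppm_by_year == other.co2_ppm_by_year
            and self.records.equals(other.records)
        )


def _doys_for_year(year: int) -> np.ndarray:
    return np.arange(1, (366 if calendar.isleap(year) else 365) + 1)


def generate_weather(
    params: WeatherGenParams,
    n_years: int,
    start_year: int = 1990,
    site_id: str = "site",
    latitude: float = -41.0,
) -> WeatherSeries:
    """Generate a contiguous seeded daily weather series of ``n_years``.

    Rainfall occurrence follows the two-state Markov chain; wet-day amounts
    are gamma with a seasonally modulated scale. Temperature and radiation
    follow sinusoidal annual cycles with AR(1) residuals; wet days are
    cooler and receive less radiation by the stated depressions. A leap
    day (doy 366) reuses the seasonal values of doy 365.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(params.seed)

    years = []
    doys = []
    for y in range(start_year, start_year + n_years):
        d = _doys_for_year(y)
        years.append(np.full(d.size, y))
        doys.append(d)
    year_arr = np.concatenate(years)
    doy_arr = np.concatenate(doys)
    n = year_arr.size
    # Seasonal cycles use doy clipped to 365 so a leap day mirrors doy 365.
    ang = 2.0 * np.pi * (np.minimum(doy_arr, 365) - 1) / 365.0

    # -- rainfall occurrence (Markov) and amounts (gamma) --
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    prev_wet = u[0] < params.p_wet_stationary
    wet[0] = prev_wet
    for i in range(1, n):
        p = params.p_wet_given_wet if wet[i - 1] else params.p_wet_given_dry
        wet[i] = u[i] < p
    season_factor = 1.0 + params.rain_season_amplitude * np.cos(
        ang - 2.0 * np.pi * (params.rain_season_phase - 1) / 365.0
    )
    amounts = rng.gamma(params.gamma_shape, params.gamma_scale, size=n) * season_factor
    rain = np.where(wet, amounts, 0.0)

    # -- temperature: seasonal mean + AR(1) residual, wet-day depression --
    phase_t = 2.0 * np.pi * (params.temp_phase - 1) / 365.0
    tmean_season = params.temp_mean + params.temp_amplitude * np.cos(ang - phase_t)
    z = rng.standard_normal(n) * params.ar1_sigma
    resid = np.empty(n)
    resid[0] = z[0]
    for i in range(1, n):
        resid[i] = params.ar1_rho * resid[i - 1] + z[i]
    tmean = tmean_season + resid - np.where(wet, params.wet_day_temp_depression, 0.0)
    half = 0.5 * params.diurnal_range
    maxt = tmean + half
    mint = tmean - half

    # -- radiation: seasonal cycle, wet-day depression, small noise --
    radn_season = params.radn_mean + params.radn_amplitude * np.cos(ang - phase_t)
    radn = radn_season * (1.0 + 0.05 * rng.standard_normal(n))
    radn = radn - np.where(wet, params.wet_day_radn_depression, 0.0)
    radn = np.maximum(radn, 0.5)

    records = pd.DataFrame(
        {
            "year": year_arr,
            "doy": doy_arr,
            "radn": np.round(radn, 3),
            "maxt": np.round(maxt, 3),
            "mint": np.round(mint, 3),
            "rain": np.round(rain, 3),
        }
    )
    co2 = {int(y): co2_for_year(int(np.clip(y, 1900, 2100))) for y in range(start_year, start_year + n_years)}
    series = WeatherSeries(
        site_id=site_id,
        latitude=latitude,
        records=records,
        co2_ppm_by_year=co2,
    )
    series.validate()
    return series


def _month_of(year: np.ndarray, doy: np.ndarray) -> np.ndarray:
    dates = pd.to_datetime(
        year.astype(int) * 1000 + doy.astype(int), format="%Y%j"
    )
    return dates.month.to_numpy()


def apply_climate_deltas(
    series: WeatherSeries,
    deltas: ClimateDeltas,
    scenario_tag: str,
    co2_ppm_by_year: dict[int, float] | None = None,
) -> WeatherSeries:
    """Perturb a baseline series by monthly delta-change factors.

    Temperatures are shifted by the month's offset; rainfall and radiation
    are scaled by the month's factors. Record order and count are
    preserved; identity deltas return an equal series.
    """
    df = series.records.copy()
    month = _month_of(df["year"].to_numpy(), df["doy"].to_numpy())
    t_off = np.asarray(deltas.monthly_temp_offset)[month - 1]
    r_fac = np.asarray(deltas.monthly_rain_factor)[month - 1]
    s_fac = np.asarray(deltas.monthly_radn_factor)[month - 1]
    df["maxt"] = df["maxt"] + t_off
    df["mint"] = df["mint"] + t_off
    df["rain"] = df["rain"] * r_fac
    df["radn"] = df["radn"] * s_fac
    return WeatherSeries(
        site_id=series.site_id,
        latitude=series.latitude,
        records=df,
        co2_ppm_by_year=dict(co2_ppm_by_year or series.co2_ppm_by_year),
        scenario_tag=scenario_tag,
    )


def co2_for_year(y: float) -> float:
    """SSP585 atmospheric CO2 (ppm) for a calendar year in [1900, 2100].

    Empirical regression curve fitted to the CMIP6 SSP585 ensemble,
    evaluated exactly as printed:

        757.44 + (84.938 - 1.537 y) / (2.2011 - 3.8289 y^-0.45242)
        + 2.4712e-4 (y + 15)^2
        + 1.9299e-5 (y - 1937) * 1e-5 * (y - 1937)^3
        + 5.1137e-7 (y - 1910)^4

    The quartic (y - 1937) term's split coefficient is reproduced verbatim;
    callers needing a different trajectory can supply a year -> ppm table
    (see :func:`co2_table`) instead of this curve.
    """
    if not 1900 <= y <= 2100:
        raise ValueError(f"year must lie in [1900, 2100], got {y}")
    return float(
        757.44
        + (84.938 - 1.537 * y) / (2.2011 - 3.8289 * y ** -0.45242)
        + 2.4712e-4 * (y + 15.0) ** 2
        + 1.9299e-5 * (y - 1937.0) * 1e-5 * (y - 1937.0) ** 3
        + 5.1137e-7 * (y - 1910.0) ** 4
    )


def co2_table(path_or_mapping) -> dict[int, float]:
    """Load a year -> ppm override table from a two-column CSV
    (``year,co2_ppm``) or pass a mapping through unchanged."""
    if isinstance(path_or_mapping, dict):
        return {int(k): float(v) for k, v in path_or_mapping.items()}
    df = pd.read_csv(path_or_mapping)
    if not {"year", "co2_ppm"} <= set(df.columns):
        raise ValueError("CO2 table needs columns 'year' and 'co2_ppm'")
    return dict(zip(df["year"].astype(int), df["co2_ppm"].astype(float)))
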
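"""One-command miniature study generator.

Builds a complete runnable factorial on disk — 2 sites (freely drained dry
site, waterlogging-prone wet site) x 2 genotypes (tolerant / susceptible
pair) x 2 sowing windows x 2 scenarios (baseline and a wet-warm 2080
delta-change variant) x 3 realisations x 5 years — exercising every code
path of the pipeline at desk scale. All content derives deterministically
from one master seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .crop import Genotype
from .io import write_genotype, write_manifest, write_soil, write_weather
from .pipeline import FactorialDesign, Scenario, Site
from .soil import generate_soil
from .weather import ClimateDeltas, WeatherGenParams, generate_weather

__all__ = ["fixture_design", "make_fixture_study", "load_design"]

# Southern-hemisphere winter-rainfall climate: peak rain and cold mid-year,
# autumn sowing. The wet site concentrates ~900 mm/yr in long winter wet
# spells over a duplex soil; the dry site gets ~350 mm/yr spread thinly
# over a freely drained profile.
_WET_SITE_PARAMS = dict(
    mean_annual_rain=950.0,
    rain_season_phase=190.0,
    rain_season_amplitude=0.7,
    p_wet_given_wet=0.75,
    p_wet_given_dry=0.35,
    gamma_shape=0.9,
    temp_mean=11.0,
    temp_amplitude=6.0,
    temp_phase=20.0,
    radn_mean=14.0,
    radn_amplitude=8.0,
)
_DRY_SITE_PARAMS = dict(
    mean_annual_rain=350.0,
    rain_season_phase=190.0,
    rain_season_amplitude=0.4,
    p_wet_given_wet=0.4,
    p_wet_given_dry=0.12,
    gamma_shape=0.8,
    temp_mean=13.0,
    temp_amplitude=7.0,
    temp_phase=20.0,
    radn_mean=16.0,
    radn_amplitude=8.0,
)

#: Wet-warm end-of-century deltas: +2.6 C, winter-half rain up 25%.
_FUTURE_DELTAS = ClimateDeltas(
    monthly_temp_offset=(2.6,) * 12,
    monthly_rain_factor=(1.0, 1.0, 1.05, 1.15, 1.25, 1.25, 1.25, 1.25, 1.15, 1.05, 1.0, 1.0),
    monthly_radn_factor=(1.0,) * 12,
)


def fixture_design(
    master_seed: int = 0,
    n_realisations: int = 3,
    n_years: int = 5,
    maturity_class: str = "spring",
) -> FactorialDesign:
    """The miniature study as an in-memory design object."""
    if maturity_class == "spring":
        genos = [
            Genotype("spring_susceptible", "spring", 1.0, 1.0, 400.0, 0.5),
            Genotype("spring_tolerant", "spring", 1.0, 1.0, 400.0, 1.0),
        ]
    else:
        genos = [
            Genotype("winter_susceptible", "winter", 2.5, 2.5, 500.0, 0.5),
            Genotype("winter_tolerant", "winter", 2.5, 2.5, 500.0, 1.0),
        ]
    return FactorialDesign(
        sites=[
            Site("wet_duplex", "duplex_waterlogging_prone",
                 WeatherGenParams(**_WET_SITE_PARAMS), latitude=-41.0),
            Site("dry_drained", "freely_drained",
                 WeatherGenParams(**_DRY_SITE_PARAMS), latitude=-35.0),
        ],
        genotypes=genos,
        sowing_doys={"ES": 121, "LS": 152},
        scenarios=[
            Scenario("baseline"),
            Scenario("2080", deltas=_FUTURE_DELTAS, co2_year_offset=85),
        ],
        n_realisations=n_realisations,
        n_years=n_years,
        master_seed=master_seed,
    )


def _design_to_dict(design: FactorialDesign) -> dict:
    return {
        "sites": [
            {
                "name": s.name,
                "soil_archetype": s.soil_archetype,
                "latitude": s.latitude,
                "weather_params": dict(s.weather_params.__dict__),
            }
            for s in design.sites
        ],
        "genotypes": [dict(g.__dict__) for g in design.genotypes],
        "sowing_doys": dict(design.sowing_doys),
        "scenarios": [
            {
                "name": sc.name,
                "co2_year_offset": sc.co2_year_offset,
                "monthly_temp_offset": list(sc.deltas.monthly_temp_offset),
                "monthly_rain_factor": list(sc.deltas.monthly_rain_factor),
                "monthly_radn_factor": list(sc.deltas.monthly_radn_factor),
            }
            for sc in design.scenarios
        ],
        "n_realisations": design.n_realisations,
        "n_years": design.n_years,
        "start_year": design.start_year,
        "master_seed": design.master_seed,
    }


def load_design(path: str | Path) -> FactorialDesign:
    """Load a factorial design from its YAML file."""
    d = yaml.safe_load(Path(path).read_text())
    return FactorialDesign(
        sites=[
            Site(
                name=s["name"],
                soil_archetype=s["soil_archetype"],
                weather_params=WeatherGenParams(**s["weather_params"]),
                latitude=float(s["latitude"]),
            )
            for s in d["sites"]
        ],
        genotypes=[Genotype(**g) for g in d["genotypes"]],
        sowing_doys={k: int(v) for k, v in d["sowing_doys"].items()},
        scenarios=[
            Scenario(
                name=sc["name"],
                co2_year_offset=int(sc["co2_year_offset"]),
                deltas=ClimateDeltas(
                    tuple(sc["monthly_temp_offset"]),
                    tuple(sc["monthly_rain_factor"]),
                    tuple(sc["monthly_radn_factor"]),
                ),
            )
            for sc in d["scenarios"]
        ],
        n_realisations=int(d["n_realisations"]),
        n_years=int(d["n_years"]),
        start_year=int(d["start_year"]),
        master_seed=int(d["master_seed"]),
    )


def make_fixture_study(out_dir: str | Path, master_seed: int = 0) -> Path:
    """Write the miniature study to ``out_dir``: design YAML, one baseline
    weather file and one soil file per site, genotype files and a run
    manifest. Identical seed, identical tree."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = fixture_design(master_seed=master_seed)
    cfg = _design_to_dict(design)
    (out_dir / "design.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    for i, site in enumerate(design.sites):
        wx = generate_weather(
            WeatherGenParams(**{**site.weather_params.__dict__, "seed": master_seed + i}),
            n_years=design.n_years + 1,
            start_year=design.start_year,
            site_id=site.name,
            latitude=site.latitude,
        )
        write_weather(wx, out_dir / f"weather_{site.name}.csv")
        write_soil(generate_soil(site.soil_archetype, seed=master_seed + i),
                   out_dir / f"soil_{site.name}.yaml")
    for geno in design.genotypes:
        write_genotype(geno, out_dir / f"genotype_{geno.name}.yaml")
    write_manifest(out_dir, cfg, {"master_seed": master_seed})
    return out_dir
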
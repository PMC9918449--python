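"""Thermal-time phenology: cardinal-temperature response, vernalisation,
photoperiod and the continuous 1-11 stage scale.

Development is driven by daily thermal time (degree-days above a base
temperature, peaking at the optimum and falling to zero at the maximum),
accumulated through ten phases between eleven crop stages (1 sowing ...
6 flowering ... 9 maturity ... 11 end of crop). Winter genotypes gate
pre-floral development on vernalising cold and day length via the
sensitivities ``vern_sens`` and ``photop_sens`` (each 0-5; higher is more
sensitive). Within a phase the stage code advances fractionally with
thermal-time progress, so stage 4.3 means 30% of the way from stage 4 to 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STAGE_NAMES",
    "PhaseTargets",
    "thermal_time",
    "day_length",
    "photoperiod_factor",
    "vernalisation_units",
    "vernalisation_factor",
]

#: Stage codes 1..11 (continuous in between).
STAGE_NAMES = {
    1: "sowing",
    2: "germination",
    3: "emergence",
    4: "end_of_juvenile",
    5: "floral_initiation",
    6: "flowering",
    7: "start_grain_fill",
    8: "end_grain_fill",
    9: "maturity",
    10: "harvest_ripe",
    11: "end_crop",
}

# Stages (inclusive start, exclusive end) over which vernalisation and
# photoperiod multipliers act on thermal-time accumulation: emergence
# through floral initiation.
VERN_PHOTOP_STAGES = (3.0, 5.0)

#: Vernalisation saturates at this many vernal days.
VERN_SATURATION_DAYS = 50.0


@dataclass(frozen=True)
class PhaseTargets:
    """Thermal-time targets (degree-days) for the ten phases between stages.

    ``tt_end_of_juvenile`` is genotype-specific and substituted at run time;
    the remaining targets are fixed, broadly representative of a mid-season
    barley. ``tt_germination_per_mm`` converts sowing depth to the
    emergence target (shoot lag plus elongation per mm of depth).
    """

    tt_sow_to_germ: float = 1.0
    shoot_lag: float = 40.0
    tt_germination_per_mm: float = 1.5
    tt_end_of_juvenile: float = 400.0
    tt_juvenile_to_floral_init: float = 200.0
    tt_floral_init_to_flowering: float = 500.0
    tt_flowering_to_grain_fill: float = 120.0
    tt_grain_fill: float = 545.0
    tt_grain_fill_to_maturity: float = 35.0
    tt_maturity_to_ripe: float = 1.0
    tt_ripe_to_end: float = 1.0

    def targets(self, sowing_depth_mm: float) -> np.ndarray:
        """Return the ten phase targets, stage i -> i+1 at index i-1."""
        return np.array(
            [
                self.tt_sow_to_germ,
                self.shoot_lag + self.tt_germination_per_mm * sowing_depth_mm,
                self.tt_end_of_juvenile,
                self.tt_juvenile_to_floral_init,
                self.tt_floral_init_to_flowering,
                self.tt_flowering_to_grain_fill,
                self.tt_grain_fill,
                self.tt_grain_fill_to_maturity,
                self.tt_maturity_to_ripe,
                self.tt_ripe_to_end,
            ]
        )


def thermal_time(
    maxt: float, mint: float, cardinals: tuple[float, float, float] = (0.0, 26.0, 34.0)
) -> float:
    """Daily thermal time (degree-days) from a three-point cardinal response.

    The daily mean temperature is mapped through the piecewise-linear
    response: zero at or below the base, rising linearly to ``opt - base``
    at the optimum, falling linearly to zero at the maximum.
    """
    if maxt < mint:
        raise ValueError(f"maxt ({maxt}) < mint ({mint})")
    base, opt, tmax = cardinals
    if not base < opt < tmax:
        raise ValueError("cardinal temperatures must satisfy base < opt < max")
    tmean = 0.5 * (maxt + mint)
    return float(np.interp(tmean, [base, opt, tmax], [0.0, opt - base, 0.0]))


def day_length(latitude: float, doy: int, twilight_angle: float = -6.0) -> float:
    """Civil-twilight day length in hours for a latitude (degrees, south
    negative) and day of year."""
    lat = np.radians(latitude)
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    a = np.radians(twilight_angle)
    cos_h = (np.sin(a) - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
    cos_h = np.clip(cos_h, -1.0, 1.0)
    return float(24.0 / np.pi * np.arccos(cos_h))


def photoperiod_factor(latitude: float, doy: int, photop_sens: float) -> float:
    """Long-day photoperiod multiplier on pre-floral thermal time.

    Quadratic shortfall response below a 20 h ceiling: unity at or above
    20 h and for insensitive genotypes (``photop_sens`` = 0), declining with
    shorter days in proportion to the sensitivity.
    """
    if not 0.0 <= photop_sens <= 5.0:
        raise ValueError("photop_sens must lie in [0, 5]")
    dl = day_length(latitude, doy)
    f = 1.0 - 0.002 * photop_sens * (20.0 - dl) ** 2
    return float(np.clip(f, 0.0, 1.0))


def vernalisation_units(maxt: float, mint: float) -> float:
    """Daily vernal-day increment: cool days (mean below 18, min below 15)
    accrue up to one vernal day, most effectively near 1-7 degrees C."""
    tmean = 0.5 * (maxt + mint)
    if mint >= 15.0 or maxt >= 30.0:
        return 0.0
    return float(np.clip(1.4 - 0.0778 * tmean, 0.0, 1.0))


def vernalisation_factor(cum_vernal_days: float, vern_sens: float) -> float:
    """Vernalisation multiplier on pre-floral thermal time.

    Unity for insensitive genotypes or once cold exposure saturates
    (50 vernal days); otherwise reduced in proportion to sensitivity and
    the remaining cold requirement.
    """
    if not 0.0 <= vern_sens <= 5.0:
        raise ValueError("vern_sens must lie in [0, 5]")
    shortfall = max(0.0, VERN_SATURATION_DAYS - cum_vernal_days)
    f = 1.0 - 0.0054545 * vern_sens * shortfall
    return float(np.clip(f, 0.0, 1.0))


def stage_from_progress(phase_index: int, frac: float) -> float:
    """Continuous stage code from integer phase (0-based, stage i -> i+1)
    and fractional thermal-time progress within it."""
    return float(phase_index + 1 + np.clip(frac, 0.0, 1.0))
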
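"""Tipping-bucket soil water balance with drainage impedance and ponding.

Each day, rain infiltrates the surface layer (excess above an infiltration
capacity runs off), water above each layer's drained upper limit cascades
downward at a rate capped by the layer's saturated conductivity, water that
cannot drain backs up into the layers above (to saturation, then to
runoff), and evapotranspiration extracts from the rooted zone. Layers at
or below a static water table are held saturated and treated as a boundary:
drainage reaching them leaves the accounted store.

Daily mass balance closes identically:
rain = change in storage + drainage + runoff + actual ET.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .soil import SoilProfile
from .stress import StressParams, DEFAULT_STRESS

__all__ = ["WaterBalanceResult", "water_balance_step", "potential_et"]


@dataclass
class WaterBalanceResult:
    layer_water: np.ndarray  # mm per layer
    drainage: float  # mm out of the accounted profile
    runoff: float  # mm
    actual_et: float  # mm
    saturation_flags: np.ndarray  # bool per layer


def potential_et(radn: float, maxt: float, mint: float, albedo: float = 0.23) -> float:
    """Potential evapotranspiration (mm/day) from an equilibrium-evaporation
    formulation: PET = 1.1 * radn * (2.04e-4 - 1.83e-4 * albedo) * (Td + 29)
    with Td the day-weighted temperature 0.6*maxt + 0.4*mint."""
    td = 0.6 * maxt + 0.4 * mint
    eeq = radn * (2.04e-4 - 1.83e-4 * albedo) * (td + 29.0)
    return max(0.0, 1.1 * eeq)


def water_balance_step(
    profile: SoilProfile,
    layer_water: np.ndarray,
    rain: float,
    pot_et: float,
    root_depth: float = 0.0,
    stress_params: StressParams = DEFAULT_STRESS,
) -> WaterBalanceResult:
    """Advance the profile water store one day.

    Parameters
    ----------
    layer_water:
        Current water (mm) per layer, each within [0, SAT * thickness].
    rain, pot_et:
        Daily rainfall and potential evapotranspiration (mm).
    root_depth:
        Depth (mm) of the root front; ET is extracted from rooted layers,
        or from the top 150 mm when there is no crop.

    Returns
    -------
    WaterBalanceResult
        Updated store, the four fluxes, and per-layer saturation flags
        (content at or above ``DUL + saturation_fraction * (SAT - DUL)``,
        or lying below the water table).
    """
    if rain < 0 or pot_et < 0:
        raise ValueError("rain and potential ET must be >= 0")
    water = np.asarray(layer_water, dtype=float).copy()
    n = profile.n_layers
    if water.shape != (n,):
        raise ValueError(f"layer_water must have shape ({n},)")
    sat_mm = profile.sat_mm
    dul_mm = profile.dul_mm
    ll_mm = profile.ll_mm
    k_sat = profile.k_sat
    wt_mask = profile.water_table_mask()
    active = ~wt_mask
    storage_before = float(water[active].sum())

    # Surface infiltration; the rest runs off.
    infiltration = min(rain, profile.max_infiltration)
    runoff = rain - infiltration
    if wt_mask[0]:
        # water table at the surface: nothing can infiltrate
        runoff += infiltration
    else:
        water[0] += infiltration

    # Downward cascade: excess above DUL drains at up to k_sat; water
    # entering a water-table layer exits the accounted store.
    drainage = 0.0
    for i in range(n):
        if wt_mask[i]:
            # flux arriving here has already been counted as drainage
            water[i] = sat_mm[i]
            continue
        excess = max(0.0, water[i] - dul_mm[i])
        flux = min(excess, k_sat[i])
        water[i] -= flux
        if i + 1 < n and not wt_mask[i + 1]:
            water[i + 1] += flux
        else:
            drainage += flux

    # Back-up pass: water above SAT rises into the layer above; excess at
    # the surface becomes runoff (ponded water is not tracked).
    for i in range(n - 1, -1, -1):
        if wt_mask[i]:
            continue
        over = max(0.0, water[i] - sat_mm[i])
        if over > 0:
            water[i] -= over
            if i == 0:
                runoff += over
            else:
                water[i - 1] += over

    # ET extraction from the rooted zone (top 150 mm bare-soil evaporation
    # when no crop), proportional to plant-available water per layer.
    et_depth = max(root_depth, 150.0)
    tops = profile.depth_top
    thick = profile.thickness
    frac_in_zone = np.clip((et_depth - tops) / thick, 0.0, 1.0)
    avail = np.maximum(0.0, water - ll_mm) * frac_in_zone * active
    total_avail = float(avail.sum())
    actual_et = min(pot_et, total_avail)
    if actual_et > 0 and total_avail > 0:
        water -= avail * (actual_et / total_avail)

    water[wt_mask] = sat_mm[wt_mask]
    storage_after = float(water[active].sum())
    # mass balance: rain - (dS + drainage + runoff + ET) == 0 by construction

    sat_threshold = dul_mm + stress_params.saturation_fraction * (sat_mm - dul_mm)
    flags = (water >= sat_threshold - 1e-9) | wt_mask
    return WaterBalanceResult(
        layer_water=water,
        drainage=drainage,
        runoff=runoff,
        actual_et=actual_et,
        saturation_flags=flags,
    )
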
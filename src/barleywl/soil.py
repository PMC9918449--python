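"""Layered soil profiles and synthetic soil archetypes.

A profile is a stack of layers, each with a thickness and three volumetric
water contents — lower limit (LL, wilting point), drained upper limit (DUL,
field capacity) and saturation (SAT) — plus a saturated hydraulic
conductivity limiting drainage out of the layer. An optional static water
table keeps all layers below it permanently saturated.

Three archetypes capture the hydrological settings that matter for
waterlogging risk: a freely drained profile, a duplex (texture-contrast)
profile whose near-impermeable clay subsoil perches winter rain, and a
profile with a shallow water table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SoilLayer", "SoilProfile", "generate_soil", "SOIL_ARCHETYPES"]


@dataclass(frozen=True)
class SoilLayer:
    thickness: float  # mm
    ll: float  # mm/mm lower limit (wilting point)
    dul: float  # mm/mm drained upper limit (field capacity)
    sat: float  # mm/mm saturation
    k_sat: float  # mm/day saturated conductivity

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if not 0.0 < self.ll < self.dul < self.sat < 1.0:
            raise ValueError(
                f"require 0 < LL < DUL < SAT < 1, got "
                f"LL={self.ll}, DUL={self.dul}, SAT={self.sat}"
            )
        if self.k_sat < 0:
            raise ValueError("k_sat must be >= 0")


@dataclass(frozen=True)
class SoilProfile:
    layers: tuple[SoilLayer, ...]
    water_table_depth: float | None = None  # mm below surface
    max_infiltration: float = 80.0  # mm/day; rain beyond this runs off
    name: str = "soil"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.water_table_depth is not None and self.water_table_depth < 0:
            raise ValueError("water_table_depth must be >= 0")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def thickness(self) -> np.ndarray:
        return np.array([l.thickness for l in self.layers])

    @property
    def depth_bottom(self) -> np.ndarray:
        return np.cumsum(self.thickness)

    @property
    def depth_top(self) -> np.ndarray:
        return self.depth_bottom - self.thickness

    @property
    def total_depth(self) -> float:
        return float(self.depth_bottom[-1])

    @property
    def ll_mm(self) -> np.ndarray:
        return np.array([l.ll * l.thickness for l in self.layers])

    @property
    def dul_mm(self) -> np.ndarray:
        return np.array([l.dul * l.thickness for l in self.layers])

    @property
    def sat_mm(self) -> np.ndarray:
        return np.array([l.sat * l.thickness for l in self.layers])

    @property
    def k_sat(self) -> np.ndarray:
        return np.array([l.k_sat for l in self.layers])

    def max_rooting_depth(self, impedance_k_sat: float = 10.0) -> float:
        """Deepest root penetration (mm): the top of the first layer whose
        saturated conductivity is below the impedance threshold (dense,
        near-impermeable subsoil blocks root exploration), else the water
        table, else the profile bottom."""
        depth = self.total_depth
        for top, layer in zip(self.depth_top, self.layers):
            if layer.k_sat < impedance_k_sat and top > 0:
                depth = float(top)
                break
        if self.water_table_depth is not None:
            depth = min(depth, self.water_table_depth)
        return depth

    def water_table_mask(self) -> np.ndarray:
        """Layers whose top lies at or below the water table."""
        if self.water_table_depth is None:
            return np.zeros(self.n_layers, dtype=bool)
        return self.depth_top >= self.water_table_depth

    def initial_water(self, plant_available_water: float) -> np.ndarray:
        """Layer water (mm) at sowing: LL everywhere plus the stated plant
        available water filled top-down to DUL; water-table layers at SAT."""
        water = self.ll_mm.copy()
        remaining = float(plant_available_water)
        for i in range(self.n_layers):
            room = self.dul_mm[i] - water[i]
            add = min(room, remaining)
            water[i] += add
            remaining -= add
            if remaining <= 0:
                break
        water[self.water_table_mask()] = self.sat_mm[self.water_table_mask()]
        return water

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "water_table_depth": self.water_table_depth,
            "max_infiltration": self.max_infiltration,
            "layers": [
                {
                    "thickness": l.thickness,
                    "ll": l.ll,
                    "dul": l.dul,
                    "sat": l.sat,
                    "k_sat": l.k_sat,
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SoilProfile":
        return cls(
            layers=tuple(
                SoilLayer(
                    thickness=float(x["thickness"]),
                    ll=float(x["ll"]),
                    dul=float(x["dul"]),
                    sat=float(x["sat"]),
                    k_sat=float(x["k_sat"]),
                )
                for x in d["layers"]
            ),
            water_table_depth=(
                None if d.get("water_table_depth") is None else float(d["water_table_depth"])
            ),
            max_infiltration=float(d.get("max_infiltration", 80.0)),
            name=str(d.get("name", "soil")),
        )


# Archetype template: (layer thicknesses, ll, dul, sat, k_sat per layer,
# water table depth). Values are representative of agricultural soils; the
# waterlogging-prone archetypes differ in subsoil conductivity / water table.
# Topsoil is discretised into thin (50 mm) layers so that the drainage of a
# perched saturated zone desaturates the profile gradually from the top
# rather than flipping a whole thick layer's saturation flag at once.
SOIL_ARCHETYPES: dict[str, dict] = {
    "freely_drained": {
        "thickness": [50, 50, 100, 200, 300, 300, 300],
        "ll": [0.10, 0.10, 0.11, 0.12, 0.13, 0.13, 0.13],
        "dul": [0.28, 0.28, 0.29, 0.30, 0.30, 0.29, 0.28],
        "sat": [0.42, 0.42, 0.42, 0.43, 0.43, 0.42, 0.41],
        "k_sat": [200.0, 180.0, 150.0, 120.0, 100.0, 80.0, 80.0],
        "water_table_depth": None,
    },
    "duplex_waterlogging_prone": {
        "thickness": [50, 50, 50, 150, 200, 300, 300, 300],
        "ll": [0.09, 0.09, 0.10, 0.10, 0.20, 0.22, 0.22, 0.22],
        "dul": [0.26, 0.26, 0.27, 0.27, 0.38, 0.39, 0.39, 0.39],
        "sat": [0.44, 0.44, 0.43, 0.43, 0.44, 0.45, 0.45, 0.45],
        "k_sat": [150.0, 120.0, 100.0, 80.0, 1.0, 0.5, 0.5, 0.5],
        "water_table_depth": None,
    },
    "shallow_water_table": {
        "thickness": [50, 50, 100, 200, 300, 300],
        "ll": [0.11, 0.11, 0.12, 0.14, 0.16, 0.18],
        "dul": [0.29, 0.29, 0.30, 0.32, 0.34, 0.36],
        "sat": [0.43, 0.43, 0.43, 0.44, 0.45, 0.46],
        "k_sat": [100.0, 80.0, 60.0, 30.0, 10.0, 5.0],
        "water_table_depth": 600.0,
    },
}

#: Subsoil conductivity (mm/day) below which a profile is drainage-impeded.
IMPEDANCE_K_SAT = 10.0


def generate_soil(archetype: str, seed: int) -> SoilProfile:
    """Generate a seeded synthetic soil profile of the given archetype.

    The archetype template is perturbed with small multiplicative noise on
    the water contents and conductivities (layer order and the
    LL < DUL < SAT ordering are preserved) so repeated sites of one
    archetype are not byte-identical. Deterministic under a fixed seed.
    """
    if archetype not in SOIL_ARCHETYPES:
        raise ValueError(
            f"unknown soil archetype {archetype!r}; choose from {sorted(SOIL_ARCHETYPES)}"
        )
    tpl = SOIL_ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    n = len(tpl["thickness"])
    jitter = rng.uniform(0.97, 1.03, size=(3, n))
    k_jitter = rng.uniform(0.8, 1.2, size=n)
    layers = []
    for i in range(n):
        ll = tpl["ll"][i] * jitter[0, i]
        dul = max(tpl["dul"][i] * jitter[1, i], ll + 0.02)
        sat = max(tpl["sat"][i] * jitter[2, i], dul + 0.02)
        layers.append(
            SoilLayer(
                thickness=float(tpl["thickness"][i]),
                ll=round(float(ll), 4),
                dul=round(float(dul), 4),
                sat=round(float(min(sat, 0.95)), 4),
                k_sat=round(float(tpl["k_sat"][i] * k_jitter[i]), 3),
            )
        )
    return SoilProfile(
        layers=tuple(layers),
        water_table_depth=tpl["water_table_depth"],
        name=f"{archetype}_{seed}",
    )
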
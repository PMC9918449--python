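"""Interchange formats: weather files, soil/genotype/design YAML, run
manifests.

The weather text format follows the APSIM ``.met`` convention: comment/
header lines carrying ``site_id``, ``latitude`` and ``scenario_tag``, a
column header ``year day radn maxt mint rain``, a units line, then one row
per day. The reader accepts whitespace- or comma-delimited rows; the writer
emits CSV with a units comment. All numeric output uses C-locale decimal
points; readers reject NaN-bearing numeric fields and report malformed rows
with their line numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crop import Genotype
from .soil import SoilProfile
from .weather import WeatherSeries

__all__ = [
    "RunConfig",
    "read_weather",
    "write_weather",
    "read_soil",
    "write_soil",
    "read_genotype",
    "write_genotype",
    "write_manifest",
]

_HEADER_KEYS = ("site_id", "latitude", "scenario_tag")

# Documented range of every model-constant override a run config may carry.
_OVERRIDE_RANGES: dict[str, tuple[float, float]] = {
    "rtfr_threshold": (0.0, 1.0),
    "pheno_floor_at_saturation": (0.0, 1.0),
    "saturation_fraction": (0.5, 1.0),
    "lag_days": (0.0, 30.0),
    "adapt_days": (0.0, 60.0),
    "co2_k_half": (1.0, 2000.0),
    "onset_threshold": (0.0, 1.0),
}


class RunConfig:
    """Validated run configuration: paths, seeds, a design reference and
    model-constant overrides.

    Overrides are checked against their documented ranges and unknown keys
    are rejected, so a typo in a config file fails loudly instead of
    silently running the defaults.
    """

    def __init__(
        self,
        design: str | Path,
        out_dir: str | Path = "results",
        master_seed: int = 0,
        overrides: dict | None = None,
    ) -> None:
        self.design = Path(design)
        self.out_dir = Path(out_dir)
        self.master_seed = int(master_seed)
        self.overrides = dict(overrides or {})
        for key, val in self.overrides.items():
            if key not in _OVERRIDE_RANGES:
                raise ValueError(
                    f"unknown override {key!r}; known: {sorted(_OVERRIDE_RANGES)}"
                )
            lo, hi = _OVERRIDE_RANGES[key]
            if not lo <= float(val) <= hi:
                raise ValueError(f"override {key}={val} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {"design", "out_dir", "master_seed", "overrides"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "design": str(self.design),
            "out_dir": str(self.out_dir),
            "master_seed": self.master_seed,
            "overrides": dict(self.overrides),
        }


def write_weather(series: WeatherSeries, path: str | Path) -> Path:
    """Write a weather series as commented-header CSV (units line second)."""
    path = Path(path)
    lines = [
        f"! site_id = {series.site_id}",
        f"! latitude = {series.latitude}",
        f"! scenario_tag = {series.scenario_tag}",
        "! co2_ppm_by_year = "
        + ";".join(f"{y}:{p:.3f}" for y, p in sorted(series.co2_ppm_by_year.items())),
        "year,day,radn,maxt,mint,rain",
        "!(),(),MJ/m2,oC,oC,mm",
    ]
    df = series.records
    for row in df.itertuples(index=False):
        lines.append(
            f"{int(row.year)},{int(row.doy)},{row.radn:g},{row.maxt:g},"
            f"{row.mint:g},{row.rain:g}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_weather(path: str | Path) -> WeatherSeries:
    """Read the APSIM-met-like weather format (comma or whitespace rows).

    Raises ``ValueError`` naming the offending line for malformed rows,
    NaN fields, maxt < mint, or gaps in the (year, doy) sequence.
    """
    path = Path(path)
    meta = {"site_id": "site", "latitude": 0.0, "scenario_tag": "baseline"}
    co2: dict[int, float] = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("!", "#")):
                body = line.lstrip("!#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "latitude":
                        meta["latitude"] = float(val)
                    elif key in _HEADER_KEYS:
                        meta[key] = val
                    elif key == "co2_ppm_by_year" and val:
                        for pair in val.split(";"):
                            y, _, p = pair.partition(":")
                            co2[int(y)] = float(p)
                continue
            parts = line.replace(",", " ").split()
            if parts[0].lower() in ("year",):
                continue
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({e})") from None
            if any(np.isnan(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: NaN field")
            if vals[3] < vals[4]:
                raise ValueError(f"{path}:{lineno}: maxt < mint")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=["year", "doy", "radn", "maxt", "mint", "rain"])
    df["year"] = df["year"].astype(int)
    df["doy"] = df["doy"].astype(int)
    if not co2:
        co2 = {int(y): 400.0 for y in df["year"].unique()}
    series = WeatherSeries(
        site_id=str(meta["site_id"]),
        latitude=float(meta["latitude"]),
        records=df,
        co2_ppm_by_year=co2,
        scenario_tag=str(meta["scenario_tag"]),
    )
    try:
        series.validate()
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None
    return series


def write_soil(profile: SoilProfile, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(profile.to_dict(), sort_keys=False))
    return path


def read_soil(path: str | Path) -> SoilProfile:
    return SoilProfile.from_dict(yaml.safe_load(Path(path).read_text()))


def write_genotype(geno: Genotype, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(geno.__dict__, sort_keys=False))
    return path


def read_genotype(path: str | Path) -> Genotype:
    return Genotype(**yaml.safe_load(Path(path).read_text()))


def write_manifest(out_dir: str | Path, config: dict, seeds: dict) -> Path:
    """Machine-readable run manifest: config hash, seeds, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds,
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
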
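"""Waterlogging stress physiology.

Soil saturation deprives roots of oxygen. The daily driver of stress is the
fraction of the root zone sitting in saturated soil layers (``rtfr``). Two
dimensionless indices respond to it:

``oxdef_photo``
    multiplies daily assimilation; 1 means no stress, 0 full stress.
``oxdef_pheno``
    modifies the developmental rate; 1 means no effect, values below 1 slow
    pre-flowering development (delayed flowering) and, combined with the
    stage modifier, values above 1 shorten grain filling.

Both indices are piecewise-linear in ``rtfr``: no stress below a threshold
(0.8 of roots waterlogged), then a linear decline to the fully saturated
endpoint (0 for photosynthesis, 0.8 for phenology).

On top of the instantaneous driver sits a three-stage whole-plant response:
an initial lag during which growth is unaffected, a full-stress phase while
oxygen-dependent metabolism is impaired, and an adaptation phase in which
tolerant genotypes (via aerenchyma formation and root porosity) recover
photosynthesis up to a genotype-specific floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StressParams",
    "oxdef_photo_factor",
    "oxdef_pheno_factor",
    "stage_modifier_pheno",
    "three_stage_response",
    "fraction_roots_waterlogged",
]


@dataclass(frozen=True)
class StressParams:
    """Tunable constants of the waterlogging stress functions.

    Attributes
    ----------
    rtfr_threshold:
        Fraction of roots waterlogged at which stress begins (default 0.8).
    pheno_floor_at_saturation:
        Value of the phenology index at full saturation (default 0.8).
    stage_anchors, stage_values:
        Anchor points of the stage-dependent phenology modifier. Below
        flowering the modifier is < 1 (development slowed); above it the
        modifier rises to 1.5 by stage 10 (grain fill truncated). The value
        0.65 printed for stage 4.0 is extended flat to earlier stages and a
        short linear ramp closes the (5.5, 6) gap — choices that preserve
        continuity at the anchor stages without inventing new extrema.
    photo_stage_anchors, photo_stage_values:
        Hook for a stage dependence of the photosynthesis index. No values
        are published, so the default is identically 1.
    saturation_fraction:
        A soil layer counts as waterlogged once its water content reaches
        this fraction of the DUL-to-SAT range (default 0.97, avoiding
        floating-point knife edges at exact saturation).
    """

    rtfr_threshold: float = 0.8
    pheno_floor_at_saturation: float = 0.8
    stage_anchors: tuple[float, ...] = (1.0, 4.0, 5.5, 6.0, 10.0, 11.0)
    stage_values: tuple[float, ...] = (0.65, 0.65, 0.95, 1.0, 1.5, 1.5)
    photo_stage_anchors: tuple[float, ...] = (1.0, 11.0)
    photo_stage_values: tuple[float, ...] = (1.0, 1.0)
    saturation_fraction: float = 0.97


DEFAULT_STRESS = StressParams()


def _check_rtfr(rtfr: float) -> None:
    if not 0.0 <= rtfr <= 1.0:
        raise ValueError(f"rtfr must lie in [0, 1], got {rtfr}")


def oxdef_photo_factor(rtfr: float, params: StressParams = DEFAULT_STRESS) -> float:
    """Photosynthesis stress index as a function of fraction of roots waterlogged.

    Returns 1 (no stress) while ``rtfr`` is below the threshold, then declines
    linearly to 0 at full saturation.
    """
    _check_rtfr(rtfr)
    t = params.rtfr_threshold
    if rtfr < t:
        return 1.0
    return float((1.0 - rtfr) / (1.0 - t))


def oxdef_pheno_factor(rtfr: float, params: StressParams = DEFAULT_STRESS) -> float:
    """Phenology stress index: 1 below the threshold, declining linearly to
    the saturation floor (0.8) at ``rtfr`` = 1."""
    _check_rtfr(rtfr)
    t = params.rtfr_threshold
    if rtfr < t:
        return 1.0
    floor = params.pheno_floor_at_saturation
    return float(1.0 - (1.0 - floor) * (rtfr - t) / (1.0 - t))


def stage_modifier_pheno(stage: float, params: StressParams = DEFAULT_STRESS) -> float:
    """Stage-dependent magnitude of the phenology response to waterlogging.

    Interpolates the anchor table: 0.65 at stage 4.0 rising to 0.95 at stage
    5.5 (pre-flowering delay weakening as flowering approaches), then 1.0 at
    flowering (stage 6) rising to 1.5 at stage 10 (progressively stronger
    grain-fill truncation).
    """
    if not params.stage_anchors[0] <= stage <= params.stage_anchors[-1]:
        raise ValueError(
            f"stage must lie in [{params.stage_anchors[0]}, "
            f"{params.stage_anchors[-1]}], got {stage}"
        )
    return float(np.interp(stage, params.stage_anchors, params.stage_values))


def stage_modifier_photo(stage: float, params: StressParams = DEFAULT_STRESS) -> float:
    """Stage dependence of the photosynthesis index (identity by default)."""
    return float(np.interp(stage, params.photo_stage_anchors, params.photo_stage_values))


def three_stage_response(
    wl_spell_age: float,
    raw_stress: float,
    lag_days: float,
    adapt_days: float,
    photo_floor: float,
) -> float:
    """Effective photosynthesis multiplier through the three response stages.

    Parameters
    ----------
    wl_spell_age:
        Days of continuous root-zone saturation (resets when ``rtfr`` drops
        below the stress threshold).
    raw_stress:
        Instantaneous index from :func:`oxdef_photo_factor`.
    lag_days:
        Duration of stage one, the immediate response, during which water
        supply is unconstrained and growth is unaffected.
    adapt_days:
        Time after stage one for adaptation (aerenchyma, root porosity) to
        complete.
    photo_floor:
        Post-adaptation photosynthesis multiplier: 1 for a fully tolerant
        genotype, below 1 for susceptible ones.

    Returns
    -------
    float
        1 during stage one; ``raw_stress`` during stage two; in stage three
        the adapted level ``max(raw_stress, photo_floor)``.
    """
    if wl_spell_age < 0:
        raise ValueError("wl_spell_age must be >= 0")
    if wl_spell_age <= lag_days:
        return 1.0
    if wl_spell_age <= lag_days + adapt_days:
        return float(raw_stress)
    return float(max(raw_stress, photo_floor))


def fraction_roots_waterlogged(
    root_depth: float,
    saturation_flags: np.ndarray,
    layer_thickness: np.ndarray,
) -> float:
    """Fraction of the root zone lying within saturated soil layers.

    A layer partially penetrated by the root front contributes only the
    rooted part of its thickness. ``root_depth`` of 0 (pre-emergence) is
    defined as no waterlogging.
    """
    if root_depth < 0:
        raise ValueError("root_depth must be >= 0")
    if root_depth == 0:
        return 0.0
    flags = np.asarray(saturation_flags, dtype=bool)
    thick = np.asarray(layer_thickness, dtype=float)
    tops = np.concatenate(([0.0], np.cumsum(thick)))[:-1]
    rooted = np.clip(root_depth - tops, 0.0, thick)
    saturated_rooted = float(np.sum(rooted * flags))
    total_rooted = float(np.sum(rooted))
    if total_rooted == 0.0:
        return 0.0
    return min(1.0, saturated_rooted / total_rooted)
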
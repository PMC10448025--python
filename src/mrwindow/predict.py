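"""End-to-end prediction of native-scale optimal WL/WW for a new image.

Given a fitted model and the trained per-condition scales, prediction for a
new series and operator is: look up the standardized optimal window
(soWL, soWW) for that operator x condition; build the image's own mapping
function from its landmarks and the condition's standard scale; convert the
standardized window to limits; push the limits through the *inverse* map;
convert back to a (WL, WW) pair in the image's native units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

from .core import ImagingCondition, MRSeries, WindowLimits, WindowSetting
from .errors import UnknownConditionError
from .model import FittedModel
from .standardize import (
    StandardScale,
    build_mapping,
    compute_landmarks,
    limits_from_window,
    window_from_limits,
)

MIN_NATIVE_WW = 1.0


@dataclass
class Prediction:
    """A predicted native window plus the intermediate audit quantities."""

    series_id: str
    operator: int
    condition: ImagingCondition
    window: WindowSetting  # oWL/oWW, native frame
    so_window: WindowSetting  # soWL/soWW, standardized frame
    so_limits: WindowLimits  # soLW/soUW
    o_limits: WindowLimits  # oLW/oUW


def resolve_condition(
    series: MRSeries,
    model: FittedModel,
    fallback_map: Optional[Dict[ImagingCondition, ImagingCondition]] = None,
) -> ImagingCondition:
    """The series' own condition if modeled, else an explicit substitute.

    Substitution (e.g. treating an unexpected acquisition like a modeled one
    with a similar intensity distribution) is opt-in and fully user-authored;
    a substitution is logged as a warning, never silent.
    """
    modeled = {(c.sequence, c.region): c for c in model.conditions}
    key = (series.condition.sequence, series.condition.region)
    if key in modeled:
        return modeled[key]
    if fallback_map:
        for src, dst in fallback_map.items():
            if (src.sequence, src.region) == key:
                sub = modeled.get((dst.sequence, dst.region))
                if sub is None:
                    raise UnknownConditionError(
                        f"fallback target {dst.label!r} is not in the model"
                    )
                warnings.warn(
                    f"series {series.series_id!r}: condition "
                    f"{series.condition.label!r} not modeled; substituting "
                    f"{sub.label!r}"
                )
                return sub
    raise UnknownConditionError(
        f"series {series.series_id!r}: condition {series.condition.label!r} "
        f"is not in the model and no fallback is mapped"
    )


def predict_window(
    series: MRSeries,
    operator: int,
    model: FittedModel,
    scales: Dict[ImagingCondition, StandardScale],
    fallback_map: Optional[Dict[ImagingCondition, ImagingCondition]] = None,
) -> Prediction:
    """Predict the operator's optimal native WL/WW for one series."""
    condition = resolve_condition(series, model, fallback_map)
    scale = scales.get(condition)
    if scale is None:
        raise UnknownConditionError(
            f"no trained standard scale for condition {condition.label!r}"
        )
    so_window = model.lookup(operator, condition)
    mapping = build_mapping(compute_landmarks(series), scale)
    so_limits = limits_from_window(so_window)
    o_limits = WindowLimits(
        lw=float(mapping.inverse(so_limits.lw)),
        uw=float(mapping.inverse(so_limits.uw)),
    )
    window = window_from_limits(o_limits)
    if window.ww < MIN_NATIVE_WW:
        warnings.warn(
            f"series {series.series_id!r}: predicted native WW {window.ww:.3g} "
            f"below {MIN_NATIVE_WW}; clamped"
        )
        window = WindowSetting(wl=window.wl, ww=MIN_NATIVE_WW)
    return Prediction(
        series_id=series.series_id,
        operator=operator,
        condition=condition,
        window=window,
        so_window=so_window,
        so_limits=so_limits,
        o_limits=o_limits,
    )
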
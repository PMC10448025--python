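"""Landmark-based piecewise-linear intensity standardization of windows.

The procedure follows the classic histogram-landmark standardization scheme:
for each image the intensities of interest (IOI; voxels strictly greater
than zero) are summarized by 11 percentile landmarks (1, 10, 20, ..., 90,
99).  Training averages each condition's landmarks — after affinely pinning
the 1st/99th-percentile landmarks to 1 and 100 — into a per-condition
*standard scale*.  At use time an image's own landmarks and its condition's
scale define a monotone piecewise-linear *mapping function*; window limits
are pushed through it (standardization) or its exact inverse
(de-standardization).

Windows convert to limits and back as

    UW = WL + WW/2,   LW = WL - WW/2
    WW = UW - LW,     WL = LW + WW/2

in every frame.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import ConditionRegistry, ImagingCondition, MRSeries, WindowLimits, WindowSetting
from .errors import (
    DegenerateImageError,
    TrainingError,
    UnmappableImageError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: IOI percentiles defining the landmarks, in order.
LANDMARK_PERCENTILES: Tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)

#: The standard scale pins the 1st/99th-percentile landmarks to these values.
SCALE_MIN: float = 1.0
SCALE_MAX: float = 100.0


@dataclass
class LandmarkVector:
    """The 11 IOI percentile intensities of one image, non-decreasing."""

    values: np.ndarray
    percentiles: Tuple[float, ...] = LANDMARK_PERCENTILES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.percentiles),):
            raise ValidationError(
                f"expected {len(self.percentiles)} landmark values, "
                f"got shape {self.values.shape}"
            )
        if np.any(np.diff(self.values) < 0):
            raise ValidationError("landmark values must be non-decreasing")


@dataclass
class StandardScale:
    """Per-condition target knots on [1, 100], trained by landmark averaging."""

    condition: ImagingCondition
    nodes: np.ndarray
    n_images: int = 0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (len(LANDMARK_PERCENTILES),):
            raise ValidationError(f"expected 11 scale nodes, got {self.nodes.shape}")
        if self.nodes[0] != SCALE_MIN or self.nodes[-1] != SCALE_MAX:
            raise ValidationError(
                f"scale nodes must start at {SCALE_MIN} and end at {SCALE_MAX}"
            )
        if np.any(np.diff(self.nodes) < 0):
            raise ValidationError("scale nodes must be non-decreasing")


@dataclass
class MappingFunction:
    """Strictly increasing piecewise-linear map, invertible everywhere.

    Between knots the map interpolates linearly; beyond the outermost knots
    it extends the terminal segment's slope indefinitely, which keeps the map
    a bijection of the real line (window limits routinely fall outside the
    1st..99th-percentile landmark range).
    """

    source_knots: np.ndarray
    target_knots: np.ndarray

    def __post_init__(self) -> None:
        self.source_knots = np.asarray(self.source_knots, dtype=float)
        self.target_knots = np.asarray(self.target_knots, dtype=float)
        if self.source_knots.shape != self.target_knots.shape:
            raise ValidationError("source/target knots must have equal length")
        if self.source_knots.size < 2:
            raise UnmappableImageError("need at least 2 distinct knots")
        if np.any(np.diff(self.source_knots) <= 0) or np.any(
            np.diff(self.target_knots) <= 0
        ):
            raise ValidationError("knots must be strictly increasing on both axes")

    @staticmethod
    def _interp_extend(x, xs: np.ndarray, ys: np.ndarray):
        x_arr = np.asarray(x, dtype=float)
        y = np.interp(x_arr, xs, ys)
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        y = np.where(x_arr < xs[0], ys[0] + lo_slope * (x_arr - xs[0]), y)
        y = np.where(x_arr > xs[-1], ys[-1] + hi_slope * (x_arr - xs[-1]), y)
        return y if y.ndim else float(y)

    def forward(self, x):
        """Map native intensity to the standard scale (scalar or array)."""
        return self._interp_extend(x, self.source_knots, self.target_knots)

    def inverse(self, y):
        """Map standard-scale value back to native intensity."""
        return self._interp_extend(y, self.target_knots, self.source_knots)


def ioi(series: MRSeries) -> np.ndarray:
    """Intensities of interest: the voxels strictly greater than zero."""
    vox = np.ravel(series.voxels)
    out = vox[vox > 0]
    if out.size == 0:
        raise DegenerateImageError(
            f"series {series.series_id!r}: no voxels with intensity > 0"
        )
    return out


def compute_landmarks(series: MRSeries) -> LandmarkVector:
    """11 IOI percentiles under the linear (type-7) percentile convention."""
    values = np.percentile(ioi(series), LANDMARK_PERCENTILES, method="linear")
    return LandmarkVector(values=values)


def _rescale_landmarks(lm: LandmarkVector) -> Optional[np.ndarray]:
    """Pin an image's p1 landmark to 1 and p99 to 100; None if degenerate."""
    v = lm.values
    span = v[-1] - v[0]
    if span <= 0:
        return None
    return SCALE_MIN + (v - v[0]) * (SCALE_MAX - SCALE_MIN) / span


def train_standard_scale(
    series_list: Sequence[MRSeries], condition: ImagingCondition
) -> StandardScale:
    """Average rescaled landmarks over a condition's training images.

    Images whose 1st- and 99th-percentile landmarks coincide carry no
    dynamic range and are excluded with a warning.
    """
    rescaled: List[np.ndarray] = []
    for s in series_list:
        if s.condition != condition:
            raise ValidationError(
                f"series {s.series_id!r} has condition {s.condition.label!r}, "
                f"expected {condition.label!r}"
            )
        r = _rescale_landmarks(compute_landmarks(s))
        if r is None:
            warnings.warn(
                f"series {s.series_id!r}: p1 == p99 landmark; excluded from "
                f"scale training for {condition.label!r}"
            )
            continue
        rescaled.append(r)
    if not rescaled:
        raise TrainingError(f"no usable training images for {condition.label!r}")
    nodes = np.mean(rescaled, axis=0)
    nodes[0], nodes[-1] = SCALE_MIN, SCALE_MAX  # exact by construction, pin anyway
    return StandardScale(condition=condition, nodes=nodes, n_images=len(rescaled))


def build_mapping(landmarks: LandmarkVector, scale: StandardScale) -> MappingFunction:
    """Knot the image's landmarks against the condition's scale nodes.

    Coincident landmarks (common on quantized or low-dynamic-range images)
    are merged into a single knot paired with the mean of their target
    nodes; ties that this produces on the target axis are merged
    symmetrically.  Fewer than 2 distinct knots is unmappable.
    """
    src, tgt = _merge_ties(landmarks.values, np.asarray(scale.nodes, dtype=float))
    if src.size < 2:
        raise UnmappableImageError("all landmarks equal; image has no dynamic range")
    return MappingFunction(source_knots=src, target_knots=tgt)


def _merge_ties(src: np.ndarray, tgt: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    src, tgt = _merge_axis(src, tgt)  # collapse ties in source
    tgt2, src2 = _merge_axis(tgt, src)  # then any remaining ties in target
    return src2, tgt2


def _merge_axis(key: np.ndarray, other: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Group consecutive equal values of ``key``; average ``other`` per group."""
    out_key: List[float] = []
    out_other: List[float] = []
    i = 0
    while i < key.size:
        j = i
        while j + 1 < key.size and key[j + 1] == key[i]:
            j += 1
        out_key.append(float(key[i]))
        out_other.append(float(np.mean(other[i : j + 1])))
        i = j + 1
    return np.asarray(out_key), np.asarray(out_other)


def limits_from_window(w: WindowSetting) -> WindowLimits:
    """UW = WL + WW/2, LW = WL - WW/2 (same formula in every frame)."""
    return WindowLimits(lw=w.wl - w.ww / 2.0, uw=w.wl + w.ww / 2.0)


def window_from_limits(l: WindowLimits) -> WindowSetting:
    """WW = UW - LW, WL = LW + WW/2 (same formula in every frame)."""
    ww = l.uw - l.lw
    return WindowSetting(wl=l.lw + ww / 2.0, ww=ww)


def standardize_window(w: WindowSetting, mapping: MappingFunction) -> WindowSetting:
    """Native-frame window -> standardized-frame window via the forward map."""
    lim = limits_from_window(w)
    return window_from_limits(
        WindowLimits(lw=float(mapping.forward(lim.lw)), uw=float(mapping.forward(lim.uw)))
    )


def destandardize_window(w: WindowSetting, mapping: MappingFunction) -> WindowSetting:
    """Standardized-frame window -> native frame via the exact inverse map."""
    lim = limits_from_window(w)
    return window_from_limits(
        WindowLimits(lw=float(mapping.inverse(lim.lw)), uw=float(mapping.inverse(lim.uw)))
    )


# ---------------------------------------------------------------------------
# Scale registry serialization (portable between train and predict runs)

def save_scales(scales: Dict[ImagingCondition, StandardScale], path) -> None:
    """Write trained scales as JSON: one entry per condition."""
    payload = [
        {
            "sequence": c.sequence,
            "region": c.region,
            "percentiles": list(LANDMARK_PERCENTILES),
            "nodes": [float(v) for v in s.nodes],
            "n_images": s.n_images,
        }
        for c, s in scales.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_scales(path, registry: ConditionRegistry) -> Dict[ImagingCondition, StandardScale]:
    payload = json.loads(Path(path).read_text())
    out: Dict[ImagingCondition, StandardScale] = {}
    for entry in payload:
        cond = registry.intern(entry["sequence"], entry["region"])
        out[cond] = StandardScale(
            condition=cond,
            nodes=np.asarray(entry["nodes"], dtype=float),
            n_images=int(entry.get("n_images", 0)),
        )
    return out


def train_all_scales(
    series_by_condition: Dict[ImagingCondition, Sequence[MRSeries]]
) -> Dict[ImagingCondition, StandardScale]:
    """Train one standard scale per condition from grouped training images."""
    return {
        cond: train_standard_scale(series, cond)
        for cond, series in series_by_condition.items()
    }
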
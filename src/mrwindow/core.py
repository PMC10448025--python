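"""Core domain types: series, imaging conditions, windows, records, datasets.

Unit frames
-----------
Window parameters live in one of two frames: ``native`` (scanner intensity
units of a particular image) or ``standardized`` (the per-condition landmark
scale on [1, 100]).  :class:`WindowSetting` and :class:`WindowLimits` are
frame-agnostic value types; the frame travels with the surrounding context
(a :class:`WindowingRecord` carries an explicit ``frame`` field, and every
operation documents the frame it consumes and produces).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


class Frame(str, enum.Enum):
    """Unit frame of a window: native scanner units or the standard scale."""

    NATIVE = "native"
    STANDARDIZED = "standardized"


@dataclass(frozen=True)
class ImagingCondition:
    """A combination of acquisition sequence and body region.

    Conditions index the random-effect structure of the model; the 1-based
    ``index`` is assigned by the :class:`ConditionRegistry` that interned the
    condition and is excluded from equality.
    """

    sequence: str
    region: str
    index: int = field(default=0, compare=False)

    @property
    def label(self) -> str:
        return f"{self.region} {self.sequence}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class ConditionRegistry:
    """Bijective mapping between (sequence, region) pairs and indices 1..J."""

    def __init__(self) -> None:
        self._by_key: Dict[tuple, ImagingCondition] = {}
        self._ordered: List[ImagingCondition] = []

    def intern(self, sequence: str, region: str) -> ImagingCondition:
        key = (sequence, region)
        cond = self._by_key.get(key)
        if cond is None:
            cond = ImagingCondition(sequence, region, index=len(self._ordered) + 1)
            self._by_key[key] = cond
            self._ordered.append(cond)
        return cond

    def get(self, sequence: str, region: str) -> Optional[ImagingCondition]:
        return self._by_key.get((sequence, region))

    def by_index(self, index: int) -> ImagingCondition:
        return self._ordered[index - 1]

    @property
    def conditions(self) -> List[ImagingCondition]:
        return list(self._ordered)

    def __len__(self) -> int:
        return len(self._ordered)

    def __contains__(self, cond: ImagingCondition) -> bool:
        return (cond.sequence, cond.region) in self._by_key

    def __iter__(self):
        return iter(self._ordered)


@dataclass
class MRSeries:
    """One MR series: a voxel array plus identity and condition labels.

    ``voxels`` is kept in native scanner units; negative and zero values are
    permitted here and excluded later by the intensity-of-interest filter.
    """

    series_id: str
    patient_id: str
    condition: ImagingCondition
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.size == 0:
            raise ValidationError(f"series {self.series_id!r}: voxel array is empty")


@dataclass(frozen=True)
class WindowSetting:
    """A display window as (level, width). Width must be positive."""

    wl: float
    ww: float

    def __post_init__(self) -> None:
        if not self.ww > 0:
            raise ValidationError(f"window width must be > 0, got {self.ww}")


@dataclass(frozen=True)
class WindowLimits:
    """A display window as (lower, upper) intensity limits."""

    lw: float
    uw: float

    def __post_init__(self) -> None:
        if not self.uw > self.lw:
            raise ValidationError(
                f"upper window limit must exceed lower ({self.lw} >= {self.uw})"
            )


@dataclass
class WindowingRecord:
    """One observed windowing event: who windowed which series, and how."""

    series_id: str
    patient_id: str
    condition: ImagingCondition
    operator: int
    window: WindowSetting
    frame: Frame = Frame.NATIVE

    def __post_init__(self) -> None:
        if self.operator < 1:
            raise ValidationError(f"operator index must be >= 1, got {self.operator}")


@dataclass
class Dataset:
    """Windowing records, the images they refer to, and a patient-level split."""

    records: List[WindowingRecord]
    images: Dict[str, MRSeries] = field(default_factory=dict)
    split: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for rec in self.records:
            img = self.images.get(rec.series_id)
            if img is None:
                raise ValidationError(f"record {rec.series_id!r}: no matching image")
            if img.condition != rec.condition:
                raise ValidationError(
                    f"record {rec.series_id!r}: condition mismatch "
                    f"({rec.condition.label} vs {img.condition.label})"
                )

    @property
    def patients(self) -> List[str]:
        seen: Dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.patient_id, None)
        return list(seen)

    def records_in(self, label: str) -> List[WindowingRecord]:
        return [r for r in self.records if self.split.get(r.patient_id) == label]

    @property
    def train_records(self) -> List[WindowingRecord]:
        return self.records_in("train")

    @property
    def test_records(self) -> List[WindowingRecord]:
        return self.records_in("test")

    def images_in(self, label: str) -> List[MRSeries]:
        ids = {r.series_id for r in self.records_in(label)}
        return [self.images[s] for s in ids if s in self.images]


def split_patients(
    patients: Iterable[str], train_fraction: float, seed: int
) -> Dict[str, str]:
    """Deterministic random partition of patient IDs into train/test."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    patients = sorted(set(patients))
    if len(patients) < 2:
        raise ValidationError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_set = {patients[k] for k in order[:n_train]}
    return {p: ("train" if p in train_set else "test") for p in patients}


def split_by_patient(
    dataset: Dataset, train_fraction: float = 0.7, seed: int = 0
) -> Dataset:
    """Randomly assign whole patients to train/test at ``train_fraction``.

    All records of one patient land in the same split.  The achieved record
    fraction generally differs from the patient fraction when record counts
    vary per patient; it is logged for audit.  Deterministic given ``seed``.
    """
    split = split_patients((r.patient_id for r in dataset.records), train_fraction, seed)
    dataset.split = split
    n_train = sum(1 for v in split.values() if v == "train")
    patients = list(split)
    n_rec_train = sum(1 for r in dataset.records if split[r.patient_id] == "train")
    logger.info(
        "patient split: %d/%d patients in train; achieved record fraction %.3f",
        n_train,
        len(patients),
        n_rec_train / len(dataset.records),
    )
    return dataset
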
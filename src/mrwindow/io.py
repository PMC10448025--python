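"""Readers and writers for windowing records, image series, and config files.

Windowing records are delimited text with a header row.  Column names and the
delimiter are configurable through a :class:`RecordDialect`, so exports from
different RIS/PACS systems can be ingested without editing the file.  Images
are NIfTI (``.nii``/``.nii.gz``, read through nibabel, which applies the
format's own slope/intercept scaling) or a plain NumPy exchange container
(``.npy``/``.npz``) used for fixtures and synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    ConditionRegistry,
    Frame,
    ImagingCondition,
    MRSeries,
    WindowSetting,
    WindowingRecord,
)
from .errors import FormatError, MRWindowError, ValidationError

PathLike = Union[str, Path]

DEFAULT_OPERATOR_COUNT = 3


@dataclass
class RecordDialect:
    """Column naming and delimiter for windowing-record files."""

    delimiter: str = ","
    patient_id: str = "patient_id"
    series_id: str = "series_id"
    sequence: str = "sequence"
    region: str = "region"
    operator: str = "operator"
    wl: str = "WL"
    ww: str = "WW"
    frame: str = "frame"  # optional column; absent => native

    @classmethod
    def from_config(cls, cfg: Dict) -> "RecordDialect":
        return cls(**{k: v for k, v in cfg.items() if k in cls.__dataclass_fields__})

    @property
    def required_columns(self) -> List[str]:
        return [
            self.patient_id,
            self.series_id,
            self.sequence,
            self.region,
            self.operator,
            self.wl,
            self.ww,
        ]


def read_windowing_records(
    path: PathLike,
    registry: Optional[ConditionRegistry] = None,
    dialect: Optional[RecordDialect] = None,
    n_operators: int = DEFAULT_OPERATOR_COUNT,
) -> List[WindowingRecord]:
    """Read one windowing record per row, interning conditions into ``registry``.

    Malformed rows (WW <= 0, operator out of 1..n_operators, unknown frame)
    are collected and reported together in a single :class:`ValidationError`;
    a missing column raises :class:`FormatError` naming the column.
    """
    dialect = dialect or RecordDialect()
    registry = registry if registry is not None else ConditionRegistry()
    df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    missing = [c for c in dialect.required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_frame = dialect.frame in df.columns

    records: List[WindowingRecord] = []
    problems: List[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        r = dict(zip(df.columns, row))
        try:
            ww = float(r[dialect.ww])
            if not ww > 0:
                raise ValidationError(f"WW must be > 0, got {ww}")
            op = int(r[dialect.operator])
            if not 1 <= op <= n_operators:
                raise ValidationError(
                    f"operator must be in 1..{n_operators}, got {op}"
                )
            frame = Frame.NATIVE
            if has_frame and not pd.isna(r[dialect.frame]):
                frame = Frame(str(r[dialect.frame]))
            cond = registry.intern(str(r[dialect.sequence]), str(r[dialect.region]))
            records.append(
                WindowingRecord(
                    series_id=str(r[dialect.series_id]),
                    patient_id=str(r[dialect.patient_id]),
                    condition=cond,
                    operator=op,
                    window=WindowSetting(float(r[dialect.wl]), ww),
                    frame=frame,
                )
            )
        except (MRWindowError, ValueError) as exc:
            problems.append(f"row {row_no}: {exc}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems)
        )
    return records


def write_windowing_records(
    records: Sequence[WindowingRecord],
    path: PathLike,
    dialect: Optional[RecordDialect] = None,
) -> None:
    dialect = dialect or RecordDialect()
    df = pd.DataFrame(
        {
            dialect.patient_id: [r.patient_id for r in records],
            dialect.series_id: [r.series_id for r in records],
            dialect.sequence: [r.condition.sequence for r in records],
            dialect.region: [r.condition.region for r in records],
            dialect.operator: [r.operator for r in records],
            dialect.wl: [repr(r.window.wl) for r in records],
            dialect.ww: [repr(r.window.ww) for r in records],
            dialect.frame: [r.frame.value for r in records],
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False)


def read_series(
    path: PathLike,
    condition: ImagingCondition,
    series_id: str,
    patient_id: str = "",
) -> MRSeries:
    """Load a voxel array as an :class:`MRSeries`.

    NIfTI data are returned with the header's scl_slope/scl_inter applied
    (nibabel's ``get_fdata``); ``.npy``/``.npz`` arrays are taken verbatim.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            voxels = np.asanyarray(nib.load(str(path)).get_fdata())
        elif path.suffix == ".npy":
            voxels = np.load(path)
        elif path.suffix == ".npz":
            with np.load(path) as z:
                voxels = z["voxels"]
        else:
            raise FormatError(f"{path}: unsupported image format {path.suffix!r}")
    except FormatError:
        raise
    except Exception as exc:  # nibabel/numpy raise their own hierarchies
        raise MRWindowError(f"{path}: cannot read image: {exc}") from exc
    if voxels.size == 0:
        raise ValidationError(f"{path}: image contains no voxels")
    return MRSeries(
        series_id=series_id, patient_id=patient_id, condition=condition, voxels=voxels
    )


def write_series(series: MRSeries, path: PathLike) -> None:
    """Write voxels as NIfTI or the ``.npy`` exchange container, by suffix."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vox = series.voxels
        if vox.ndim == 1:
            vox = vox.reshape(-1, 1, 1)
        nib.save(nib.Nifti1Image(vox.astype(np.float64), np.eye(4)), str(path))
    elif path.suffix == ".npy":
        np.save(path, series.voxels)
    else:
        raise FormatError(f"{path}: unsupported image format {path.suffix!r}")


def load_config(path: PathLike) -> Dict:
    """Load the single structured (YAML) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
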
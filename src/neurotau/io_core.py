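"""Core containers and readers/writers shared by every pipeline stage.

The in-memory currency of the pipeline is deliberately small:

* :class:`VolumeGrid` — a voxel grid plus its affine (voxel -> mm).
* :class:`Mask` — the gray-matter domain; all maps live on its in-mask voxels.
* :class:`BoldRun` — masked voxel x time BOLD data with the repetition time.
* :class:`ScalarMap` — one value per in-mask voxel (timescale, ALFF, FCD, t).
* :class:`Parcellation` — integer-labelled atlas with hemisphere tags.
* :class:`SubjectTable` — per-subject covariates and group labels.

Voxel ordering convention: everywhere in the package, in-mask voxels are
enumerated in row-major (C) order over the ``True`` entries of the mask
indicator.  Missing values in a :class:`ScalarMap` are encoded as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, GridMismatchError, SchemaError

log = logging.getLogger("neurotau")

_REQUIRED_SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "mean_fd",
    "snr0",
    "education",
    "illness_duration",
    "hamd",
)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid with the affine mapping voxel indices to mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise DataError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise DataError("affine is singular")
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise DataError(f"grid shape must be 3 positive ints, got {shape}")
        object.__setattr__(self, "affine", affine)

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class Mask:
    """Boolean gray-matter indicator on a grid.

    ``flat_indices`` enumerates in-mask voxels in row-major order; this
    ordering is the package-wide convention for the ``values`` vector of
    every :class:`ScalarMap` and the rows of every :class:`BoldRun`.
    """

    grid: VolumeGrid
    indicator: np.ndarray

    def __post_init__(self):
        ind = np.asarray(self.indicator, dtype=bool)
        if ind.shape != self.grid.shape:
            raise GridMismatchError(
                f"indicator shape {ind.shape} != grid shape {self.grid.shape}"
            )
        if not ind.any():
            raise DataError("mask has no voxels")
        object.__setattr__(self, "indicator", ind)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Row-major flat indices of in-mask voxels (deterministic)."""
        return np.flatnonzero(self.indicator.ravel(order="C"))

    @property
    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates in the same order."""
        return np.array(np.unravel_index(self.flat_indices, self.grid.shape)).T

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a full 3D volume."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise GridMismatchError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        vol = np.full(int(np.prod(self.grid.shape)), fill, dtype=float)
        vol[self.flat_indices] = values
        return vol.reshape(self.grid.shape)


@dataclass(frozen=True)
class BoldRun:
    """Masked voxel x time BOLD data for one subject."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    mask: Mask

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != self.mask.n_voxels:
            raise GridMismatchError(
                f"data shape {data.shape} inconsistent with mask "
                f"({self.mask.n_voxels} voxels)"
            )
        if data.shape[1] < 20:
            raise DataError(f"need at least 20 timepoints, got {data.shape[1]}")
        if not np.isfinite(data).all():
            bad = np.argwhere(~np.isfinite(data).all(axis=1)).ravel()
            raise DataError(f"non-finite values at voxel rows {bad[:10].tolist()}")
        if self.tr_seconds <= 0:
            raise DataError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ScalarMap:
    """One real value per in-mask voxel; NaN marks missing voxels."""

    values: np.ndarray
    mask: Mask
    name: str = ""
    units: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.mask.n_voxels,):
            raise GridMismatchError(
                f"map has {values.shape} values for a {self.mask.n_voxels}-voxel mask"
            )
        if np.isinf(values).any():
            raise DataError("map contains infinite values")
        self.values = values

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def volume(self, fill: float = 0.0) -> np.ndarray:
        vals = np.where(self.missing, fill, self.values)
        return self.mask.unmask(vals, fill=fill)


@dataclass(frozen=True)
class Parcellation:
    """Integer-labelled atlas; label 0 is background."""

    grid: VolumeGrid
    labels: np.ndarray
    hemisphere: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise DataError("parcellation labels must be integers")
            labels = np.round(labels).astype(np.int32)
        if labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"labels shape {labels.shape} != grid shape {self.grid.shape}"
            )
        if (labels < 0).any():
            raise DataError("parcellation labels must be non-negative")
        object.__setattr__(self, "labels", labels)
        hemi = dict(self.hemisphere)
        for pid, tag in hemi.items():
            if tag not in ("left", "right", "midline"):
                raise DataError(f"bad hemisphere tag {tag!r} for parcel {pid}")
        object.__setattr__(self, "hemisphere", hemi)

    @property
    def parcel_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


class SubjectTable:
    """Typed wrapper around the per-subject covariate table.

    Columns: subject_id, group (HC/MDD), age, sex (F/M), mean_fd, snr0,
    education, illness_duration (months; NaN for HC), hamd (NaN for HC).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _REQUIRED_SUBJECT_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"subject table missing columns: {missing}")
        frame = frame.copy()
        if frame["subject_id"].duplicated().any():
            dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
            raise SchemaError(f"duplicate subject_id: {dup}")
        bad_group = set(frame["group"]) - {"HC", "MDD"}
        if bad_group:
            raise SchemaError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(frame["sex"]) - {"F", "M"}
        if bad_sex:
            raise SchemaError(f"unknown sex labels: {sorted(bad_sex)}")
        for col in ("age", "mean_fd", "snr0", "education", "illness_duration", "hamd"):
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        dur = frame["illness_duration"]
        if (dur.dropna() < 0).any():
            raise DataError("negative illness_duration")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def subset(self, mask) -> "SubjectTable":
        return SubjectTable(self.frame.loc[np.asarray(mask)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_img(img) -> VolumeGrid:
    return VolumeGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def read_mask(path) -> Mask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GridMismatchError(f"mask must be 3D, got shape {data.shape}")
    return Mask(grid=_grid_from_img(img), indicator=data > 0)


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(
        mask.indicator.astype(np.uint8), affine=mask.grid.affine
    )
    nib.save(img, str(path))


def read_bold(path, mask: Mask, tr_seconds: float) -> BoldRun:
    """Read a 4D NIfTI and extract in-mask voxel time series.

    The TR is supplied explicitly; if the header pixdim[4] disagrees by more
    than 1 ms a warning is logged (headers in shared data are often wrong).
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise GridMismatchError(f"expected 4D BOLD, got shape {img.shape}")
    grid = _grid_from_img(img)
    if not grid.matches(mask.grid):
        raise GridMismatchError(
            f"BOLD grid {grid.shape} / affine does not match mask grid"
        )
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if header_tr > 0 and abs(header_tr - tr_seconds) > 1e-3:
        log.warning(
            "header TR %.4f s differs from supplied TR %.4f s; using supplied",
            header_tr,
            tr_seconds,
        )
    data4d = np.asanyarray(img.dataobj, dtype=np.float64)
    if data4d.shape[3] < 20:
        raise DataError(f"too-short run: T={data4d.shape[3]} < 20")
    flat = data4d.reshape(-1, data4d.shape[3])[mask.flat_indices]
    if not np.isfinite(flat).all():
        bad_rows = np.flatnonzero(~np.isfinite(flat).all(axis=1))
        coords = mask.voxel_coords[bad_rows[:5]]
        raise DataError(f"non-finite BOLD values at voxels {coords.tolist()}")
    import os

    subject_id = os.path.basename(str(path)).split(".")[0]
    return BoldRun(subject_id=subject_id, data=flat, tr_seconds=tr_seconds, mask=mask)


def write_bold(run: BoldRun, path) -> None:
    """Write a masked run back to a 4D NIfTI (out-of-mask voxels are zero)."""
    shape = run.mask.grid.shape
    vol = np.zeros((int(np.prod(shape)), run.n_timepoints), dtype=np.float32)
    vol[run.mask.flat_indices] = run.data.astype(np.float32)
    img = nib.Nifti1Image(vol.reshape(*shape, run.n_timepoints), run.mask.grid.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_seconds))
    nib.save(img, str(path))


def write_map(scalar_map: ScalarMap, path) -> None:
    """Write a ScalarMap as float32 NIfTI; out-of-mask and missing voxels -> 0."""
    vol = scalar_map.volume(fill=0.0).astype(np.float32)
    img = nib.Nifti1Image(vol, scalar_map.mask.grid.affine)
    nib.save(img, str(path))


def read_map(path, mask: Mask, name: str = "", units: str = "") -> ScalarMap:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise GridMismatchError(f"scalar map must be 3D, got {img.shape}")
    grid = _grid_from_img(img)
    if not grid.matches(mask.grid):
        raise GridMismatchError("map grid does not match mask grid")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    values = data.ravel(order="C")[mask.flat_indices]
    return ScalarMap(values=values, mask=mask, name=name or str(path), units=units)


def read_parcellation(path, hemisphere: dict | None = None) -> Parcellation:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return Parcellation(
        grid=_grid_from_img(img),
        labels=np.round(data).astype(np.int32),
        hemisphere=hemisphere or {},
    )


def write_parcellation(parc: Parcellation, path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Tabular I/O


def read_subject_table(path) -> SubjectTable:
    """Read the subject covariate TSV (empty fields encode missing values)."""
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return SubjectTable(frame)


def write_subject_table(table: SubjectTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="")


def read_parcel_table(path) -> pd.DataFrame:
    """Read a parcel-indexed TSV (first column parcel_id, one column per map)."""
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "parcel_id":
        raise SchemaError("first column of a parcel table must be 'parcel_id'")
    if frame["parcel_id"].duplicated().any():
        raise SchemaError("duplicate parcel_id rows")
    return frame.set_index("parcel_id")
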
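"""Volume and atlas I/O, Gaussian smoothing, and per-region value extraction.

The containers here are deliberately small: a gray-matter (GM) volume map is
a scalar 3-D grid with voxel geometry, and an atlas is an integer label grid
plus a region table. Everything downstream (density estimation, similarity,
graph analysis) consumes the per-region voxel-value vectors produced by
:func:`extract_region_values`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AlignmentError, DegenerateRegionError, FormatError

logger = logging.getLogger(__name__)

#: conversion factor between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

REGION_TABLE_COLUMNS = ["id", "name", "hemisphere", "category", "homotopic_partner_id"]

VALID_CATEGORIES = {"primary", "association", "paralimbic", "limbic", "subcortical"}


@dataclass
class GMVolumeMap:
    """One subject/session gray-matter volume map.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z)
        Voxelwise GM volume in arbitrary units (>= 0 for real data; the
        container itself only requires finite values).
    voxel_size_mm : tuple of float
        Voxel edge lengths in millimetres.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    subject_id, session_id : str
        Identifiers carried through the pipeline for bookkeeping.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"GM map must be 3-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("GM map contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise FormatError(f"voxel sizes must be three positive lengths, got {vs}")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([*vs, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class AtlasParcellation:
    """Integer label volume plus its region table.

    The table has columns ``id, name, hemisphere, category,
    homotopic_partner_id`` where ``homotopic_partner_id`` is the paired
    mirror region's id or <NA>.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "atlas"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise FormatError(f"atlas must be 3-D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.round(labels)
            if not np.allclose(labels, rounded, atol=1e-8):
                raise FormatError("atlas voxel values are not integers")
            labels = rounded.astype(np.int64)
        self.labels = labels.astype(np.int64)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([*vs, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

        regions = pd.DataFrame(self.regions).copy()
        missing = [c for c in REGION_TABLE_COLUMNS if c not in regions.columns]
        if missing:
            raise FormatError(f"region table missing columns: {missing}")
        regions["id"] = regions["id"].astype(int)
        regions["homotopic_partner_id"] = regions["homotopic_partner_id"].astype("Int64")
        if regions["id"].duplicated().any():
            raise FormatError("region ids are not unique")
        table_ids = set(regions["id"])
        present = set(np.unique(self.labels)) - {0}
        absent = sorted(present - table_ids)
        if absent:
            raise FormatError(f"labels present in image but absent from table: {absent}")
        # homotopic pairing must be symmetric
        partner = dict(
            zip(regions["id"], regions["homotopic_partner_id"], strict=True)
        )
        for rid, pid in partner.items():
            if pd.isna(pid):
                continue
            pid = int(pid)
            if pid not in partner or int(partner[pid]) != rid:
                raise FormatError(f"homotopic pairing not symmetric for region {rid}")
        self.regions = regions.reset_index(drop=True)

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["id"].to_numpy()

    @property
    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Unordered homotopic pairs, each reported once as (low, high)."""
        pairs = set()
        for rid, pid in zip(
            self.regions["id"], self.regions["homotopic_partner_id"], strict=True
        ):
            if pd.isna(pid):
                continue
            pairs.add(tuple(sorted((int(rid), int(pid)))))
        return sorted(pairs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _load_3d(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=float), zooms


def read_gm_map(path: str | Path, subject_id: str = "", session_id: str = "") -> GMVolumeMap:
    """Read a scalar 3-D GM volume map from a NIfTI file."""
    data, affine, zooms = _load_3d(path)
    return GMVolumeMap(
        values=data.astype(float),
        voxel_size_mm=zooms,  # type: ignore[arg-type]
        affine=affine,
        subject_id=subject_id,
        session_id=session_id,
    )


def write_gm_map(gm_map: GMVolumeMap, path: str | Path) -> None:
    img = nib.Nifti1Image(gm_map.values.astype(np.float64), gm_map.affine)
    img.header.set_zooms(gm_map.voxel_size_mm)
    nib.save(img, str(path))


def read_atlas(path: str | Path, table_path: str | Path, name: str = "") -> AtlasParcellation:
    """Read an integer label volume and its TSV region table."""
    data, affine, zooms = _load_3d(path)
    regions = pd.read_csv(table_path, sep="\t")
    return AtlasParcellation(
        labels=data,
        regions=regions,
        voxel_size_mm=zooms,  # type: ignore[arg-type]
        affine=affine,
        name=name or Path(path).stem,
    )


def write_atlas(atlas: AtlasParcellation, path: str | Path, table_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    img.header.set_zooms(atlas.voxel_size_mm)
    nib.save(img, str(path))
    atlas.regions.to_csv(table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_gm_map(gm_map: GMVolumeMap, fwhm_mm: float = 6.0) -> GMVolumeMap:
    """Apply an isotropic-in-mm Gaussian smooth.

    The per-axis kernel width in voxels is
    ``fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm[axis]``. Boundaries use
    zero padding, the convention of volumetric smoothing in neuroimaging
    pipelines. ``fwhm_mm == 0`` returns an identical copy.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return replace(gm_map, values=gm_map.values.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in gm_map.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(gm_map.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return replace(gm_map, values=smoothed)


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Kernel standard deviation in voxel units for a given FWHM in mm."""
    return fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_region_values(
    gm_map: GMVolumeMap,
    atlas: AtlasParcellation,
    region_id: int,
    positive_only: bool = True,
    min_voxels: int = 10,
) -> np.ndarray:
    """Voxel values of ``gm_map`` under the atlas mask of ``region_id``.

    Values are returned in raster (C) order, so the output is deterministic.
    With ``positive_only`` (default), exact zeros are dropped: under an atlas
    mask a zero GM voxel is background bleed and would distort the density.
    Regions with fewer than ``min_voxels`` usable voxels raise
    :class:`DegenerateRegionError` — a density estimate there is meaningless.
    """
    if gm_map.values.shape != atlas.labels.shape:
        raise AlignmentError(
            f"map shape {gm_map.values.shape} != atlas shape {atlas.labels.shape}"
        )
    if region_id not in set(atlas.regions["id"]):
        raise KeyError(f"region id {region_id} not in atlas table")
    vals = gm_map.values[atlas.labels == region_id]
    if positive_only:
        vals = vals[vals > 0]
    if vals.size < min_voxels:
        raise DegenerateRegionError(
            f"region {region_id}: only {vals.size} usable voxels (< {min_voxels})"
        )
    return np.ascontiguousarray(vals, dtype=float)


def extract_all_regions(
    gm_map: GMVolumeMap,
    atlas: AtlasParcellation,
    positive_only: bool = True,
    min_voxels: int = 10,
) -> dict[int, np.ndarray]:
    """Per-region value vectors for every region in the atlas table."""
    return {
        int(rid): extract_region_values(
            gm_map, atlas, int(rid), positive_only=positive_only, min_voxels=min_voxels
        )
        for rid in atlas.region_ids
    }
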
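"""Reading and writing volumes and regional tables.

Volumes are NIfTI (via nibabel); regional tables are TSV with a fixed header
(``region_id``, ``region_name``, ``compartment``, ``hemisphere``, then one
column per quantity). Invalid regions are spelled ``NaN`` so tables are
diff-able and round-trip exactly.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas, RegionInfo, require_same_atlas
from .errors import ContractError, FormatError
from .maps import RegionalMap

_META_COLUMNS = ["region_id", "region_name", "compartment", "hemisphere"]


def read_volume(path: str) -> Tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI volume; returns (data, affine) with NaNs preserved."""
    if not os.path.exists(path):
        raise FormatError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=float)
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected 3-D volume in {path}, got {data.ndim}-D")
    return data, img.affine


def write_volume(data: np.ndarray, path: str, affine: Optional[np.ndarray] = None) -> None:
    """Write a 3-D grid as NIfTI; identity affine by default."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ContractError(f"expected 3-D volume, got {data.ndim}-D")
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)


def read_label_volume(path: str) -> Tuple[np.ndarray, np.ndarray]:
    """Read an integer label volume (0 = background)."""
    data, affine = read_volume(path)
    rounded = np.round(data)
    if not np.allclose(data, rounded, atol=1e-6, equal_nan=False):
        raise FormatError(f"label volume {path} has non-integer voxel values")
    return rounded.astype(np.int32), affine


def _column_names(maps: Sequence[RegionalMap], names: Optional[Sequence[str]]) -> List[str]:
    if names is not None:
        if len(names) != len(maps):
            raise ContractError("one column name per map required")
        cols = list(names)
    else:
        cols, seen = [], {}
        for m in maps:
            base = m.quantity
            seen[base] = seen.get(base, 0) + 1
            cols.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
    if len(set(cols)) != len(cols):
        raise ContractError(f"duplicate column names {cols}")
    return cols


def write_regional_table(maps, path: str, names: Optional[Sequence[str]] = None) -> None:
    """Write one or more maps sharing an atlas to a TSV (one row per region)."""
    if isinstance(maps, RegionalMap):
        maps = [maps]
    if not maps:
        raise ContractError("no maps to write")
    atlas = maps[0].atlas
    for m in maps[1:]:
        require_same_atlas(atlas, m.atlas)
    cols = _column_names(maps, names)
    frame = pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "region_name": [r.name for r in atlas.regions],
            "compartment": [r.compartment for r in atlas.regions],
            "hemisphere": [r.hemisphere for r in atlas.regions],
        }
    )
    for col, m in zip(cols, maps):
        frame[col] = np.where(m.valid, m.values, np.nan)
    # repr() is the shortest digit string that round-trips the double exactly
    frame.to_csv(path, sep="\t", index=False, na_rep="NaN",
                 float_format=lambda v: repr(float(v)))


def read_regional_table(path: str, atlas: Optional[ParcellationAtlas] = None):
    """Read a regional TSV back into a list of :class:`RegionalMap`.

    Reconstructs an atlas (without voxel geometry) from the metadata columns
    unless an ``atlas`` is supplied, in which case rows are checked and
    aligned against it.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such table file: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"table {path} missing required columns {missing}")
    if frame["region_id"].duplicated().any():
        dupes = frame.loc[frame["region_id"].duplicated(), "region_id"].tolist()
        raise FormatError(f"duplicate region_id values {sorted(set(dupes))} in {path}")
    if atlas is None:
        regions = [
            RegionInfo(int(row.region_id), str(row.region_name),
                       str(row.compartment), str(row.hemisphere))
            for row in frame.itertuples()
        ]
        atlas = ParcellationAtlas(regions=regions, name=os.path.basename(path))
    else:
        table_ids = frame["region_id"].to_numpy(dtype=int)
        if not np.array_equal(np.sort(table_ids), np.sort(atlas.region_ids)):
            raise ContractError(f"table {path} region ids do not match atlas")
        pos = {rid: i for i, rid in enumerate(table_ids)}
        frame = frame.iloc[[pos[rid] for rid in atlas.region_ids]].reset_index(drop=True)
    value_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    maps = []
    for col in value_cols:
        values = frame[col].to_numpy(dtype=float)
        quantity = col.split("_")[0] if col.split("_")[0] in ("mean", "std", "cv") else "mean"
        if col.startswith("scaled_cv"):
            quantity = "scaled_cv"
        maps.append(RegionalMap(atlas=atlas, values=values, quantity=quantity, units_label=col))
    return maps
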
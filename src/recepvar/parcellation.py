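"""Voxel-to-region reduction and tracer-specific region exclusions.

Parcellation takes the unweighted arithmetic mean of the non-NaN voxels in
each label; a region with no finite voxels (or no voxels at all) becomes
invalid rather than zero, because a zero would corrupt downstream CV
denominators. No partial-volume weighting is applied.
"""

from __future__ import annotations

import numpy as np

from .atlas import ParcellationAtlas
from .errors import ContractError
from .maps import RegionalMap, TracerStudy


def parcellate_volume(volume: np.ndarray, atlas: ParcellationAtlas,
                      quantity: str = "mean", units_label: str = "") -> RegionalMap:
    """Reduce a voxelwise volume to one mean value per atlas region."""
    if atlas.label_volume is None:
        raise ContractError("atlas has no label volume; cannot parcellate")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas.label_volume.shape:
        raise ContractError(
            f"volume shape {volume.shape} != atlas shape {atlas.label_volume.shape}"
        )
    labels = atlas.label_volume.ravel()
    vals = volume.ravel()
    finite = np.isfinite(vals) & (labels > 0)
    nmax = int(labels.max()) + 1
    sums = np.bincount(labels[finite], weights=vals[finite], minlength=nmax)
    counts = np.bincount(labels[finite], minlength=nmax)
    out = np.full(atlas.n_regions, np.nan)
    for i, rid in enumerate(atlas.region_ids):
        if rid < nmax and counts[rid] > 0:
            out[i] = sums[rid] / counts[rid]
    return RegionalMap(atlas=atlas, values=out, quantity=quantity, units_label=units_label)


def embed_regional(regional: RegionalMap, atlas: ParcellationAtlas = None) -> np.ndarray:
    """Paint each region's value into its voxels; background/invalid -> NaN.

    Inverse of :func:`parcellate_volume` on piecewise-constant volumes.
    """
    atlas = atlas or regional.atlas
    if atlas.label_volume is None:
        raise ContractError("atlas has no label volume; cannot embed")
    if not atlas.same_regions(regional.atlas):
        raise ContractError("map does not match atlas")
    lut = np.full(int(atlas.label_volume.max()) + 1, np.nan)
    for i, rid in enumerate(atlas.region_ids):
        if regional.valid[i]:
            lut[rid] = regional.values[i]
    return lut[atlas.label_volume]


def apply_exclusions(regional: RegionalMap, study: TracerStudy) -> RegionalMap:
    """Invalidate reference-region ids and, for striatum-only tracers, all
    non-striatal regions. Values of surviving regions are untouched."""
    if not regional.atlas.same_regions(study.atlas):
        raise ContractError("map does not belong to the study's atlas")
    valid = regional.valid.copy()
    if study.reference_exclusion:
        idx = [regional.atlas.index_of(rid) for rid in study.reference_exclusion]
        valid[idx] = False
    if study.striatum_only:
        from .atlas import striatal_regions

        keep = striatal_regions(regional.atlas)
        for i, rid in enumerate(regional.atlas.region_ids):
            if rid not in keep:
                valid[i] = False
    return regional.with_values(regional.values, valid=valid)
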
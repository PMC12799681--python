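"""Parcellation atlas bookkeeping.

The analysis operates on a pair of co-registered label volumes: a cortical
parcellation (100 regions, Schaefer-style, 7 resting-state networks split
between hemispheres) and a subcortical parcellation (54 regions,
Melbourne-Subcortex-style structures). Both are represented jointly as one
:class:`ParcellationAtlas` whose region list carries the compartment
(cortex/subcortex) of every label.

Real atlas volumes can be loaded from NIfTI; :func:`build_default_atlas`
constructs a small synthetic stand-in with the same region bookkeeping
(100 + 54 regions, hemispheres, network/structure names) so that every
stage of the pipeline is exercisable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ContractError

CORTEX = "cortex"
SUBCORTEX = "subcortex"
COMPARTMENTS = (CORTEX, SUBCORTEX)

# Schaefer-style network names; the Vis block doubles as the occipital lobe
# for the MOR reference-region exclusion preset.
_CORTICAL_NETWORKS = [
    ("Vis", 8),
    ("SomMot", 8),
    ("DorsAttn", 7),
    ("SalVentAttn", 7),
    ("Limbic", 6),
    ("Cont", 7),
    ("Default", 7),
]  # 50 regions per hemisphere

# Melbourne-style subcortical structures, 3 subdivisions each per hemisphere.
_SUBCORTICAL_STRUCTURES = ["HIP", "AMY", "aTHA", "pTHA", "NAc", "CAU", "PUT", "GP", "HTH"]
_STRIATAL_STRUCTURES = ("NAc", "CAU", "PUT")


@dataclass(frozen=True)
class RegionInfo:
    """One atlas region: integer label, name, compartment, hemisphere."""

    region_id: int
    name: str
    compartment: str
    hemisphere: str = "NA"

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ContractError(f"region_id must be positive, got {self.region_id}")
        if self.compartment not in COMPARTMENTS:
            raise ContractError(f"unknown compartment {self.compartment!r}")
        if self.hemisphere not in ("L", "R", "NA"):
            raise ContractError(f"hemisphere must be L/R/NA, got {self.hemisphere!r}")


@dataclass
class ParcellationAtlas:
    """A labelled brain volume plus per-region metadata.

    ``label_volume`` is an integer 3-D grid where 0 is background and every
    nonzero label appears in ``regions``. It may be ``None`` for atlases
    reconstructed from regional tables (no voxel geometry available).
    """

    regions: Sequence[RegionInfo]
    label_volume: Optional[np.ndarray] = None
    voxel_dimensions: tuple = (1.0, 1.0, 1.0)
    name: str = "atlas"
    _id_index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ContractError("duplicate region_id in atlas")
        self._id_index = {rid: i for i, rid in enumerate(ids)}
        if self.label_volume is not None:
            lv = np.asarray(self.label_volume)
            if lv.ndim != 3:
                raise ContractError("label_volume must be 3-D")
            if not np.issubdtype(lv.dtype, np.integer):
                raise ContractError("label_volume must be integer-valued")
            present = set(np.unique(lv).tolist()) - {0}
            missing = present - set(ids)
            if missing:
                raise ContractError(f"labels {sorted(missing)} missing from region list")
            self.label_volume = lv

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions], dtype=int)

    @property
    def compartments(self) -> np.ndarray:
        return np.array([r.compartment for r in self.regions])

    def index_of(self, region_id: int) -> int:
        try:
            return self._id_index[region_id]
        except KeyError:
            raise ContractError(f"region_id {region_id} not in atlas {self.name!r}")

    def compartment_mask(self, compartment: str) -> np.ndarray:
        """Boolean mask (region order) selecting one compartment, or all if None."""
        if compartment is None:
            return np.ones(self.n_regions, dtype=bool)
        if compartment not in COMPARTMENTS:
            raise ContractError(f"unknown compartment {compartment!r}")
        return self.compartments == compartment

    def same_regions(self, other: "ParcellationAtlas") -> bool:
        """Two atlases are interchangeable when region ids/compartments agree."""
        return (
            self.n_regions == other.n_regions
            and np.array_equal(self.region_ids, other.region_ids)
            and np.array_equal(self.compartments, other.compartments)
        )

    def regions_matching(self, pattern: str) -> set:
        """Region ids whose name contains ``pattern`` (case-sensitive substring)."""
        return {r.region_id for r in self.regions if pattern in r.name}


def require_same_atlas(a: ParcellationAtlas, b: ParcellationAtlas, what: str = "maps") -> None:
    if not a.same_regions(b):
        raise ContractError(f"{what} do not share an atlas ({a.name!r} vs {b.name!r})")


def _default_regions() -> list:
    regions = []
    label = 0
    for hemi in ("L", "R"):
        for net, count in _CORTICAL_NETWORKS:
            for i in range(1, count + 1):
                label += 1
                regions.append(
                    RegionInfo(label, f"Ctx_{hemi}_{net}_{i}", CORTEX, hemi)
                )
    for hemi in ("L", "R"):
        for struct in _SUBCORTICAL_STRUCTURES:
            for i in range(1, 4):
                label += 1
                regions.append(
                    RegionInfo(label, f"Sub_{hemi}_{struct}_{i}", SUBCORTEX, hemi)
                )
    assert label == 154
    return regions


def build_default_atlas(shape: tuple = (12, 12, 6), voxel_dimensions: tuple = (2.0, 2.0, 2.0)) -> ParcellationAtlas:
    """Synthetic 100-cortex + 54-subcortex atlas with a compact label volume.

    Voxels are assigned to the 154 labels in contiguous flat-index blocks of
    equal size; leftover voxels stay background (label 0). The geometry is
    artificial but the label/region bookkeeping matches the real atlas pair,
    which is all the parcellation statistics depend on. The block size is a
    power of two so that averaging a region's (identical) voxels after
    :func:`~recepvar.parcellation.embed_regional` is bitwise exact.
    """
    regions = _default_regions()
    n_vox = int(np.prod(shape))
    n_reg = len(regions)
    if n_vox < 2 * n_reg:
        raise ContractError(f"shape {shape} too small for {n_reg} regions")
    per = 2 ** int(np.log2(n_vox // n_reg))
    labels = np.zeros(n_vox, dtype=np.int32)
    for i in range(n_reg):
        labels[i * per : (i + 1) * per] = regions[i].region_id
    return ParcellationAtlas(
        regions=regions,
        label_volume=labels.reshape(shape),
        voxel_dimensions=voxel_dimensions,
        name="synthetic-schaefer100-tianS4",
    )


def occipital_regions(atlas: ParcellationAtlas) -> set:
    """Preset: occipital-cortex region ids (the MOR reference region)."""
    ids = atlas.regions_matching("_Vis_")
    if not ids:
        raise ContractError("atlas has no occipital ('Vis') regions; supply ids explicitly")
    return ids


def striatal_regions(atlas: ParcellationAtlas) -> set:
    """Preset: striatal region ids (the only reliable raclopride territory)."""
    ids: set = set()
    for struct in _STRIATAL_STRUCTURES:
        ids |= atlas.regions_matching(f"_{struct}_")
    if not ids:
        raise ContractError("atlas has no striatal regions; supply ids explicitly")
    return ids
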
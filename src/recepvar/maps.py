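"""Regional maps and study containers.

A :class:`RegionalMap` holds one scalar per atlas region (a group mean, a
group standard deviation, or a coefficient of variation) together with a
validity mask: regions excluded by reference-region rules or the low-binding
filter are invalid and serialize as NaN. A :class:`TracerStudy` bundles the
mean and standard-deviation maps contributed for one tracer with its cohort
metadata (receptor, tracer, binding measure, N, age) and its
exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .atlas import ParcellationAtlas, require_same_atlas
from .errors import ContractError

QUANTITIES = ("mean", "std", "cv", "scaled_cv")
MEASURES = ("BP_ND", "V_T", "B_max", "SUVR")


@dataclass
class RegionalMap:
    """Per-region scalar values with a validity mask, tied to an atlas."""

    atlas: ParcellationAtlas
    values: np.ndarray
    valid: Optional[np.ndarray] = None
    quantity: str = "mean"
    units_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.ndim != 1 or self.values.size != self.atlas.n_regions:
            raise ContractError(
                f"values length {self.values.size} != atlas region count {self.atlas.n_regions}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).copy()
            if self.valid.shape != self.values.shape:
                raise ContractError("valid mask shape mismatch")
            # a non-finite value cannot be valid
            self.valid &= np.isfinite(self.values)
        if self.quantity not in QUANTITIES:
            raise ContractError(f"unknown quantity {self.quantity!r}")
        self.values[~self.valid] = np.nan

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self, compartment: Optional[str] = None) -> np.ndarray:
        """Values of valid regions, optionally restricted to one compartment."""
        mask = self.valid & self.atlas.compartment_mask(compartment)
        return self.values[mask]

    def with_values(self, values: np.ndarray, quantity: Optional[str] = None,
                    valid: Optional[np.ndarray] = None) -> "RegionalMap":
        return RegionalMap(
            atlas=self.atlas,
            values=values,
            valid=self.valid if valid is None else valid,
            quantity=quantity or self.quantity,
            units_label=self.units_label,
        )

    def copy(self) -> "RegionalMap":
        return replace(self, values=self.values.copy(), valid=self.valid.copy())


@dataclass
class TracerStudy:
    """One contributed dataset: group mean/std maps plus cohort metadata."""

    receptor: str
    tracer: str
    measure: str
    n_subjects: int
    mean_map: RegionalMap
    std_map: RegionalMap
    n_female: int = 0
    age_mean: float = float("nan")
    age_sd: float = float("nan")
    reference_exclusion: frozenset = frozenset()
    striatum_only: bool = False
    study_id: str = ""
    family: str = ""  # receptor family for consistency grouping ("" = receptor)
    ground_truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ContractError(f"unknown binding measure {self.measure!r}")
        if self.n_subjects < 2:
            raise ContractError("n_subjects must be >= 2")
        if self.n_female < 0:
            raise ContractError("n_female must be nonnegative")
        require_same_atlas(self.mean_map.atlas, self.std_map.atlas, "mean/std maps")
        with np.errstate(invalid="ignore"):
            if np.any(self.std_map.values[self.std_map.valid] < 0):
                raise ContractError("std map contains negative values")
        self.reference_exclusion = frozenset(int(i) for i in self.reference_exclusion)
        known = set(self.mean_map.atlas.region_ids.tolist())
        bad = set(self.reference_exclusion) - known
        if bad:
            raise ContractError(f"exclusion ids {sorted(bad)} not in atlas")
        if not self.study_id:
            self.study_id = f"{self.receptor}:{self.tracer}"
        if not self.family:
            self.family = self.receptor

    @property
    def atlas(self) -> ParcellationAtlas:
        return self.mean_map.atlas


@dataclass
class CompartmentStats:
    """Summary statistics for one tracer within one compartment."""

    compartment: str
    inter_regional_cv: float
    mean_interindividual_cv: float
    ratio: float
    p_boot: float = float("nan")
    n_boot: int = 0
    seed: Optional[int] = None
    n_regions: int = 0
    significant: Optional[bool] = None


@dataclass
class VariabilityResult:
    """Per-tracer output: CV map, retained mask, per-compartment statistics."""

    study_id: str
    cv_map: RegionalMap
    retained: np.ndarray
    compartments: dict  # compartment name -> CompartmentStats

    def stats(self, compartment: str) -> CompartmentStats:
        return self.compartments[compartment]
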
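"""Coefficient-of-variation statistics.

The core quantities:

* **inter-individual CV** — per region, the group standard deviation of
  tracer binding divided by the group mean (sigma/mu); one value per region,
  describing how much a region's density varies across people.
* **inter-regional CV** — per map and compartment, the standard deviation of
  group-mean binding across regions divided by its mean; one value per brain
  map, describing how much density varies across the brain.
* **regional-to-population ratio** — inter-regional CV divided by the mean
  inter-individual CV over retained regions; above 1 means a tracer varies
  more across regions than across individuals.

Because a CV is unstable when its denominator approaches zero, regions with
near-zero mean binding are omitted before any CV is formed: by default a
region is dropped iff its mean is in the bottom 5th percentile of the map's
valid regions AND below 0.1 binding units (the conjunction is configurable
via :class:`FilterPolicy`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .atlas import require_same_atlas
from .errors import ContractError
from .maps import RegionalMap

logger = logging.getLogger(__name__)

_COMBINE_MODES = ("and", "or", "percentile_only")


@dataclass(frozen=True)
class FilterPolicy:
    """Low-binding omission rule applied before CV computation.

    percentile_cut: bottom percentile of valid mean-binding values (default 5).
    absolute_threshold: absolute binding cut in map units (default 0.1).
    combine: how the two conditions combine — "and" (default, the literal
        conditional reading of the rule), "or", or "percentile_only".
    """

    percentile_cut: float = 5.0
    absolute_threshold: float = 0.1
    combine: str = "and"

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile_cut <= 100.0:
            raise ContractError("percentile_cut must be in [0, 100]")
        if self.absolute_threshold < 0:
            raise ContractError("absolute_threshold must be nonnegative")
        if self.combine not in _COMBINE_MODES:
            raise ContractError(f"combine must be one of {_COMBINE_MODES}")

    def omitted(self, means: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Boolean mask of regions omitted for low binding.

        The percentile is computed over all valid regions of the map jointly
        (cortex + subcortex), with linear interpolation.
        """
        omit = np.zeros(means.shape, dtype=bool)
        if not valid.any():
            return omit
        cut = np.percentile(means[valid], self.percentile_cut)
        in_bottom = valid & (means <= cut)
        below_abs = valid & (means < self.absolute_threshold)
        if self.combine == "and":
            omit = in_bottom & below_abs
        elif self.combine == "or":
            omit = in_bottom | below_abs
        else:
            omit = in_bottom
        return omit


def interindividual_cv(
    mean_map: RegionalMap,
    std_map: RegionalMap,
    policy: Optional[FilterPolicy] = None,
) -> Tuple[RegionalMap, np.ndarray]:
    """Per-region CV map (sigma/mu) plus the retained-region mask.

    Regions invalid in either input, omitted by the filter policy, or with
    nonpositive mean are invalid in the output. A nonpositive mean in a
    region that survived the filter is logged and invalidated rather than
    raised, since upstream kinetic modelling can leave small negatives.
    """
    require_same_atlas(mean_map.atlas, std_map.atlas, "mean/std maps")
    policy = policy or FilterPolicy()
    with np.errstate(invalid="ignore"):
        if np.any(std_map.values[std_map.valid] < 0):
            raise ContractError("std map contains negative values")
    joint = mean_map.valid & std_map.valid
    retained = joint & ~policy.omitted(mean_map.values, joint)
    with np.errstate(invalid="ignore"):
        nonpositive = retained & ~(mean_map.values > 0)
    if nonpositive.any():
        bad = mean_map.atlas.region_ids[nonpositive].tolist()
        logger.warning("invalidating %d region(s) with nonpositive mean: %s", len(bad), bad)
        retained = retained & ~nonpositive
    cv = np.full(mean_map.values.shape, np.nan)
    cv[retained] = std_map.values[retained] / mean_map.values[retained]
    cv_map = RegionalMap(atlas=mean_map.atlas, values=cv, valid=retained, quantity="cv")
    return cv_map, retained


def interregional_cv(mean_map: RegionalMap, compartment: Optional[str] = None,
                     ddof: int = 1) -> float:
    """Across-region CV of group-mean binding for one compartment.

    Sample (n-1) standard deviation by default (``ddof`` configurable).
    """
    values = mean_map.valid_values(compartment)
    if values.size < 2:
        raise ContractError(
            f"need >= 2 valid regions in {compartment or 'map'}, got {values.size}"
        )
    mu = values.mean()
    if mu <= 0:
        raise ContractError("unstable coefficient of variation: mean <= 0 across regions")
    return float(values.std(ddof=ddof) / mu)


def mean_interindividual_cv(cv_map: RegionalMap, compartment: Optional[str] = None) -> float:
    """Mean CV over the retained regions of one compartment."""
    values = cv_map.valid_values(compartment)
    if values.size < 1:
        raise ContractError(f"no retained regions in {compartment or 'map'}")
    return float(values.mean())


def cv_ratio(inter_regional: float, cv_map: RegionalMap,
             compartment: Optional[str] = None) -> float:
    """Regional-to-population CV ratio: inter-regional CV / mean CV."""
    mean_cv = mean_interindividual_cv(cv_map, compartment)
    if mean_cv <= 0:
        raise ContractError("mean inter-individual CV must be positive")
    return float(inter_regional / mean_cv)


def minmax_scale(regional: RegionalMap, compartment: Optional[str] = None) -> RegionalMap:
    """Min-max scale valid values to [0, 1] (display normalization).

    With a compartment given, scaling is restricted to that compartment and
    regions outside it become invalid in the output.
    """
    scope = regional.valid & regional.atlas.compartment_mask(compartment)
    values = regional.values[scope]
    if values.size < 2:
        raise ContractError("need >= 2 valid regions to min-max scale")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ContractError("degenerate range: map is constant over valid regions")
    out = np.full(regional.values.shape, np.nan)
    out[scope] = (regional.values[scope] - lo) / (hi - lo)
    return RegionalMap(atlas=regional.atlas, values=out, valid=scope, quantity="scaled_cv")


def std_mean_scaling(mean_map: RegionalMap, std_map: RegionalMap,
                     compartment: Optional[str] = None) -> Tuple[float, float]:
    """Fluctuation-scaling diagnostic: does sigma grow with mu across regions?

    Returns ``(spearman_r, log_log_slope)`` over regions valid in both maps
    with strictly positive mean and std. The slope is the OLS fit of
    log sigma on log mu — the exponent beta in sigma = c * mu**beta.
    """
    require_same_atlas(mean_map.atlas, std_map.atlas, "mean/std maps")
    scope = mean_map.atlas.compartment_mask(compartment)
    with np.errstate(invalid="ignore"):
        ok = (mean_map.valid & std_map.valid & scope
              & (mean_map.values > 0) & (std_map.values > 0))
    if ok.sum() < 3:
        raise ContractError(f"need >= 3 positive regions, got {int(ok.sum())}")
    mu, sigma = mean_map.values[ok], std_map.values[ok]
    rho = stats.spearmanr(mu, sigma).statistic
    slope = stats.linregress(np.log(mu), np.log(sigma)).slope
    return float(rho), float(slope)
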
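"""Bootstrap inference and spatial-consistency scoring.

The bootstrap asks whether a tracer's inter-regional CV is significantly
greater than its inter-individual CV: the retained per-region CV values are
resampled with replacement 10,000 times, the mean of each resample forms a
null distribution of mean inter-individual CVs, and

    p = #(null mean >= empirical inter-regional CV) / n_boot

exactly as stated — no small-sample (+1) correction. Resampling is within
compartment because the inter-regional CV is defined for cortex and
subcortex separately.

Spatial consistency is the mean Spearman correlation between a tracer's
group-mean map and replicate group-mean maps of the same receptor from
other cohorts or tracers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ContractError
from .maps import RegionalMap

ALPHA_DEFAULT = 0.05


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-label random stream.

    Streams are derived from ``(seed, crc32(label)...)`` so that, for
    example, adding a tracer to a suite never perturbs the draws of the
    others.
    """
    keys = [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


@dataclass
class BootstrapResult:
    """Null distribution of bootstrap mean CVs and the resulting p-value."""

    null_means: np.ndarray = field(repr=False)
    p_value: float
    n_boot: int
    seed: Optional[int]
    compartment: Optional[str]
    threshold: float
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        """Inter-regional CV significantly greater than inter-individual CV."""
        return bool(self.p_value < self.alpha)


def bootstrap_compare(
    cv_map: RegionalMap,
    inter_regional_cv: float,
    compartment: Optional[str] = None,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    alpha: float = ALPHA_DEFAULT,
) -> BootstrapResult:
    """Bootstrap the retained CV distribution and compare to a threshold."""
    values = cv_map.valid_values(compartment)
    k = values.size
    if k < 2:
        raise ContractError(
            f"need >= 2 retained regions in {compartment or 'map'}, got {k}"
        )
    if n_boot < 1:
        raise ContractError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # resample in chunks so large n_boot stays memory-bounded
    null_means = np.empty(n_boot)
    chunk = max(1, min(n_boot, 5_000_000 // max(k, 1)))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, k, size=(stop - start, k))
        null_means[start:stop] = values[idx].mean(axis=1)
    p = float(np.count_nonzero(null_means >= inter_regional_cv)) / n_boot
    return BootstrapResult(
        null_means=null_means, p_value=p, n_boot=n_boot, seed=seed,
        compartment=compartment, threshold=float(inter_regional_cv), alpha=alpha,
    )


def enumerate_bootstrap_p(values: Sequence[float], threshold: float) -> float:
    """Exact bootstrap p by exhausting all k**k ordered resamples.

    Independent oracle for :func:`bootstrap_compare`; only feasible for
    small k (<= ~7).
    """
    values = np.asarray(values, dtype=float)
    k = values.size
    if k < 1 or k ** k > 5_000_000:
        raise ContractError(f"enumeration infeasible for k={k}")
    grids = np.meshgrid(*([values] * k), indexing="ij")
    means = np.mean(np.stack([g.ravel() for g in grids]), axis=0)
    return float(np.count_nonzero(means >= threshold)) / means.size


def spearman_spatial(map_a: RegionalMap, map_b: RegionalMap) -> float:
    """Spearman rank correlation over jointly valid regions (average ranks)."""
    if not map_a.atlas.same_regions(map_b.atlas):
        raise ContractError("maps do not share an atlas")
    joint = map_a.valid & map_b.valid
    if joint.sum() < 3:
        raise ContractError(f"need >= 3 jointly valid regions, got {int(joint.sum())}")
    a, b = map_a.values[joint], map_b.values[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ContractError("zero variance in ranks: constant map")
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class ConsistencyRecord:
    """Replicate-map agreement for one receptor."""

    receptor: str
    original_map_id: str
    other_map_ids: List[str]
    pairwise_r: List[float]
    mean_consistency: float


def mean_consistency(
    original: RegionalMap,
    others: Sequence[RegionalMap],
    receptor: str = "",
    original_map_id: str = "original",
    other_map_ids: Optional[Sequence[str]] = None,
    mode: str = "original_vs_others",
) -> ConsistencyRecord:
    """Mean spatial Spearman correlation across replicate group-mean maps.

    Default mode correlates the original map against each other map; the
    ``all_pairs`` mode averages Spearman r over every unordered pair among
    {original} + others. With a single other map the two coincide: the score
    is simply the correlation between the two group-mean images.
    """
    others = list(others)
    if not others:
        raise ContractError("need at least one other map")
    ids = list(other_map_ids) if other_map_ids is not None else [
        f"other_{i+1}" for i in range(len(others))
    ]
    if len(ids) != len(others):
        raise ContractError("one id per other map required")
    if mode == "original_vs_others":
        pairwise = [spearman_spatial(original, o) for o in others]
    elif mode == "all_pairs":
        pool = [original] + others
        pairwise = [
            spearman_spatial(pool[i], pool[j])
            for i in range(len(pool))
            for j in range(i + 1, len(pool))
        ]
    else:
        raise ContractError(f"unknown consistency mode {mode!r}")
    return ConsistencyRecord(
        receptor=receptor,
        original_map_id=original_map_id,
        other_map_ids=ids,
        pairwise_r=pairwise,
        mean_consistency=float(np.mean(pairwise)),
    )


def _permutation_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float,
                            n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p for a Spearman correlation (shuffle one vector).

    Spearman r is the Pearson correlation of average ranks, so the permuted
    statistics are computed vectorized on pre-ranked data.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.empty((n_perm, y.size))
    for i in range(n_perm):
        perms[i] = rng.permutation(ry)
    r_null = perms @ rx / x.size
    count = int(np.count_nonzero(np.abs(r_null) >= abs(r_obs) - 1e-12))
    return (count + 1) / (n_perm + 1)


def ratio_vs_consistency(
    ratios: Sequence[float],
    consistencies: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float, float]:
    """Across receptors, Spearman r between CV ratio and spatial consistency.

    Returns ``(r, p_perm, p_asymptotic)``. The permutation p is preferred at
    the small n (~14-16 receptors) typical here; the asymptotic p is reported
    for comparison.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(consistencies, dtype=float)
    if x.size != y.size:
        raise ContractError("ratios and consistencies differ in length")
    if x.size < 4:
        raise ContractError(f"need >= 4 paired receptors, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ContractError("constant vector: ranks undefined")
    res = stats.spearmanr(x, y)
    if rng is None:
        rng = np.random.default_rng(seed)
    p_perm = _permutation_spearman_p(x, y, res.statistic, n_perm, rng)
    return float(res.statistic), float(p_perm), float(res.pvalue)


def covariate_diagnostics(
    studies,
    cv_summaries: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
):
    """Correlate per-study mean inter-individual CV with N and mean age.

    Returns a pandas DataFrame with one row per covariate: Spearman r,
    permutation p, asymptotic p, and the number of studies used. Studies
    with a missing covariate are dropped (with a 'not testable' row if fewer
    than 4 remain or the CVs are constant).
    """
    import pandas as pd

    studies = list(studies)
    cvs = np.asarray(cv_summaries, dtype=float)
    if len(studies) != cvs.size:
        raise ContractError("one CV summary per study required")
    rows = []
    for covariate, getter in (("n_subjects", lambda s: s.n_subjects),
                              ("age_mean", lambda s: s.age_mean)):
        vals = np.array([float(getter(s)) for s in studies])
        ok = np.isfinite(vals) & np.isfinite(cvs)
        if ok.sum() < 4 or np.ptp(cvs[ok]) == 0 or np.ptp(vals[ok]) == 0:
            rows.append({"covariate": covariate, "spearman_r": np.nan,
                         "p_perm": np.nan, "p_asymptotic": np.nan,
                         "n_studies": int(ok.sum()), "note": "not testable"})
            continue
        res = stats.spearmanr(vals[ok], cvs[ok])
        rng = derive_rng(seed if seed is not None else 0, "covariate", covariate)
        p_perm = _permutation_spearman_p(vals[ok], cvs[ok], res.statistic, n_perm, rng)
        rows.append({"covariate": covariate, "spearman_r": float(res.statistic),
                     "p_perm": float(p_perm), "p_asymptotic": float(res.pvalue),
                     "n_studies": int(ok.sum()), "note": ""})
    return pd.DataFrame(rows)
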
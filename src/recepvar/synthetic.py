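"""Synthetic PET cohorts with the statistical structure the analysis assumes.

The generator emulates what contributed group mean/std images look like
after parcellation: per-region true mean binding profiles on the scales of
the usual binding measures (BP_ND around 0.5-3, V_T around 5-25, B_max in
tens of pmol/ml, SUVR around 1-4), subject noise whose standard deviation
scales with the regional mean (sigma_r = true_cv_r * true_mean_r, i.e. the
fluctuation-scaling exponent beta = 1 when true_cv is constant), near-zero
binding in reference regions, and an optional subject-specific global
multiplicative baseline shift (lognormal) — the "conserved spatial profile,
individually shifted baseline" scenario.

Subject s, region r:

    value[s, r] = shift_s * (true_mean_r + eps[s, r]),   shift_s ~ LogNormal(0, baseline_shift_sd)

with eps drawn from the chosen noise family at sd true_cv_r * true_mean_r.
Gaussian noise is clamped at zero (binding measures are nonnegative);
a moment-matched lognormal family is available as an alternative.
Noise and shifts come from separate sub-streams of the seed, so changing
``baseline_shift_sd`` alone leaves the eps draws identical — useful for
paired comparisons.

``make_tracer_suite`` builds a full multi-tracer fixture suite whose
metadata (receptor, tracer, measure, N, age) mirrors the 18 contributed
studies of the real compilation, including a low-CV serotonergic tracer,
high-baseline-shift CB1/mGluR5-like tracers, noisy GABA_A/NMDA-like
tracers, a striatum-only raclopride-like tracer, and the MOR occipital
reference-region exclusion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .atlas import (SUBCORTEX, ParcellationAtlas, build_default_atlas,
                    occipital_regions, striatal_regions)
from .errors import ContractError
from .inference import derive_rng
from .maps import RegionalMap, TracerStudy

NOISE_FAMILIES = ("gaussian", "lognormal")


@dataclass
class SyntheticCohortSpec:
    """Ground truth for one synthetic cohort."""

    atlas: ParcellationAtlas
    true_mean: np.ndarray
    true_cv: np.ndarray
    n_subjects: int
    seed: int
    scaling_exponent: float = 1.0
    subject_noise: str = "gaussian"
    baseline_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        self.true_mean = np.asarray(self.true_mean, dtype=float)
        self.true_cv = np.asarray(self.true_cv, dtype=float)
        n = self.atlas.n_regions
        if self.true_mean.shape != (n,) or self.true_cv.shape != (n,):
            raise ContractError("true_mean/true_cv must have one value per region")
        if np.any(self.true_mean <= 0):
            raise ContractError("true_mean must be strictly positive")
        if np.any(self.true_cv < 0) or np.any(self.true_cv >= 1.5):
            raise ContractError("true_cv must lie in [0, 1.5)")
        if self.n_subjects < 2:
            raise ContractError("n_subjects must be >= 2")
        if self.subject_noise not in NOISE_FAMILIES:
            raise ContractError(f"subject_noise must be one of {NOISE_FAMILIES}")
        if self.baseline_shift_sd < 0:
            raise ContractError("baseline_shift_sd must be nonnegative")


@dataclass
class Cohort:
    """Generated subject-by-region data plus the spec that produced it."""

    spec: SyntheticCohortSpec
    data: np.ndarray  # (n_subjects, n_regions)

    @property
    def atlas(self) -> ParcellationAtlas:
        return self.spec.atlas

    def subject_maps(self) -> List[RegionalMap]:
        return [
            RegionalMap(atlas=self.atlas, values=row, quantity="mean")
            for row in self.data
        ]


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a subject-by-region cohort; deterministic given ``spec.seed``."""
    noise_rng = derive_rng(spec.seed, "noise")
    shift_rng = derive_rng(spec.seed, "shift")
    n, r = spec.n_subjects, spec.atlas.n_regions
    sigma = spec.true_cv * spec.true_mean
    if spec.subject_noise == "gaussian":
        data = spec.true_mean + noise_rng.standard_normal((n, r)) * sigma
        np.clip(data, 0.0, None, out=data)  # binding measures are nonnegative
    else:
        # lognormal moment-matched to (true_mean, sigma)
        with np.errstate(divide="ignore"):
            s2 = np.log1p((sigma / spec.true_mean) ** 2)
        mu_log = np.log(spec.true_mean) - s2 / 2
        data = np.exp(mu_log + noise_rng.standard_normal((n, r)) * np.sqrt(s2))
    if spec.baseline_shift_sd > 0:
        shifts = np.exp(shift_rng.standard_normal(n) * spec.baseline_shift_sd)
        data = data * shifts[:, None]
    return Cohort(spec=spec, data=data)


def group_statistics(cohort: Cohort) -> Tuple[RegionalMap, RegionalMap]:
    """Region-wise group mean and sample (n-1) std across subjects."""
    if cohort.data.shape[0] < 2:
        raise ContractError("need >= 2 subjects for group statistics")
    mean = cohort.data.mean(axis=0)
    std = cohort.data.std(axis=0, ddof=1)
    return (
        RegionalMap(atlas=cohort.atlas, values=mean, quantity="mean"),
        RegionalMap(atlas=cohort.atlas, values=std, quantity="std"),
    )


# --------------------------------------------------------------------------
# Tracer suite: study-roster templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerTemplate:
    """Recipe for one synthetic tracer study.

    ``cv_level`` is the typical inter-individual CV of the tracer;
    ``mean_scale`` sets the magnitude of regional mean binding in the units
    of ``measure``; ``spread`` controls how heterogeneous the true mean is
    across cortical regions (log-sd of the regional profile; subcortical
    heterogeneity is 1.6x larger, since subcortical group maps vary more
    across regions than cortical ones).
    """

    receptor: str
    tracer: str
    measure: str
    n_subjects: int
    n_female: int
    age_mean: float
    age_sd: float
    cv_level: float
    mean_scale: float
    spread: float = 0.3
    baseline_shift_sd: float = 0.0
    striatum_only: bool = False
    occipital_reference: bool = False
    study_id: str = ""
    family: str = ""  # receptor family for consistency grouping; "" = receptor

    @property
    def uid(self) -> str:
        return self.study_id or f"{self.receptor}:{self.tracer}:{self.n_subjects}"

    @property
    def receptor_family(self) -> str:
        return self.family or self.receptor


# Metadata mirrors the contributed studies (receptor, tracer, measure, N,
# n_female, age mean/sd); cv_level / baseline_shift_sd encode each tracer's
# variability character (low-CV serotonergic, shifted CB1/mGluR5, noisy
# GABA_A/NMDA, striatum-only raclopride, occipital-referenced carfentanil).
DEFAULT_TEMPLATES: Tuple[TracerTemplate, ...] = (
    TracerTemplate("5-HT1A", "[11C]CUMI-101", "B_max", 8, 5, 28.4, 8.8, 0.20, 40.0, 0.40),
    TracerTemplate("5-HT1B", "[11C]AZ10419369", "B_max", 36, 12, 27.8, 6.9, 0.20, 30.0, 0.30),
    TracerTemplate("5-HT2A", "[11C]Cimbi-36", "B_max", 29, 14, 22.6, 2.7, 0.25, 50.0, 0.25),
    TracerTemplate("5-HT4", "[11C]SB207145", "B_max", 59, 18, 25.9, 5.3, 0.20, 30.0, 0.30),
    TracerTemplate("5-HTT", "[11C]DASB", "B_max", 100, 71, 25.1, 5.8, 0.20, 35.0, 0.35),
    TracerTemplate("5-HTT", "[11C]MADAM", "BP_ND", 49, 24, 39.3, 6.4, 0.30, 1.5, 0.35),
    TracerTemplate("CB1", "[18F]FMPEP-d2", "V_T", 20, 0, 24.4, 3.0, 0.20, 15.0, 0.15,
                   baseline_shift_sd=0.3),
    TracerTemplate("D2", "[11C]raclopride", "BP_ND", 16, 7, 32.7, 8.8, 0.25, 2.5, 0.30,
                   striatum_only=True, study_id="D2:[11C]raclopride:a"),
    TracerTemplate("D2", "[11C]raclopride", "BP_ND", 47, 0, 23.5, 2.5, 0.25, 2.5, 0.30,
                   striatum_only=True, study_id="D2:[11C]raclopride:b"),
    TracerTemplate("D2", "[18F]fallypride", "BP_ND", 49, 33, 18.4, 0.6, 0.30, 1.8, 0.40),
    TracerTemplate("GABAA-alpha1", "[11C]Ro15-4513", "V_T", 27, 1, 45.96, 7.4, 0.55, 8.0, 0.20,
                   family="GABAA"),
    TracerTemplate("GABAA-alpha5", "[11C]Ro15-4513", "V_T", 27, 1, 45.96, 7.4, 0.55, 6.0, 0.20,
                   family="GABAA"),
    TracerTemplate("GABAA-bz", "[11C]flumazenil", "B_max", 16, 9, 26.6, 8.0, 0.30, 60.0, 0.25,
                   family="GABAA"),
    TracerTemplate("NMDA", "[18F]GE-179", "V_T", 29, 8, 40.9, 12.7, 0.55, 10.0, 0.20),
    TracerTemplate("mGluR5", "[11C]ABP688", "BP_ND", 27, 12, 54.6, 13.4, 0.35, 1.8, 0.25,
                   baseline_shift_sd=0.2, study_id="mGluR5:[11C]ABP688:a"),
    TracerTemplate("mGluR5", "[11C]ABP688", "BP_ND", 73, 48, 19.9, 3.0, 0.35, 1.8, 0.25,
                   baseline_shift_sd=0.2, study_id="mGluR5:[11C]ABP688:b"),
    TracerTemplate("MOR", "[11C]carfentanil", "BP_ND", 86, 42, 35.6, 9.9, 0.40, 2.0, 0.35,
                   occipital_reference=True),
    TracerTemplate("VAChT", "[18F]FEOBV", "SUVR", 25, 8, 36.6, 9.7, 0.20, 2.5, 0.25),
)


def receptor_profile(template: TracerTemplate, atlas: ParcellationAtlas) -> np.ndarray:
    """Deterministic true regional mean profile for a receptor.

    Profiles are drawn from a lognormal field seeded by the receptor name
    only, so replicate studies of the same receptor share one spatial truth
    (the basis of spatial-consistency scoring). Subcortical regions get a
    mild multiplicative offset so the two compartments differ. Striatum-only
    tracers get high striatal binding and near-zero (reference-level)
    binding elsewhere; occipital-referenced tracers get near-zero binding in
    the occipital regions.
    """
    rng = derive_rng(0, "profile", template.receptor)
    field = rng.standard_normal(atlas.n_regions)
    sub = atlas.compartment_mask(SUBCORTEX)
    spread = np.where(sub, 1.6 * template.spread, template.spread)
    profile = template.mean_scale * np.exp(field * spread)
    profile[sub] *= 1.5
    if template.striatum_only:
        striatum = np.isin(atlas.region_ids, sorted(striatal_regions(atlas)))
        profile[~striatum] *= 0.02  # non-displaceable-level background
    if template.occipital_reference:
        occ = np.isin(atlas.region_ids, sorted(occipital_regions(atlas)))
        profile[occ] = 0.05  # reference region: near-zero specific binding
    return profile


def cv_profile(template: TracerTemplate, atlas: ParcellationAtlas) -> np.ndarray:
    """True CV field: tracer's cv_level with mild regional heterogeneity."""
    rng = derive_rng(0, "cv-profile", template.uid)
    wiggle = 1.0 + 0.25 * rng.uniform(-1.0, 1.0, atlas.n_regions)
    return np.clip(template.cv_level * wiggle, 0.01, 1.49)


def make_study(template: TracerTemplate, atlas: ParcellationAtlas, seed: int,
               replicate: int = 0) -> TracerStudy:
    """Generate one TracerStudy from a template.

    The cohort stream is derived from ``(seed, study uid, replicate)`` so
    adding or re-ordering templates never perturbs other studies, and
    replicate cohorts (``replicate > 0``) are independent draws of the same
    truth.
    """
    true_mean = receptor_profile(template, atlas)
    true_cv = cv_profile(template, atlas)
    cohort_seed = int(
        np.random.SeedSequence(
            [int(seed), hash_label(template.uid), int(replicate)]
        ).generate_state(1)[0] % (2**31)
    )
    spec = SyntheticCohortSpec(
        atlas=atlas, true_mean=true_mean, true_cv=true_cv,
        n_subjects=template.n_subjects, seed=cohort_seed,
        baseline_shift_sd=template.baseline_shift_sd,
    )
    cohort = generate_cohort(spec)
    mean_map, std_map = group_statistics(cohort)
    exclusion = frozenset(occipital_regions(atlas)) if template.occipital_reference else frozenset()
    return TracerStudy(
        receptor=template.receptor, tracer=template.tracer, measure=template.measure,
        n_subjects=template.n_subjects, n_female=template.n_female,
        age_mean=template.age_mean, age_sd=template.age_sd,
        mean_map=mean_map, std_map=std_map,
        reference_exclusion=exclusion, striatum_only=template.striatum_only,
        family=template.receptor_family,
        study_id=template.uid if replicate == 0 else f"{template.uid}#rep{replicate}",
        ground_truth={"true_mean": true_mean, "true_cv": true_cv, "spec": spec},
    )


def hash_label(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def make_tracer_suite(
    templates: Optional[Sequence[TracerTemplate]] = None,
    atlas: Optional[ParcellationAtlas] = None,
    seed: int = 0,
    n_replicates: int = 1,
) -> Tuple[List[TracerStudy], Dict[str, List[TracerStudy]]]:
    """Build the default multi-tracer fixture suite.

    Returns ``(studies, replicates)`` where ``replicates[study_id]`` holds
    ``n_replicates`` independent cohorts of the same receptor truth — the
    out-of-sample "other maps" used for spatial-consistency scoring.
    An empty template list yields an empty suite.
    """
    templates = DEFAULT_TEMPLATES if templates is None else tuple(templates)
    atlas = atlas or build_default_atlas()
    studies: List[TracerStudy] = []
    replicates: Dict[str, List[TracerStudy]] = {}
    for template in templates:
        study = make_study(template, atlas, seed, replicate=0)
        studies.append(study)
        replicates[study.study_id] = [
            make_study(template, atlas, seed, replicate=i)
            for i in range(1, n_replicates + 1)
        ]
    return studies, replicates
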
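# Methods

## The quantities

Let μ_r and σ_r be the group mean and group standard deviation of tracer
binding in region r of a parcellated brain volume (100 cortical + 54
subcortical regions by default), contributed per tracer study along with
cohort metadata (N subjects, age). Three statistics organize the analysis:

1. **Inter-individual CV** (one value per region): CV_r = σ_r / μ_r.
   Standard deviations of biological measurements scale with their means
   (fluctuation scaling, σ ∝ μ^β with β near 1), so σ alone conflates
   signal magnitude with variability; the mean-normalized CV does not.
2. **Inter-regional CV** (one value per map and compartment):
   sd({μ_r}) / mean({μ_r}) across the retained regions of the cortex or
   subcortex, using the sample (n−1) standard deviation.
3. **Regional-to-population ratio**: inter-regional CV divided by the mean
   inter-individual CV over the same retained regions. Above 1, the
   tracer's spatial profile dominates individual differences — its group
   map is representative of essentially any individual's regional ranking.

**Low-binding filter.** A CV is numerically unstable when μ_r approaches
zero (reference regions, out-of-territory binding). Before any CV is
formed, a region is omitted iff its mean is in the bottom 5th percentile of
the map's valid regions AND below 0.1 binding units. The conditional
phrasing of this rule admits other readings, so the conjunction is
configurable (`FilterPolicy.combine`: `and` (default), `or`,
`percentile_only`). The percentile is computed over all valid regions of
the map jointly (cortex + subcortex), with linear interpolation. A region
that survives the filter with μ_r ≤ 0 (small negatives can leak out of
upstream kinetic modelling) is invalidated with a logged warning rather
than raised. Note that the absolute cut is expressed in the map's binding
units: the analysis is invariant under a common rescaling of (μ, σ, 0.1),
i.e. under a change of units.

**Bootstrap comparison.** To test whether a tracer varies significantly
more across regions than across individuals, the retained CV values of a
compartment are resampled with replacement (resample size = number of
retained regions) n_boot = 10,000 times; the mean of each resample forms a
null distribution of mean inter-individual CVs, and

    p = #(null mean ≥ inter-regional CV) / n_boot

with no small-sample (+1) correction — the estimator is implemented exactly
as defined. Resampling is within compartment because the inter-regional CV
is defined per compartment. Significance is declared at α = 0.05 per
tracer, uncorrected (a Benjamini–Hochberg pass can be applied downstream;
the per-tracer p-values are all exported). An exhaustive enumerator
(`enumerate_bootstrap_p`, all k^k ordered resamples) serves as the exact
oracle for small k in the tests.

**Spatial consistency.** For a receptor with replicate group-mean maps
(other cohorts or other tracers of the same receptor family), consistency
is the mean Spearman correlation between the original map and each other
map, computed over jointly valid regions with average ranks for ties. With
a single other map this is simply the correlation between the two group
means. The stated definition can also be read as averaging all unordered
pairs among the replicate set; both modes are implemented
(`mean_consistency(..., mode="all_pairs")`), original-vs-others being the
default. The three GABA_A variants (α1, α5, benzodiazepine site) are one
*family* for grouping purposes even though their spatial profiles differ —
which is exactly why their measured consistency is moderate (~0.5 in the
default suite).

**Cross-tracer correlations.** The ratio-vs-consistency association and
the covariate diagnostics (mean CV vs N, vs mean age) use Spearman r with a
two-sided permutation p (one vector shuffled, (count+1)/(n_perm+1),
n_perm = 10,000 by default), because only ~14–18 receptor points are
available; the asymptotic p is reported alongside.

## Inter-regional CV over retained regions

The filter is defined for the CV computation; whether the inter-regional
CV should also exclude the omitted regions is ambiguous. The pipeline
computes the inter-regional CV over the *same retained region set* as the
CV map, so both sides of the ratio describe identical territory. The
operation itself (`interregional_cv`) accepts any validity mask, so either
convention is reachable.

## Synthetic cohorts

`generate_cohort` draws subject s, region r as

    x[s, r] = shift_s · (m_r + ε[s, r]),   shift_s ~ LogNormal(0, s_b)

where m_r > 0 is the true regional mean, ε has standard deviation
c_r · m_r (c_r the true regional CV, i.e. fluctuation-scaling exponent
β = 1 when c_r is constant; other β are reachable by constructing c_r from
(c, β)), and s_b ≥ 0 is the subject baseline-shift scale. The default noise
family is gaussian clamped at zero (binding measures are nonnegative; at
the suite's mean/CV scales the clamped mass is negligible); a
moment-matched lognormal family is available since true subject-level
distributions are unknown and may be skewed. Noise and shifts come from
separate deterministic sub-streams of the seed, so changing s_b alone
leaves the ε draws untouched — this makes the baseline-shift comparison
exactly paired.

The multiplicative shift is the "conserved spatial profile, individually
shifted baseline" scenario: raising s_b from 0 to 0.3 inflates every
region's CV (a global multiplier adds variance everywhere) while leaving
the rank order of the group mean map — and hence between-cohort spatial
consistency — intact.

**The default tracer suite** (`DEFAULT_TEMPLATES`) mirrors the 18
contributed studies' metadata: receptor, tracer, binding measure, N
(e.g. 5-HTT/[11C]DASB N=100, MOR/[11C]carfentanil N=86,
5-HT1A/[11C]CUMI-101 N=8, two [11C]raclopride studies N=16/47), sex counts
and ages. Per-tracer character is encoded by:

- `cv_level`: typical inter-individual CV — ~0.2 for serotonergic tracers,
  ~0.4 for MOR, >0.5 for GABA_A α-subunits and NMDA, as described for the
  real compilation;
- `baseline_shift_sd` > 0 for CB1 and mGluR5 (consistent spatial profile,
  high individual variability);
- `striatum_only` for raclopride (reliable only where D2 density is high;
  all non-striatal regions are invalidated);
- `occipital_reference` for carfentanil (occipital cortex is the MOR
  reference region: set to near-zero binding and excluded).

True mean profiles are lognormal fields seeded by receptor name only, so
replicate studies of one receptor share a spatial truth; profile magnitudes
sit on the scales of each measure (B_max in tens of pmol/ml, V_T ~5–25,
BP_ND ~0.5–3, SUVR ~1–4). Cortical profile heterogeneity (log-sd 0.15–0.40
per tracer) is set below subcortical heterogeneity (1.6× larger), since
subcortical group maps vary more across regions; with the tracers' CV
levels this yields a cortex where only a minority of tracers pass the
bootstrap test while most do in subcortex — the qualitative regime of real
parcellated PET data. These spreads are generator conditions fixed at
design time, not fitted quantities.

What the generator does **not** emulate: spatial autocorrelation of maps
and noise, partial-volume and registration error, site/scanner batch
effects, kinetic-modelling error structure, non-stationary noise within
compartments. Passing tests therefore validate the statistical machinery
and its contracts, not claims about any real tracer.

## Atlas handling

All volumes are assumed co-registered in one space; shape mismatches are
errors and no registration is performed. Parcellation is the unweighted
mean of non-NaN voxels per label; a region with no finite voxels becomes
invalid (never zero — zeros would corrupt CV denominators). Occipital and
striatal region sets are name-based presets on the bundled synthetic atlas
(`Vis` network blocks; NAc/CAU/PUT structures) and explicit id sets for
user atlases, since anatomy-to-label mappings are atlas-specific. The
synthetic default atlas assigns each of the 154 labels a power-of-two
number of voxels so that the embed→parcellate round trip is bitwise exact
(the mean of 2^k identical doubles is exact; other counts can be off by
1 ulp).

## Numerical and reproducibility choices

- TSV serialization uses `repr`-shortest float strings: lossless round
  trips and diff-able files; invalid regions are spelled `NaN`.
- Percentiles: linear interpolation (`numpy.percentile` default);
  membership in the bottom percentile is inclusive (≤).
- Inter-regional sd: ddof = 1 by default, configurable (`ddof=0` for the
  population convention).
- One master seed per run; every stochastic stage derives its stream as
  `SeedSequence([seed, crc32(label)...])`, so per-tracer results are
  independent — adding or removing a tracer never changes another tracer's
  numbers, and reruns are byte-identical.
- Bootstrap resampling is chunked (≤5M indices at a time) to bound memory
  at large n_boot.
- Degenerate inputs raise typed errors: constant maps for min-max scaling
  or rank correlation, <2 regions for dispersion statistics, <3 jointly
  valid regions for Spearman, nonpositive across-region mean for the
  inter-regional CV.

## Known limitations

- Contributed σ maps are taken as given; whether source sites used n or
  n−1 denominators is unknowable downstream and left untouched.
- The pipeline's "k/N significant" counts and correlation values on the
  synthetic suite characterize the generator's regime, not the real
  compilation; reproducing published values requires the original group
  maps (an external download) fed through `recepvar parcellate`/`run`.
- Whether the low-binding percentile should be computed per compartment
  rather than per map is undocumented in the field; per map is the default
  here and the choice is visible in `FilterPolicy`.
- No spatial-autocorrelation-preserving null models: the bootstrap and
  permutation tests treat regions/receptors as exchangeable units.
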
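"""Bootstrap null construction, Spearman consistency, permutation tests."""

import itertools

import numpy as np
import pytest

from recepvar import (ContractError, RegionalMap, bootstrap_compare,
                      covariate_diagnostics, derive_rng, enumerate_bootstrap_p,
                      mean_consistency, ratio_vs_consistency, spearman_spatial)

from conftest import tabular_atlas


def cv_map_of(values, compartment="cortex"):
    return RegionalMap(atlas=tabular_atlas(len(values), compartment),
                       values=values, quantity="cv")


def brute_force_bootstrap_p(values, threshold):
    """Oracle: count ordered resamples whose mean >= threshold."""
    hits = total = 0
    for combo in itertools.product(values, repeat=len(values)):
        total += 1
        if np.mean(combo) >= threshold:
            hits += 1
    return hits / total


class TestBootstrapCompare:
    def test_threshold_below_minimum_gives_p_one(self):
        boot = bootstrap_compare(cv_map_of([0.2, 0.3, 0.4]), 0.1,
                                 n_boot=10_000, seed=0)
        assert boot.p_value == 1.0

    def test_threshold_above_maximum_gives_p_zero(self):
        boot = bootstrap_compare(cv_map_of([0.2, 0.3, 0.4]), 0.5,
                                 n_boot=10_000, seed=0)
        assert boot.p_value == 0.0

    def test_enumeration_oracle_three_regions(self):
        # all 3^3 = 27 ordered resamples of {0.1, 0.2, 0.6}: exactly 7 have
        # mean >= 0.4, so the exact bootstrap p is 7/27
        values = [0.1, 0.2, 0.6]
        assert brute_force_bootstrap_p(values, 0.4) == pytest.approx(7 / 27)
        assert enumerate_bootstrap_p(values, 0.4) == pytest.approx(7 / 27)

    @pytest.mark.parametrize("values,threshold", [
        ([0.1, 0.2, 0.6], 0.4),
        ([0.05, 0.5], 0.3),
        ([0.1, 0.3, 0.35, 0.9], 0.5),
        ([0.2, 0.21, 0.22, 0.7, 0.8], 0.45),
    ])
    def test_monte_carlo_converges_to_enumeration(self, values, threshold):
        exact = brute_force_bootstrap_p(values, threshold)
        boot = bootstrap_compare(cv_map_of(values), threshold,
                                 n_boot=50_000, seed=42)
        tol = 4 * np.sqrt(max(exact * (1 - exact), 1e-4) / 50_000)
        assert boot.p_value == pytest.approx(exact, abs=tol)

    def test_reproducible_given_seed(self):
        values = np.linspace(0.1, 0.6, 20)
        a = bootstrap_compare(cv_map_of(values), 0.3, n_boot=2_000, seed=9)
        b = bootstrap_compare(cv_map_of(values), 0.3, n_boot=2_000, seed=9)
        assert np.array_equal(a.null_means, b.null_means)
        assert a.p_value == b.p_value

    def test_p_non_increasing_in_threshold_for_fixed_resamples(self):
        values = np.linspace(0.1, 0.6, 10)
        ps = [
            bootstrap_compare(cv_map_of(values), thr, n_boot=3_000, seed=5).p_value
            for thr in np.linspace(0.05, 0.7, 12)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_resampling_respects_compartment(self):
        atlas_regions = (
            [("cortex", v) for v in (0.1, 0.1, 0.1)]
            + [("subcortex", v) for v in (0.9, 0.9, 0.9)]
        )
        from recepvar import ParcellationAtlas, RegionInfo
        atlas = ParcellationAtlas(regions=[
            RegionInfo(i + 1, f"r{i}", comp) for i, (comp, _) in
            enumerate(atlas_regions)
        ])
        cv_map = RegionalMap(atlas=atlas, values=[v for _, v in atlas_regions],
                             quantity="cv")
        # cortical values are all 0.1: a threshold of 0.5 can never be reached
        boot = bootstrap_compare(cv_map, 0.5, compartment="cortex",
                                 n_boot=1_000, seed=0)
        assert boot.p_value == 0.0
        boot = bootstrap_compare(cv_map, 0.5, compartment="subcortex",
                                 n_boot=1_000, seed=0)
        assert boot.p_value == 1.0

    def test_too_few_regions_rejected(self):
        with pytest.raises(ContractError, match=">= 2"):
            bootstrap_compare(cv_map_of([0.2, np.nan, np.nan]), 0.1, n_boot=10)


class TestSpearmanSpatial:
    def test_identity_reversal_and_monotone_invariance(self, atlas20, rng):
        values = rng.standard_normal(20)
        a = RegionalMap(atlas=atlas20, values=values)
        assert spearman_spatial(a, a) == pytest.approx(1.0)
        rev = RegionalMap(atlas=atlas20, values=-values)
        assert spearman_spatial(a, rev) == pytest.approx(-1.0)
        mono = RegionalMap(atlas=atlas20, values=np.exp(values))
        assert spearman_spatial(a, mono) == pytest.approx(1.0)

    def test_symmetry(self, atlas20, rng):
        a = RegionalMap(atlas=atlas20, values=rng.standard_normal(20))
        b = RegionalMap(atlas=atlas20, values=rng.standard_normal(20))
        assert spearman_spatial(a, b) == pytest.approx(spearman_spatial(b, a))

    def test_joint_validity_only(self, atlas20, rng):
        values = rng.standard_normal(20)
        mask_a = np.ones(20, dtype=bool)
        mask_a[:5] = False
        a = RegionalMap(atlas=atlas20, values=values, valid=mask_a)
        noise = values.copy()
        noise[:5] = -999  # must be ignored: invalid in a
        b = RegionalMap(atlas=atlas20, values=noise)
        assert spearman_spatial(a, b) == pytest.approx(1.0)

    def test_too_few_joint_regions_rejected(self, atlas20):
        valid = np.zeros(20, dtype=bool)
        valid[:2] = True
        a = RegionalMap(atlas=atlas20, values=np.arange(20.0), valid=valid)
        b = RegionalMap(atlas=atlas20, values=np.arange(20.0))
        with pytest.raises(ContractError, match=">= 3"):
            spearman_spatial(a, b)

    def test_constant_map_rejected(self, atlas20):
        a = RegionalMap(atlas=atlas20, values=np.full(20, 3.0))
        b = RegionalMap(atlas=atlas20, values=np.arange(20.0))
        with pytest.raises(ContractError, match="constant"):
            spearman_spatial(a, b)


class TestMeanConsistency:
    def test_duplicate_map_scores_one(self, atlas20, rng):
        m = RegionalMap(atlas=atlas20, values=rng.standard_normal(20))
        record = mean_consistency(m, [m.copy()])
        assert record.mean_consistency == pytest.approx(1.0)

    def test_arithmetic_mean_of_designed_ranks(self):
        # rank designs with sum of squared rank differences 4 and 8 give
        # Spearman r = 0.8 and 0.6 (n = 5); their mean is 0.7
        atlas = tabular_atlas(5)
        original = RegionalMap(atlas=atlas, values=[1, 2, 3, 4, 5])
        r08 = RegionalMap(atlas=atlas, values=[2, 1, 3, 5, 4])
        r06 = RegionalMap(atlas=atlas, values=[3, 2, 1, 4, 5])
        assert spearman_spatial(original, r08) == pytest.approx(0.8)
        assert spearman_spatial(original, r06) == pytest.approx(0.6)
        record = mean_consistency(original, [r08, r06])
        assert record.pairwise_r == pytest.approx([0.8, 0.6])
        assert record.mean_consistency == pytest.approx(0.7)

    def test_single_other_equals_single_r(self, atlas20, rng):
        a = RegionalMap(atlas=atlas20, values=rng.standard_normal(20))
        b = RegionalMap(atlas=atlas20, values=rng.standard_normal(20))
        record = mean_consistency(a, [b])
        assert record.mean_consistency == pytest.approx(spearman_spatial(a, b))

    def test_all_pairs_mode(self, atlas20, rng):
        maps = [RegionalMap(atlas=atlas20, values=rng.standard_normal(20))
                for _ in range(3)]
        record = mean_consistency(maps[0], maps[1:], mode="all_pairs")
        expected = np.mean([
            spearman_spatial(maps[i], maps[j])
            for i in range(3) for j in range(i + 1, 3)
        ])
        assert record.mean_consistency == pytest.approx(expected)
        assert len(record.pairwise_r) == 3

    def test_empty_others_rejected(self, atlas20):
        m = RegionalMap(atlas=atlas20, values=np.arange(20.0))
        with pytest.raises(ContractError, match="at least one"):
            mean_consistency(m, [])


class TestRatioVsConsistency:
    def test_concordant_ranks(self):
        r, p_perm, p_asym = ratio_vs_consistency(
            [1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5], n_perm=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p_perm < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ContractError, match="constant"):
            ratio_vs_consistency([1, 1, 1, 1], [1, 2, 3, 4], n_perm=10, seed=0)

    def test_length_mismatch_and_small_n_rejected(self):
        with pytest.raises(ContractError, match="length"):
            ratio_vs_consistency([1, 2, 3, 4], [1, 2, 3], n_perm=10)
        with pytest.raises(ContractError, match=">= 4"):
            ratio_vs_consistency([1, 2, 3], [1, 2, 3], n_perm=10)

    def test_permutation_p_calibrated_under_independence(self):
        # 8 independent pairs per replicate; over 300 seeded replicates the
        # permutation p should be roughly uniform: false-positive rate near
        # the nominal 5% and mean p near 0.5
        rng = np.random.default_rng(2024)
        ps = []
        for _ in range(300):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            _, p_perm, _ = ratio_vs_consistency(
                x, y, n_perm=199, rng=np.random.default_rng(rng.integers(2**31)))
            ps.append(p_perm)
        ps = np.asarray(ps)
        assert 0.25 <= ps.mean() <= 0.75
        assert (ps < 0.05).mean() <= 0.12


class TestCovariateDiagnostics:
    def _studies(self, ns, ages):
        from recepvar import TracerStudy
        atlas = tabular_atlas(5)
        out = []
        for i, (n, age) in enumerate(zip(ns, ages)):
            mean = RegionalMap(atlas=atlas, values=np.full(5, 2.0))
            std = RegionalMap(atlas=atlas, values=np.full(5, 0.2), quantity="std")
            out.append(TracerStudy(
                receptor=f"r{i}", tracer=f"t{i}", measure="BP_ND",
                n_subjects=int(n), age_mean=float(age), age_sd=1.0,
                mean_map=mean, std_map=std))
        return out

    def test_identical_cvs_not_testable(self):
        studies = self._studies([10, 20, 30, 40], [20, 25, 30, 35])
        table = covariate_diagnostics(studies, [0.2, 0.2, 0.2, 0.2],
                                      n_perm=50, seed=0)
        assert (table["note"] == "not testable").all()

    def test_monotone_cv_in_sample_size(self):
        studies = self._studies([10, 20, 30, 40, 50], [33, 21, 40, 28, 35])
        cvs = [0.1, 0.2, 0.3, 0.4, 0.5]  # CV rises with N by construction
        table = covariate_diagnostics(studies, cvs, n_perm=200, seed=0)
        row = table[table.covariate == "n_subjects"].iloc[0]
        assert row.spearman_r == pytest.approx(1.0)

    def test_independent_cv_rarely_significant(self):
        # calibration: CV independent of N and age; over 100 seeded
        # replicates the permutation p should exceed 0.05 in >= 90%
        rng = np.random.default_rng(77)
        over = 0
        n_rep = 100
        for i in range(n_rep):
            ns = rng.integers(8, 100, size=8)
            ages = rng.uniform(20, 55, size=8)
            cvs = rng.uniform(0.1, 0.6, size=8)
            studies = self._studies(ns, ages)
            table = covariate_diagnostics(studies, cvs, n_perm=199, seed=int(i))
            row = table[table.covariate == "n_subjects"].iloc[0]
            over += row.p_perm > 0.05
        assert over >= 0.9 * n_rep

    def test_missing_covariate_dropped(self):
        studies = self._studies([10, 20, 30, 40, 50], [33, 21, 40, 28, 35])
        studies[0].age_mean = float("nan")
        table = covariate_diagnostics(studies, [0.3, 0.2, 0.5, 0.1, 0.4],
                                      n_perm=50, seed=0)
        age_row = table[table.covariate == "age_mean"].iloc[0]
        assert age_row.n_studies == 4


class TestDerivedStreams:
    def test_streams_independent_of_other_labels(self):
        a1 = derive_rng(3, "boot", "tracer-A").standard_normal(5)
        a2 = derive_rng(3, "boot", "tracer-A").standard_normal(5)
        b = derive_rng(3, "boot", "tracer-B").standard_normal(5)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)
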
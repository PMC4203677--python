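"""MAF estimation, rare-variant selection, gene collapsing, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rareburden.burden import (
    AssociationError,
    compute_maf,
    fit_association,
    fit_gene_burden,
    gene_dosage,
    prepare_covariates,
    select_rare_variants,
)
from rareburden.cohort import GeneInterval

from conftest import make_cohort


class TestComputeMaf:
    def test_folds_to_minor_allele(self):
        assert compute_maf([0, 0, 1, 1]) == pytest.approx(0.25)

    def test_fixed_alternate_allele_has_zero_maf(self):
        assert compute_maf([2.0, 2.0, 2.0]) == 0.0

    def test_missing_entries_excluded(self):
        assert compute_maf([1.0, np.nan, 0.0, np.nan]) == pytest.approx(0.25)

    def test_all_missing_raises(self):
        with pytest.raises(AssociationError):
            compute_maf([np.nan, np.nan])

    def test_binomial_consistency_at_truth(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.02, size=1000).astype(float)
        sd = np.sqrt(0.02 * 0.98 / (2 * 1000))
        assert abs(compute_maf(d) - 0.02) < 3 * sd


class TestSelectRareVariants:
    @staticmethod
    def _cohort_with_mafs(mafs, positions, info=1.0):
        n = 4000
        rng = np.random.default_rng(123)
        cols = [rng.binomial(2, m, size=n).astype(float) for m in mafs]
        return make_cohort(np.column_stack(cols), positions=positions, info=info)

    def test_maf_ceiling_is_inclusive(self):
        # exact dosage frequencies, no sampling noise
        n = 1000
        col_at = np.zeros(n); col_at[:60] = 1.0     # maf 0.030
        col_above = np.zeros(n); col_above[:62] = 1.0  # maf 0.031
        cohort = make_cohort(np.column_stack([col_at, col_above]),
                             positions=[100, 200])
        sel = select_rare_variants(cohort, [GeneInterval("G", "1", 1, 500)])
        assert list(sel["G"]) == [0]

    def test_stage2_floor_excludes_ultra_rare(self):
        n = 1000
        ok = np.zeros(n); ok[:10] = 1.0        # maf 0.005, kept (floor inclusive)
        too_rare = np.zeros(n); too_rare[:8] = 1.0  # maf 0.004
        cohort = make_cohort(np.column_stack([ok, too_rare]), positions=[100, 200])
        sel = select_rare_variants(cohort, [GeneInterval("G", "1", 1, 500)],
                                   maf_min=0.005)
        assert list(sel["G"]) == [0]

    def test_info_floor_is_inclusive(self):
        cohort = self._cohort_with_mafs([0.02, 0.02], [100, 200])
        cohort.variants.loc[0, "info"] = 0.4
        cohort.variants.loc[1, "info"] = 0.39
        sel = select_rare_variants(cohort, [GeneInterval("G", "1", 1, 500)])
        assert list(sel["G"]) == [0]

    def test_interval_boundaries_are_inclusive(self):
        cohort = self._cohort_with_mafs([0.02] * 3, [99, 100, 200])
        sel = select_rare_variants(cohort, [GeneInterval("G", "1", 100, 200)])
        assert list(sel["G"]) == [1, 2]

    def test_overlapping_genes_share_variants(self):
        cohort = self._cohort_with_mafs([0.02], [150])
        sel = select_rare_variants(
            cohort,
            [GeneInterval("G1", "1", 100, 200), GeneInterval("G2", "1", 140, 300)],
        )
        assert list(sel["G1"]) == [0] and list(sel["G2"]) == [0]

    def test_gene_without_qualifying_variants_is_empty(self):
        cohort = self._cohort_with_mafs([0.02], [150])
        sel = select_rare_variants(cohort, [GeneInterval("G", "2", 100, 200)])
        assert sel["G"].size == 0


class TestGeneDosage:
    def test_mean_of_included_dosages(self):
        cohort = make_cohort([[0.5, 1.5], [0.0, 2.0]])
        d = gene_dosage(cohort, np.array([0, 1]), "G")
        assert d.values == pytest.approx([1.0, 1.0])
        assert d.n_variants == 2

    def test_single_variant_gene_is_identity(self):
        cohort = make_cohort([[0.3], [1.7]])
        d = gene_dosage(cohort, np.array([0]), "G")
        assert d.values == pytest.approx([0.3, 1.7])

    def test_missing_dosages_average_over_observed(self):
        cohort = make_cohort([[np.nan, 1.0], [np.nan, np.nan]])
        d = gene_dosage(cohort, np.array([0, 1]), "G")
        assert d.values[0] == pytest.approx(1.0)
        assert np.isnan(d.values[1])  # sample missing everything drops out

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_variant_ordering(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 2, size=(9, 5))
        cohort = make_cohort(g)
        idx = np.arange(5)
        perm = rng.permutation(idx)
        a = gene_dosage(cohort, idx, "G").values
        b = gene_dosage(cohort, perm, "G").values
        assert a == pytest.approx(b)

    def test_empty_selection_raises(self):
        with pytest.raises(AssociationError):
            gene_dosage(make_cohort([[0.0]]), np.array([], dtype=int), "G")


class TestFitAssociation:
    def test_recovers_simulated_effect(self):
        rng = np.random.default_rng(31)
        n = 6000
        x = rng.binomial(2, 0.3, size=n).astype(float)
        beta = 0.4
        p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
        y = rng.binomial(1, p)
        res = fit_association(x, y)
        assert res.estimable
        assert abs(res.beta - beta) < 2 * res.se

    def test_null_type_one_error(self):
        rng = np.random.default_rng(32)
        n, reps = 800, 200
        rejections = 0
        for _ in range(reps):
            x = rng.binomial(2, 0.2, size=n).astype(float)
            y = rng.binomial(1, 0.5, size=n)
            res = fit_association(x, y)
            rejections += abs(res.z) > 1.959964
        # expect ~5%; allow 3 binomial SDs
        assert rejections / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_class_phenotype_raises(self):
        with pytest.raises(AssociationError):
            fit_association([0.0, 1.0, 2.0], [1, 1, 1])

    def test_zero_variance_predictor_flagged(self):
        y = [0, 1] * 20
        res = fit_association([1.0] * 40, y)
        assert not res.estimable
        assert "zero-variance" in res.message

    def test_p_consistent_with_z(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=500)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        res = fit_association(x, y)
        from scipy import stats
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.z)), abs=1e-10)
        assert np.sign(res.z) == np.sign(res.beta)

    def test_linear_family_available(self):
        rng = np.random.default_rng(34)
        x = rng.normal(size=400)
        y = rng.binomial(1, 0.5, size=400)
        res = fit_association(x, y, family="linear")
        assert res.estimable


class TestPrepareCovariates:
    def test_education_mean_imputed(self):
        samples = pd.DataFrame(
            {
                "sample_id": list("abcdefghij"),
                "age": 70.0,
                "sex": 0.0,
                "edu": [2, 3, 2, 3, 2, 3, 2, 3, np.nan, np.nan],
            }
        )
        cov = prepare_covariates(samples)
        assert cov["edu"].iloc[-1] == pytest.approx(2.5)

    def test_pc_columns_collected(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "age": 70.0, "sex": 1.0,
             "edu": 2.0, "PC1": [0.1, 0.2, 0.3], "PC2": 0.0}
        )
        assert list(prepare_covariates(samples).columns) == ["age", "sex", "edu",
                                                            "PC1", "PC2"]


def test_single_variant_gene_equals_single_snp_result(two_study_data):
    """Burden test on a one-variant gene is exactly the SNP test."""
    cohort = two_study_data.cohorts[0]
    j = 0
    col = cohort.dosages[:, j]
    cov = prepare_covariates(cohort.samples)
    snp = fit_association(col, cohort.status, cov)
    gene = fit_gene_burden(cohort, np.array([j]), "G")
    assert gene.beta == pytest.approx(snp.beta, rel=1e-9)
    assert gene.z == pytest.approx(snp.z, rel=1e-9)
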
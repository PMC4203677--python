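"""Variant- and sample-level QC: exact HWE test, filters, IBS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from rareburden.qc import (
    QcThresholds,
    hwe_exact_test,
    pairwise_ibs,
    sample_qc,
    variant_qc,
)

from conftest import make_cohort


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent full enumeration of the conditional het-count
    distribution via the closed-form multinomial probability."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    nr = (rare - hets) // 2
    nc = n - nr - hets
    logp = (
        gammaln(n + 1) - gammaln(nr + 1) - gammaln(hets + 1) - gammaln(nc + 1)
        + hets * np.log(2)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_ab][0]
    return float(np.sum(p[p <= obs * (1 + 1e-12)]))


class TestHweExactTest:
    def test_monomorphic_sample_is_perfectly_compatible(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 42) == 1.0

    def test_known_heterozygote_deficit(self):
        # frozen from the enumeration oracle
        assert hwe_exact_test(57, 14, 50) == pytest.approx(5.562047311095614e-19,
                                                           rel=1e-10)

    def test_symmetric_under_allele_relabelling(self):
        for cfg in [(57, 14, 50), (3, 10, 87), (12, 40, 8)]:
            assert hwe_exact_test(*cfg) == pytest.approx(
                hwe_exact_test(cfg[2], cfg[1], cfg[0]), rel=1e-12
            )

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_p_lies_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            counts = rng.integers(0, 60, size=3)
            if counts.sum() == 0:
                continue
            p = hwe_exact_test(*counts)
            assert 0.0 < p <= 1.0

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80))
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_ab, n_bb), rel=1e-10, abs=1e-300
        )

    def test_null_rejection_rate_is_nominal(self):
        """HWE-true variants should reject at close to alpha."""
        rng = np.random.default_rng(42)
        n, reps = 500, 2000
        p_vals = []
        for _ in range(reps):
            maf = rng.uniform(0.05, 0.5)
            g = rng.binomial(2, maf, size=n)
            p_vals.append(
                hwe_exact_test(int(np.sum(g == 0)), int(np.sum(g == 1)),
                               int(np.sum(g == 2)))
            )
        p_vals = np.asarray(p_vals)
        for alpha in (0.05, 0.01):
            frac = np.mean(p_vals < alpha)
            sd = np.sqrt(alpha * (1 - alpha) / reps)
            # exact conditional tests are conservative: below alpha is fine
            assert frac <= alpha + 3 * sd


class TestVariantQc:
    def test_low_call_rate_genotyped_variant_dropped(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        g[:6, 0] = np.nan  # call rate 0.94
        cohort = make_cohort(g, genotyped=True)
        report = variant_qc(cohort)
        assert not report["keep"][0]
        assert "call_rate" in report["reason"][0]
        assert report["keep"][1]

    def test_info_threshold_is_strict_less_than(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        cohort = make_cohort(g, genotyped=False)
        cohort.variants.loc[0, "info"] = 0.40   # kept: threshold is < 0.4
        cohort.variants.loc[1, "info"] = 0.399  # dropped
        report = variant_qc(cohort)
        assert report["keep"][0]
        assert not report["keep"][1]
        assert report["reason"][1] == "info"

    def test_maf_filter_applies_to_genotyped_not_imputed(self):
        # 36 het carriers of 2000 samples: MAF exactly 0.009
        col = np.zeros((2000, 1))
        col[:36, 0] = 1.0
        genotyped = make_cohort(col, genotyped=True)
        imputed = make_cohort(col, genotyped=False)
        assert not variant_qc(genotyped)["keep"][0]
        assert "maf" in variant_qc(genotyped)["reason"][0]
        assert variant_qc(imputed)["keep"][0]

    def test_hwe_violation_dropped(self):
        # all heterozygotes: extreme HWE violation at n=300
        g = np.ones((300, 1))
        cohort = make_cohort(g, genotyped=True)
        report = variant_qc(cohort)
        assert not report["keep"][0]
        assert "hwe" in report["reason"][0]

    def test_idempotent_on_kept_variants(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, rng.uniform(0.005, 0.4, size=30),
                         size=(400, 30)).astype(float)
        cohort = make_cohort(g, genotyped=True)
        first = variant_qc(cohort)
        kept = cohort.subset_variants(first["keep"].to_numpy())
        second = variant_qc(kept)
        assert second["keep"].all()


class TestPairwiseIbs:
    def test_identical_samples_score_one(self):
        g = np.array([0, 1, 2, 1, 0], float)
        assert pairwise_ibs(g, g) == 1.0

    def test_opposite_homozygotes_score_zero(self):
        assert pairwise_ibs([0, 2], [2, 0]) == 0.0

    def test_mixed_sharing_arithmetic(self):
        assert pairwise_ibs([0, 1, 2], [0, 1, 0]) == pytest.approx(2 / 3)

    def test_missing_sites_excluded_from_mean(self):
        g1 = np.array([0, np.nan, 2])
        g2 = np.array([0, 1, 2])
        assert pairwise_ibs(g1, g2) == 1.0

    def test_no_shared_sites_raises(self):
        with pytest.raises(ValueError):
            pairwise_ibs([np.nan, 1], [0, np.nan])


class TestSampleQc:
    @staticmethod
    def _clean_matrix(n=40, m=400, seed=0):
        rng = np.random.default_rng(seed)
        return rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(float)

    def test_duplicate_sample_removes_exactly_one(self):
        g = self._clean_matrix()
        g[1] = g[0]  # duplicate pair, IBS = 1
        report = sample_qc(g, [f"s{i}" for i in range(g.shape[0])])
        dropped = report.loc[~report["keep"], "sample_id"].tolist()
        assert len(dropped) == 1
        assert dropped[0] in {"s0", "s1"}
        assert (report.loc[~report["keep"], "reason"] == "relatedness").all()

    def test_low_call_rate_sample_removed(self):
        g = self._clean_matrix()
        g[3, : g.shape[1] // 10] = np.nan  # 10% missing
        report = sample_qc(g, [f"s{i}" for i in range(g.shape[0])])
        assert not report.set_index("sample_id").loc["s3", "keep"]
        assert report.set_index("sample_id").loc["s3", "reason"] == "call_rate"

    def test_constant_heterozygosity_flags_nobody(self):
        # identical het rate for every sample (zero variance is guarded)
        # but shuffled genotypes so nobody looks related
        rng = np.random.default_rng(6)
        base = np.tile([0.0, 1.0, 2.0], 50)
        g = np.vstack([rng.permutation(base) for _ in range(10)])
        report = sample_qc(g, [f"s{i}" for i in range(10)])
        assert report["keep"].all()

    def test_extreme_heterozygosity_outlier_flagged(self):
        g = self._clean_matrix(n=60, m=600, seed=4)
        g[7] = 1.0  # fully heterozygous sample
        report = sample_qc(g, [f"s{i}" for i in range(60)])
        assert not report.set_index("sample_id").loc["s7", "keep"]

    def test_fewer_than_three_samples_skips_with_warning(self):
        g = self._clean_matrix(n=2)
        with pytest.warns(UserWarning):
            report = sample_qc(g, ["a", "b"])
        assert report["keep"].all()

    def test_idempotent_on_clean_cohort(self):
        g = self._clean_matrix(n=50, m=500, seed=9)
        first = sample_qc(g, [f"s{i}" for i in range(50)])
        kept_idx = np.flatnonzero(first["keep"].to_numpy())
        second = sample_qc(g[kept_idx], [f"s{i}" for i in kept_idx])
        assert second["keep"].all()


def test_thresholds_must_be_probabilities():
    with pytest.raises(ValueError):
        QcThresholds(info_min=1.5)
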
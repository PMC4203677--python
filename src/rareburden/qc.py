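"""Genotype- and sample-level quality control.

Filters mirror standard GWAS practice for array data that is
subsequently imputed: directly genotyped variants are screened on minor
allele frequency, call rate and an exact Hardy-Weinberg test, imputed
variants on the imputation INFO score; samples are screened on call
rate, autosomal heterozygosity outliers (Benjamini-Hochberg FDR) and
pairwise identity-by-state relatedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .burden import compute_maf
from .cohort import StudyCohort


@dataclass
class QcThresholds:
    """Exclusion thresholds.

    Genotyped variants are dropped when MAF < ``maf_min_genotyped``,
    call rate < ``variant_call_rate_min`` or HWE exact P <
    ``hwe_p_min``; imputed variants when INFO < ``info_min`` (INFO equal
    to the threshold is kept).  Samples are dropped on call rate, on
    heterozygosity outliers at FDR ``het_fdr`` and on pairwise IBS >
    ``ibs_max``.
    """

    maf_min_genotyped: float = 0.01
    variant_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    sample_call_rate_min: float = 0.95
    het_fdr: float = 0.01
    ibs_max: float = 0.95
    info_min: float = 0.4

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts no more probable than the observed one
    (the standard exact HWE formulation, computed with a stable
    recurrence from the distribution mode).

    Returns the P value in ``(0, 1]``; monomorphic input gives 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers: {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    n_alleles = 2 * n

    # Heterozygote counts share the parity of the rare-allele count.
    h_max = min(rare, n_alleles - rare)
    h_mid = int(rare * (n_alleles - rare) / n_alleles)
    if h_mid % 2 != rare % 2:
        h_mid += 1
    if h_mid > h_max:
        h_mid = h_max

    probs = {h_mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (n_r+1)(n_c+1))
    h = h_mid
    n_r = (rare - h) // 2          # rare homozygotes
    n_c = n - n_r - h              # common homozygotes
    p = 1.0
    while h >= 2:
        p *= h * (h - 1) / (4.0 * (n_r + 1) * (n_c + 1))
        h -= 2
        n_r += 1
        n_c += 1
        probs[h] = p
    # upward recurrence: P(h+2)/P(h) = 4 n_r n_c / ((h+1)(h+2))
    h = h_mid
    n_r = (rare - h) // 2
    n_c = n - n_r - h
    p = 1.0
    while h + 2 <= h_max:
        p *= 4.0 * n_r * n_c / ((h + 1) * (h + 2))
        h += 2
        n_r -= 1
        n_c -= 1
        probs[h] = p

    total = sum(probs.values())
    p_obs = probs[n_het] if n_het in probs else 0.0
    if p_obs == 0.0:
        raise ValueError(
            f"heterozygote count {n_het} incompatible with allele counts"
        )
    tail = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12))
    return min(1.0, tail / total)


def variant_qc(cohort: StudyCohort, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-variant keep/drop decisions with reason codes.

    Returns a DataFrame aligned with ``cohort.variants`` carrying
    ``keep`` (bool) and ``reason`` (comma-joined codes among ``maf``,
    ``call_rate``, ``hwe`` for genotyped variants and ``info`` for
    imputed ones; empty when kept).
    """
    thr = thresholds or QcThresholds()
    n_s, n_v = cohort.dosages.shape
    genotyped = cohort.variants["genotyped"].to_numpy(dtype=bool)
    info = cohort.variants["info"].to_numpy(dtype=float)
    call_rate = 1.0 - np.mean(np.isnan(cohort.dosages), axis=0)
    hard = cohort.hard_calls()

    reasons: list[str] = []
    keep = np.ones(n_v, dtype=bool)
    for j in range(n_v):
        why = []
        if genotyped[j]:
            col = cohort.dosages[:, j]
            if call_rate[j] < thr.variant_call_rate_min:
                why.append("call_rate")
            if np.any(~np.isnan(col)):
                if compute_maf(col) < thr.maf_min_genotyped:
                    why.append("maf")
            else:
                why.append("call_rate")
            g = hard[:, j]
            g = g[~np.isnan(g)]
            if g.size:
                n_aa = int(np.sum(g == 0))
                n_ab = int(np.sum(g == 1))
                n_bb = int(np.sum(g == 2))
                if hwe_exact_test(n_aa, n_ab, n_bb) < thr.hwe_p_min:
                    why.append("hwe")
        else:
            if info[j] < thr.info_min:
                why.append("info")
        keep[j] = not why
        reasons.append(",".join(why))

    return pd.DataFrame(
        {"id": cohort.variants["id"], "keep": keep, "reason": reasons}
    )


def pairwise_ibs(g1: np.ndarray, g2: np.ndarray) -> float:
    """Mean identity-by-state between two hard-call genotype vectors.

    Averaged over variants non-missing in both samples:
    ``(2 - |g1 - g2|) / 2`` per variant, so identical genotypes score 1
    and opposite homozygotes score 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    shared = ~np.isnan(g1) & ~np.isnan(g2)
    if not np.any(shared):
        raise ValueError("no variants genotyped in both samples")
    return float(np.mean((2.0 - np.abs(g1[shared] - g2[shared])) / 2.0))


def _bh_reject(p: np.ndarray, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask."""
    m = p.size
    order = np.argsort(p)
    thresh = fdr * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        reject[order[: k + 1]] = True
    return reject


def sample_qc(
    hardcalls: np.ndarray,
    sample_ids: Sequence[str],
    thresholds: QcThresholds | None = None,
    ibs_variant_subset: int | None = None,
) -> pd.DataFrame:
    """Per-sample keep/drop decisions from a hard-call genotype matrix.

    Applies, in order: call-rate exclusion; heterozygosity-rate outlier
    exclusion (z score against the cohort mean/SD, two-sided normal P,
    Benjamini-Hochberg at ``het_fdr``); and pairwise-IBS relatedness
    exclusion, dropping the lower-call-rate member of each pair above
    ``ibs_max`` (ties broken by sample order).  With fewer than three
    samples the heterozygosity and relatedness steps are skipped with a
    warning.  ``ibs_variant_subset`` optionally thins the variants used
    for IBS (evenly spaced deterministic subset).
    """
    thr = thresholds or QcThresholds()
    g = np.asarray(hardcalls, dtype=float)
    ids = list(sample_ids)
    n = g.shape[0]
    if len(ids) != n:
        raise ValueError("sample_ids length must match hardcall rows")

    call_rate = 1.0 - np.mean(np.isnan(g), axis=1)
    keep = call_rate >= thr.sample_call_rate_min
    reason = np.where(keep, "", "call_rate").astype(object)

    het_p = np.full(n, np.nan)
    if np.sum(keep) < 3:
        warnings.warn("fewer than 3 samples pass call rate; skipping "
                      "heterozygosity and relatedness checks")
    else:
        with np.errstate(invalid="ignore"):
            het = np.nanmean(g == 1, axis=1)
        mu = np.mean(het[keep])
        sd = np.std(het[keep], ddof=1)
        if sd > 0:
            z = (het - mu) / sd
            het_p = 2.0 * stats.norm.sf(np.abs(z))
            flag = np.zeros(n, dtype=bool)
            flag[keep] = _bh_reject(het_p[keep], thr.het_fdr)
            for i in np.flatnonzero(flag):
                keep[i] = False
                reason[i] = "heterozygosity"

        idx = np.flatnonzero(keep)
        g_ibs = g
        if ibs_variant_subset is not None and ibs_variant_subset < g.shape[1]:
            cols = np.linspace(0, g.shape[1] - 1, ibs_variant_subset).astype(int)
            g_ibs = g[:, cols]
        # greedy pass in sample order; the lower-call-rate member goes
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            if not keep[i]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                j = idx[b_pos]
                if not keep[j]:
                    continue
                shared = ~np.isnan(g_ibs[i]) & ~np.isnan(g_ibs[j])
                if not shared.any():
                    continue
                ibs = np.mean((2.0 - np.abs(g_ibs[i, shared] - g_ibs[j, shared])) / 2.0)
                if ibs > thr.ibs_max:
                    drop = j if call_rate[j] <= call_rate[i] else i
                    keep[drop] = False
                    reason[drop] = "relatedness"
                    if drop == i:
                        break

    return pd.DataFrame(
        {
            "sample_id": ids,
            "call_rate": call_rate,
            "het_outlier_p": het_p,
            "keep": keep,
            "reason": reason,
        }
    )


def apply_variant_qc(cohort: StudyCohort, thresholds: QcThresholds | None = None):
    """Convenience wrapper: run :func:`variant_qc` and return the
    filtered cohort together with the report."""
    report = variant_qc(cohort, thresholds)
    return cohort.subset_variants(report["keep"].to_numpy()), report
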
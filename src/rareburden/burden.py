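"""Gene-collapsed rare-variant dosage ("burden") association.

Rare variants (MAF at or below 3% by default) falling in a gene's
interval are collapsed into a per-sample gene dosage

    D = (sum_i G_i) / n

where ``G_i`` is the imputed dosage of the i-th qualifying variant and
``n`` the number of qualifying variants, so ``D`` stays on the [0, 2]
dosage scale.  ``D`` (or a single SNP's dosage) is then tested for
case-control association by covariate-adjusted logistic regression with
Wald inference.  Risk and protective alleles are pooled: every
qualifying allele counts toward ``D`` regardless of its direction of
effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import GeneInterval, StudyCohort, normalize_chrom


class AssociationError(ValueError):
    """Raised when an association test cannot be set up at all."""


@dataclass
class GeneDosage:
    """Collapsed dosage for one gene in one study."""

    gene: str
    n_variants: int
    values: np.ndarray          # per-sample D, NaN where no variant observed
    variant_ids: list[str]


@dataclass
class GeneResult:
    """One burden (or single-SNP) regression result in one study.

    ``estimable`` is False when the fit is degenerate (zero-variance
    predictor, separation, non-convergence); such results enter the
    meta-analysis as unavailable (``?``).
    """

    study: str
    gene: str
    beta: float
    se: float
    z: float
    p: float
    n_variants: int
    n_samples: int
    estimable: bool = True
    message: str = ""


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from a dosage column.

    ``p_hat = mean(dosage)/2`` over non-missing entries; returns
    ``min(p_hat, 1 - p_hat)``.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise AssociationError("all dosages missing; MAF undefined")
    p = float(np.mean(d)) / 2.0
    return min(p, 1.0 - p)


def select_rare_variants(
    cohort: StudyCohort,
    gene_intervals: Sequence[GeneInterval],
    maf_max: float = 0.03,
    maf_min: float = 0.0,
    info_min: float = 0.4,
) -> dict[str, np.ndarray]:
    """Qualifying variant column indices per gene.

    A variant qualifies for a gene when its position lies inside the
    gene's interval (1-based inclusive on both ends), its study MAF lies
    in ``[maf_min, maf_max]`` (both ends inclusive: MAF exactly 3% is
    rare, and the stage-2 floor keeps MAF exactly 0.5%) and its INFO is
    at least ``info_min``.  Genes with no qualifying variant map to an
    empty index array — untestable in this study, ``?`` downstream.
    Overlapping genes may share variants.
    """
    chrom = cohort.variants["chrom"].map(normalize_chrom).to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    info = cohort.variants["info"].to_numpy(dtype=float)
    maf = np.array([
        compute_maf(cohort.dosages[:, j]) if np.any(~np.isnan(cohort.dosages[:, j]))
        else np.nan
        for j in range(cohort.n_variants)
    ])
    with np.errstate(invalid="ignore"):
        base = (maf >= maf_min) & (maf <= maf_max) & (info >= info_min)
    out: dict[str, np.ndarray] = {}
    for iv in gene_intervals:
        in_gene = (chrom == normalize_chrom(iv.chrom)) & (pos >= iv.start) & (pos <= iv.end)
        out[iv.gene] = np.flatnonzero(base & in_gene)
    return out


def gene_dosage(cohort: StudyCohort, variant_idx: np.ndarray, gene: str = "") -> GeneDosage:
    """Collapse the selected variants into the per-sample gene dosage D.

    A sample's D averages over its non-missing qualifying dosages (the
    per-sample ``n`` shrinks with missingness, keeping D on [0, 2]);
    samples missing every qualifying variant get ``NaN`` and drop out of
    the regression.
    """
    idx = np.asarray(variant_idx, dtype=int)
    if idx.size == 0:
        raise AssociationError(f"gene {gene}: no qualifying variants")
    sub = cohort.dosages[:, idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        d = np.nanmean(sub, axis=1)
    return GeneDosage(
        gene=gene,
        n_variants=idx.size,
        values=d,
        variant_ids=cohort.variants["id"].iloc[idx].tolist(),
    )


#: Covariate columns picked up automatically from a sample table.
BASE_COVARIATES = ("age", "sex", "edu")


def prepare_covariates(
    samples: pd.DataFrame,
    include_apoe: bool = False,
) -> pd.DataFrame:
    """Assemble the regression covariate matrix from a sample table.

    Takes age, sex and education (mean-imputing missing education, then
    treating the 1-4 category as continuous), every ``PC*`` column, and
    optionally the APOE e4 term (genotyped count preferred over imputed
    dosage).
    """
    cols = {}
    for c in BASE_COVARIATES:
        if c in samples.columns:
            v = samples[c].astype(float)
            if c == "edu" and v.isna().any():
                v = v.fillna(v.mean())
            cols[c] = v
    for c in samples.columns:
        if c.startswith("PC"):
            cols[c] = samples[c].astype(float)
    if include_apoe:
        from .conditional import apoe_covariate  # local import: no cycle at module load
        cols["apoe_e4"] = pd.Series(apoe_covariate(samples), index=samples.index)
    return pd.DataFrame(cols, index=samples.index)


def fit_association(
    predictor: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    family: str = "logistic",
    study: str = "",
    gene: str = "",
    n_variants: int = 1,
) -> GeneResult:
    """Covariate-adjusted association test of a dosage predictor.

    Fits ``status ~ const + predictor + covariates`` by maximum
    likelihood (logistic by default; ``family="linear"`` gives ordinary
    least squares for comparison with linear-model burden engines) and
    reports the Wald beta, SE, Z and two-sided P for the predictor.

    Rows with missing predictor or covariates are dropped.  Separation,
    non-convergence and zero predictor variance yield a non-estimable
    result rather than an exception; a single-class phenotype raises.
    """
    y = np.asarray(status, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        cov = np.empty((len(y), 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_names = [f"c{i}" for i in range(cov.shape[1])]

    ok = np.isfinite(y) & np.isfinite(x)
    if cov.shape[1]:
        ok &= np.all(np.isfinite(cov), axis=1)
    y, x, cov = y[ok], x[ok], cov[ok]
    n = int(ok.sum())

    classes = np.unique(y)
    if family == "logistic" and classes.size < 2:
        raise AssociationError("phenotype has a single class; cannot fit")

    def degenerate(msg: str) -> GeneResult:
        return GeneResult(study, gene, np.nan, np.nan, np.nan, np.nan,
                          n_variants, n, estimable=False, message=msg)

    if n < cov.shape[1] + 3:
        return degenerate("too few complete observations")
    if np.var(x) == 0:
        return degenerate("zero-variance predictor")
    if cov.shape[1]:
        # zero-variance covariates are collinear with the intercept and
        # carry no information: adjusting for one equals not adjusting
        keep_cov = np.var(cov, axis=0) > 0
        cov = cov[:, keep_cov]
        cov_names = [c for c, k in zip(cov_names, keep_cov) if k]

    design = np.column_stack([np.ones(n), x, cov])
    names = ["const", "predictor", *cov_names]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "logistic":
                res = sm.Logit(y, design).fit(disp=0, maxiter=200, warn_convergence=False)
                converged = bool(res.mle_retvals.get("converged", True))
            elif family == "linear":
                res = sm.OLS(y, design).fit()
                converged = True
            else:
                raise AssociationError(f"unknown family {family!r}")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return degenerate("separation or singular design")
    except Exception as exc:  # statsmodels raises assorted numerical errors
        if isinstance(exc, AssociationError):
            raise
        return degenerate(f"fit failed: {exc}")

    beta = float(res.params[1])
    se = float(res.bse[1])
    if not converged or not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return degenerate("non-convergence or unstable standard error")
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return GeneResult(study, gene, beta, se, z, p, n_variants, n)


def fit_gene_burden(
    cohort: StudyCohort,
    variant_idx: np.ndarray,
    gene: str,
    include_apoe: bool = False,
    family: str = "logistic",
) -> GeneResult:
    """Collapse + regress in one step for one gene in one study."""
    if np.asarray(variant_idx).size == 0:
        return GeneResult(cohort.name, gene, np.nan, np.nan, np.nan, np.nan,
                          0, 0, estimable=False, message="no qualifying variants")
    gd = gene_dosage(cohort, variant_idx, gene)
    cov = prepare_covariates(cohort.samples, include_apoe=include_apoe)
    return fit_association(
        gd.values, cohort.status, cov, family=family,
        study=cohort.name, gene=gene, n_variants=gd.n_variants,
    )
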
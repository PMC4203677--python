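"""Synthetic multi-study case-control cohorts of imputed rare-variant dosages.

The generator emulates the statistical structure the burden/meta
pipeline assumes: several case-control studies of unequal size drawn
from one population; genes laid out on a synthetic chromosome, each
holding a handful of rare variants (MAF spectrum concentrated below
3%); Hardy-Weinberg genotypes; a logistic disease model with age, sex,
education and principal-component effects plus a strong APOE-e4-like
confounder locus; case-control ascertainment to fixed per-study quotas;
and a parametric imputation-noise model that turns hard genotypes into
posterior-mean dosages with a per-variant INFO score.

Ground truth (true genotypes, linear predictors, causal flags) is
retained alongside each generated study so recovery and calibration
tests can score the pipeline against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import compute_maf
from .cohort import GeneInterval, StudyCohort, VARIANT_COLUMNS
from . import io as study_io


class SimulationError(ValueError):
    """Invalid generator configuration or unreachable sampling target."""


@dataclass(frozen=True)
class StudySpec:
    """Shape of one study: label plus post-QC case/control quotas."""

    name: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise SimulationError(
                f"study {self.name}: case/control counts must be positive"
            )


#: The six-study AD meta-analysis shape this package emulates: post-QC
#: case/control counts of ADNI, ADNI2, GenADA, eMERGE, NIA-LOAD and the
#: Framingham study (4,171 cases and 9,358 controls in total).  The
#: order fixes the per-study direction strings.
AD_STUDY_TABLE: tuple[StudySpec, ...] = (
    StudySpec("ADNI", 350, 169),
    StudySpec("ADNI2", 53, 125),
    StudySpec("GenADA", 779, 803),
    StudySpec("eMERGE", 632, 1843),
    StudySpec("NIA-LOAD", 2098, 2095),
    StudySpec("Framingham", 259, 4323),
)


@dataclass(frozen=True)
class CovariateEffects:
    """Log odds ratios of the non-genetic covariates.

    ``age`` is per year (age enters centred), ``sex`` for female=1,
    ``edu`` per education category (centred), ``pc`` per unit of each
    standard-normal principal component.
    """

    age: float = 0.03
    sex: float = 0.2
    edu: float = -0.15
    pc: float = 0.0


#: Multinomial over the four education categories (mean 2.95).
EDU_PROBS = (0.05, 0.25, 0.40, 0.30)
_EDU_MEAN = sum((k + 1) * p for k, p in enumerate(EDU_PROBS))
_AGE_MEAN, _AGE_SD = 75.0, 6.5


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; identical config + seed gives
    byte-identical output.

    ``maf_beta`` parametrises the Beta distribution the per-variant
    population MAFs are drawn from, truncated to ``maf_range``; the
    default Beta(0.6, 30) puts most mass below 3%, matching the rare
    regime the pipeline targets.  ``causal_log_or`` maps gene ids to the
    log odds ratio applied per unit of that gene's true collapsed
    dosage.  ``confounder_ld_gene`` optionally names a gene whose rare
    alleles ride on e4 haplotypes (D' = 1), giving an LD-driven signal
    with no direct effect — the pattern the conditional analysis must
    expose.  ``imputation_error`` is the mean per-variant posterior
    miscall rate (per-variant rates are drawn uniformly on
    [0, 2 x mean], capped below 0.5).
    """

    studies: tuple[StudySpec, ...] = AD_STUDY_TABLE
    n_genes: int = 100
    variants_per_gene: tuple[int, int] = (4, 10)
    maf_beta: tuple[float, float] = (0.6, 30.0)
    maf_range: tuple[float, float] = (0.001, 0.05)
    causal_log_or: Mapping[str, float] = field(default_factory=dict)
    confounder_log_or: float = float(np.log(3.0))
    confounder_allele_freq: float = 0.15
    confounder_ld_gene: str | None = None
    covariate_effects: CovariateEffects = CovariateEffects()
    n_pcs: int = 2
    imputation_error: float = 0.05
    edu_missing_rate: float = 0.05
    baseline_prevalence_logit: float = -1.0
    seed: int = 0
    max_batches: int = 500

    def __post_init__(self) -> None:
        if not self.studies:
            raise SimulationError("need at least one study")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be positive")
        lo, hi = self.variants_per_gene
        if lo < 1 or hi < lo:
            raise SimulationError(f"bad variants_per_gene range ({lo}, {hi})")
        a, b = self.maf_beta
        if a <= 0 or b <= 0:
            raise SimulationError(f"Beta parameters must be positive, got {a}, {b}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise SimulationError(
                f"MAF range must satisfy 0 < lo <= hi < 0.5, got ({lo}, {hi})"
            )
        if not 0.0 <= self.imputation_error < 0.5:
            raise SimulationError("imputation_error must lie in [0, 0.5)")
        if not 0.0 < self.confounder_allele_freq < 0.5:
            raise SimulationError("confounder allele frequency must lie in (0, 0.5)")
        if not 0.0 <= self.edu_missing_rate < 1.0:
            raise SimulationError("edu_missing_rate must lie in [0, 1)")
        for g in self.causal_log_or:
            if g == self.confounder_ld_gene:
                raise SimulationError(
                    f"gene {g} cannot be both causal and the LD-linked gene"
                )

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]


@dataclass
class GeneMap:
    """Synthetic coordinate system: gene intervals and variant sites."""

    intervals: list[GeneInterval]
    variants: pd.DataFrame      # id, chrom, pos, gene, maf_true
    gene_columns: dict[str, np.ndarray]


@dataclass
class StudyTruth:
    """Ground truth retained for one generated study."""

    genotypes: np.ndarray       # int8, n_samples x n_variants
    linear_predictor: np.ndarray
    e4: np.ndarray


@dataclass
class TrueModel:
    """Generator ground truth across studies."""

    causal_log_or: dict[str, float]
    ld_gene: str | None
    per_study: dict[str, StudyTruth]

    def is_causal(self, gene: str) -> bool:
        return gene in self.causal_log_or


@dataclass
class SimulatedData:
    cohorts: list[StudyCohort]
    intervals: list[GeneInterval]
    truth: TrueModel
    config: SimulationConfig


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def draw_gene_map(config: SimulationConfig, rng: np.random.Generator) -> GeneMap:
    """Lay genes on one synthetic chromosome and draw variant sites with
    population MAFs from the truncated Beta spectrum."""
    lo, hi = config.variants_per_gene
    gene_ids = config.gene_ids()
    intervals, rows = [], []
    gene_cols: dict[str, np.ndarray] = {}
    col = 0
    for i, gene in enumerate(gene_ids):
        start = i * 100_000 + 1
        end = start + 49_999
        intervals.append(GeneInterval(gene=gene, chrom="1", start=start, end=end))
        n_v = int(rng.integers(lo, hi + 1))
        pos = np.sort(rng.choice(np.arange(start, end + 1), size=n_v, replace=False))
        mafs = _draw_mafs(config, rng, n_v)
        for p, m in zip(pos, mafs):
            rows.append((f"snp_1_{p}", "1", int(p), gene, float(m)))
        gene_cols[gene] = np.arange(col, col + n_v)
        col += n_v
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "gene", "maf_true"])
    return GeneMap(intervals, variants, gene_cols)


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a, b = config.maf_beta
    lo, hi = config.maf_range
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        draw = rng.beta(a, b, size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + keep.size] = keep
        filled += keep.size
        if filled == n:
            return out
    raise SimulationError(
        f"MAF spectrum Beta{config.maf_beta} puts almost no mass in {config.maf_range}"
    )


def simulate_true_genotypes(
    mafs: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    e4: np.ndarray | None = None,
    ld_columns: np.ndarray | None = None,
    ld_carrier_prob: np.ndarray | None = None,
) -> np.ndarray:
    """Draw hard genotypes under Hardy-Weinberg proportions.

    Each variant is Binomial(2, maf) per sample.  Columns listed in
    ``ld_columns`` are instead drawn as Binomial(e4 count, q): their
    rare alleles occur only on e4 haplotypes (D' = 1 linkage with the
    confounder locus).
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 0.5)):
        raise SimulationError("MAFs must lie strictly inside (0, 0.5)")
    g = rng.binomial(2, mafs, size=(n_samples, mafs.size)).astype(np.int8)
    if ld_columns is not None and ld_columns.size:
        if e4 is None or ld_carrier_prob is None:
            raise SimulationError("LD columns need e4 counts and carrier probabilities")
        g[:, ld_columns] = rng.binomial(
            e4[:, None].astype(int), ld_carrier_prob[None, :]
        ).astype(np.int8)
    return g


def apply_imputation_noise(
    genotypes: np.ndarray,
    error: float | np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean dosages and per-variant INFO from hard genotypes.

    With per-variant miscall rate ``e``, each genotype's posterior is
    the (1-e)/e mixture of a point mass on the true genotype and the
    variant's empirical genotype distribution, so the dosage is

        d = (1 - e) g + e * mu,   mu = mean genotype of the column.

    INFO is the standard imputation quality ratio
    ``1 - mean(posterior variance) / (2 theta (1 - theta))`` with
    ``theta`` the estimated allele frequency, clamped to [0, 1]; a
    monomorphic column has INFO 0 by convention.  With ``e = 0`` the
    dosage equals the genotype and INFO is 1 for every polymorphic
    variant.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise SimulationError("genotype matrix must be 2-dimensional")
    if not np.all(np.isin(g, (0.0, 1.0, 2.0))):
        raise SimulationError("genotypes must be hard calls in {0, 1, 2}")
    e = np.asarray(error, dtype=float)
    if np.any((e < 0) | (e >= 0.5)):
        raise SimulationError("imputation error rates must lie in [0, 0.5)")
    e = np.broadcast_to(e, (g.shape[1],))

    pi = np.stack([(g == k).mean(axis=0) for k in (0, 1, 2)])  # 3 x V
    m1 = pi[1] + 2.0 * pi[2]
    m2 = pi[1] + 4.0 * pi[2]
    dosage = (1.0 - e) * g + e * m1
    post_var = (1.0 - e) * g**2 + e * m2 - dosage**2
    mean_var = post_var.mean(axis=0)

    theta = m1 / 2.0
    denom = 2.0 * theta * (1.0 - theta)
    polymorphic = g.var(axis=0) > 0
    info = np.zeros(g.shape[1])
    ok = polymorphic & (denom > 0)
    info[ok] = np.clip(1.0 - mean_var[ok] / denom[ok], 0.0, 1.0)
    return dosage, info


def simulate_covariates(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw age, sex, education category and principal components."""
    cols = {
        "age": np.round(rng.normal(_AGE_MEAN, _AGE_SD, size=n), 1),
        "sex": rng.binomial(1, 0.45, size=n).astype(float),
        "edu": (rng.choice(4, size=n, p=EDU_PROBS) + 1).astype(float),
    }
    for k in range(config.n_pcs):
        cols[f"PC{k + 1}"] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(cols)


def disease_logit(
    genotypes: np.ndarray,
    covariates: pd.DataFrame,
    e4: np.ndarray,
    gene_columns: Mapping[str, np.ndarray],
    config: SimulationConfig,
) -> np.ndarray:
    """Linear predictor of the logistic disease model from TRUE genotypes."""
    eff = config.covariate_effects
    lp = np.full(len(covariates), config.baseline_prevalence_logit)
    for gene, beta in config.causal_log_or.items():
        cols = gene_columns[gene]
        d_true = genotypes[:, cols].mean(axis=1)
        lp += beta * d_true
    lp += config.confounder_log_or * e4
    lp += eff.age * (covariates["age"].to_numpy() - _AGE_MEAN)
    lp += eff.sex * covariates["sex"].to_numpy()
    lp += eff.edu * (covariates["edu"].to_numpy() - _EDU_MEAN)
    for k in range(config.n_pcs):
        lp += eff.pc * covariates[f"PC{k + 1}"].to_numpy()
    return lp


def simulate_phenotypes(
    logit: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli case status from the linear predictor."""
    p = 1.0 / (1.0 + np.exp(-np.asarray(logit, dtype=float)))
    return (rng.random(p.size) < p).astype(int)


# ---------------------------------------------------------------------------
# per-study assembly
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimulationConfig,
    study: StudySpec,
    gene_map: GeneMap,
    rng: np.random.Generator,
) -> tuple[StudyCohort, StudyTruth]:
    """Generate one ascertained study.

    Population individuals (genotypes, covariates, e4, phenotype) are
    drawn in batches and kept until the case and control quotas are both
    filled (rejection sampling); variants monomorphic in the final
    sample are redrawn up to 100 times and otherwise left for QC to
    drop.  Hard genotypes are then degraded to posterior-mean dosages
    with per-variant INFO, and education values are masked at the
    configured missing rate.
    """
    mafs = gene_map.variants["maf_true"].to_numpy()
    n_v = mafs.size
    ld_cols = np.array([], dtype=int)
    ld_q = None
    if config.confounder_ld_gene is not None:
        if config.confounder_ld_gene not in gene_map.gene_columns:
            raise SimulationError(
                f"LD gene {config.confounder_ld_gene!r} not in the gene map"
            )
        ld_cols = gene_map.gene_columns[config.confounder_ld_gene]
        ld_q = np.clip(mafs[ld_cols] / config.confounder_allele_freq, 0.0, 1.0)

    need = {1: study.n_cases, 0: study.n_controls}
    kept_g, kept_cov, kept_e4, kept_lp, kept_y = [], [], [], [], []
    for _ in range(config.max_batches):
        if need[1] == 0 and need[0] == 0:
            break
        batch = max(512, 2 * (need[1] + need[0]))
        e4 = rng.binomial(2, config.confounder_allele_freq, size=batch).astype(np.int8)
        g = simulate_true_genotypes(
            mafs, batch, rng, e4=e4, ld_columns=ld_cols, ld_carrier_prob=ld_q
        )
        cov = simulate_covariates(batch, config, rng)
        lp = disease_logit(g, cov, e4, gene_map.gene_columns, config)
        y = simulate_phenotypes(lp, rng)
        for cls in (1, 0):
            take = np.flatnonzero(y == cls)[: need[cls]]
            if take.size:
                kept_g.append(g[take])
                kept_cov.append(cov.iloc[take])
                kept_e4.append(e4[take])
                kept_lp.append(lp[take])
                kept_y.append(y[take])
                need[cls] -= take.size
    if need[1] or need[0]:
        raise SimulationError(
            f"study {study.name}: case/control quotas unreachable within "
            f"{config.max_batches} batches (intercept too extreme?)"
        )

    g = np.vstack(kept_g)
    cov = pd.concat(kept_cov, ignore_index=True)
    e4 = np.concatenate(kept_e4)
    lp = np.concatenate(kept_lp)
    y = np.concatenate(kept_y)
    order = rng.permutation(len(y))
    g, cov, e4, lp, y = g[order], cov.iloc[order].reset_index(drop=True), e4[order], lp[order], y[order]

    # monomorphic redraw policy: up to 100 fresh draws per stuck variant
    for _ in range(100):
        mono = np.flatnonzero(np.ptp(g, axis=0) == 0)
        mono = mono[~np.isin(mono, ld_cols)]
        if mono.size == 0:
            break
        g[:, mono] = rng.binomial(2, mafs[mono], size=(len(y), mono.size)).astype(np.int8)

    err = (
        np.minimum(rng.uniform(0.0, 2.0 * config.imputation_error, size=n_v), 0.499)
        if config.imputation_error > 0
        else np.zeros(n_v)
    )
    dosages, info = apply_imputation_noise(g, err)

    if config.edu_missing_rate > 0:
        mask = rng.random(len(y)) < config.edu_missing_rate
        cov.loc[mask, "edu"] = np.nan

    samples = cov.copy()
    samples.insert(0, "status", y)
    samples.insert(0, "sample_id", [f"{study.name}_{i:05d}" for i in range(len(y))])
    samples["apoe_e4"] = e4.astype(int)

    variants = pd.DataFrame(
        {
            "id": gene_map.variants["id"],
            "chrom": gene_map.variants["chrom"],
            "pos": gene_map.variants["pos"],
            "ref": "A",
            "alt": "C",
            "maf": [compute_maf(dosages[:, j]) for j in range(n_v)],
            "info": info,
            "genotyped": False,
        }
    )[VARIANT_COLUMNS]

    cohort = StudyCohort(study.name, dosages, variants, samples)
    return cohort, StudyTruth(genotypes=g, linear_predictor=lp, e4=np.asarray(e4))


def simulate_cohorts(config: SimulationConfig) -> SimulatedData:
    """Generate every configured study from one seeded stream."""
    for gene in list(config.causal_log_or) + (
        [config.confounder_ld_gene] if config.confounder_ld_gene else []
    ):
        if gene not in config.gene_ids():
            raise SimulationError(f"unknown gene id {gene!r} in config")
    rng = np.random.default_rng(config.seed)
    gene_map = draw_gene_map(config, rng)
    cohorts, per_study = [], {}
    for study in config.studies:
        cohort, truth = simulate_study(config, study, gene_map, rng)
        cohorts.append(cohort)
        per_study[study.name] = truth
    return SimulatedData(
        cohorts=cohorts,
        intervals=gene_map.intervals,
        truth=TrueModel(
            causal_log_or=dict(config.causal_log_or),
            ld_gene=config.confounder_ld_gene,
            per_study=per_study,
        ),
        config=config,
    )


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_study(cohort: StudyCohort, directory: str | Path, format: str = "vcf") -> None:
    """Write one study's dosages (VCF or .gen/.sample) plus its
    covariate TSV into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "vcf":
        study_io.write_vcf(cohort, directory / f"{cohort.name}.vcf")
    elif format == "gen":
        study_io.write_gen(cohort, directory / cohort.name)
    else:
        raise SimulationError(f"unsupported output format {format!r}")
    cohort.samples.to_csv(
        directory / f"{cohort.name}_covariates.tsv", sep="\t", index=False,
        float_format="%.6g",
    )


def write_simulation(data: SimulatedData, directory: str | Path,
                     format: str = "vcf") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cohort in data.cohorts:
        write_study(cohort, directory, format=format)
    study_io.write_bed(data.intervals, directory / "genes.bed")


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain (e.g. YAML-loaded) dictionary."""
    d = dict(d)
    if "studies" in d:
        d["studies"] = tuple(
            StudySpec(s["name"], int(s["n_cases"]), int(s["n_controls"]))
            for s in d["studies"]
        )
    if "covariate_effects" in d:
        d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
    for key in ("variants_per_gene", "maf_beta", "maf_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
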
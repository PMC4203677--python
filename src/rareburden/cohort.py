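"""In-memory containers for per-study imputed-dosage cohorts.

A study is held as a :class:`StudyCohort`: a samples-by-variants dosage
matrix (expected alternate-allele counts in ``[0, 2]``, ``NaN`` for
missing), a variant metadata table and a sample covariate/phenotype
table.  Dosages are the posterior-mean genotypes produced by imputation;
hard genotype calls, where available, are the rounded integer dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical column order of the variant metadata table.
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "info", "genotyped"]


class CohortError(ValueError):
    """Raised when a cohort or one of its inputs fails validation."""


@dataclass
class VariantRecord:
    """Metadata for one variant.

    ``maf`` is the minor allele frequency estimated from the dosages
    (``min(p, 1-p)``); ``info`` is the imputation quality score in
    ``[0, 1]``; ``genotyped`` distinguishes directly genotyped variants
    (subject to MAF/call-rate/HWE QC) from imputed ones (subject to the
    INFO filter).
    """

    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "C"
    maf: float = np.nan
    info: float = 1.0
    genotyped: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass
class GeneInterval:
    """A gene's span in 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CohortError(
                f"gene {self.gene}: start {self.start} > end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and (
            self.start <= pos <= self.end
        )


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr19`` and ``19`` compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def variants_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        (r.id, normalize_chrom(r.chrom), r.pos, r.ref, r.alt, r.maf, r.info, r.genotyped)
        for r in records
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


class StudyCohort:
    """One study's dosage matrix plus variant and sample metadata.

    Parameters
    ----------
    name : study label used in reports and direction strings.
    dosages : float array, shape ``(n_samples, n_variants)``, entries in
        ``[0, 2]`` or ``NaN`` for missing.
    variants : DataFrame with columns :data:`VARIANT_COLUMNS`.
    samples : DataFrame with at least ``sample_id``; a binary ``status``
        column (1 = case) and covariates (``age``, ``sex``, ``edu``,
        ``PC*``, ``apoe_e4`` / ``apoe_e4_dosage``) where available.
    """

    def __init__(
        self,
        name: str,
        dosages: np.ndarray,
        variants: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> None:
        self.name = str(name)
        self.dosages = np.asarray(dosages, dtype=float)
        self.variants = variants.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        if self.dosages.ndim != 2:
            raise CohortError("dosage matrix must be 2-dimensional")
        n_s, n_v = self.dosages.shape
        if len(self.variants) != n_v:
            raise CohortError(
                f"{n_v} dosage columns but {len(self.variants)} variant records"
            )
        if len(self.samples) != n_s:
            raise CohortError(
                f"{n_s} dosage rows but {len(self.samples)} sample records"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise CohortError(f"variant table missing columns: {missing}")
        if "sample_id" not in self.samples.columns:
            raise CohortError("sample table missing 'sample_id'")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"dosage out of [0, 2] at sample {i}, variant "
                f"{self.variants['id'].iat[j]}: {self.dosages[i, j]}"
            )
        if "status" in self.samples.columns:
            vals = set(pd.unique(self.samples["status"].dropna()))
            if not vals <= {0, 1}:
                raise CohortError(f"status must be binary 0/1, got {sorted(vals)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def status(self) -> np.ndarray:
        if "status" not in self.samples.columns:
            raise CohortError(f"study {self.name}: no phenotype attached")
        return self.samples["status"].to_numpy(dtype=int)

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.status == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.status == 0))

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(
                id=r.id, chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
                maf=float(r.maf), info=float(r.info), genotyped=bool(r.genotyped),
            )
            for r in self.variants.itertuples(index=False)
        ]

    def hard_calls(self, tol: float = 0.1) -> np.ndarray:
        """Rounded integer genotypes; dosages farther than ``tol`` from an
        integer (or missing) become ``NaN``."""
        g = np.round(self.dosages)
        with np.errstate(invalid="ignore"):
            g[np.abs(self.dosages - g) > tol] = np.nan
        return g

    def subset_variants(self, mask: np.ndarray) -> "StudyCohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return StudyCohort(
            self.name,
            self.dosages[:, idx],
            self.variants.iloc[idx],
            self.samples,
        )

    def subset_samples(self, mask: np.ndarray) -> "StudyCohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return StudyCohort(
            self.name,
            self.dosages[idx, :],
            self.variants,
            self.samples.iloc[idx],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pheno = ""
        if "status" in self.samples.columns:
            pheno = f", cases={self.n_cases}, controls={self.n_controls}"
        return (
            f"StudyCohort({self.name!r}, samples={self.n_samples}, "
            f"variants={self.n_variants}{pheno})"
        )
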
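"""Readers and writers for the external formats the pipeline touches.

Dosage matrices travel as VCF 4.2 with a per-sample ``DS`` FORMAT field
(read back through cyvcf2) or as IMPUTE2-style ``.gen``/``.sample``
pairs with an IMPUTE2-style sidecar ``.gen_info`` file carrying the
per-variant INFO score.  Gene intervals come from BED (0-based
half-open, converted to 1-based inclusive internally) and sample
covariates/phenotypes from a headered TSV.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .burden import compute_maf
from .cohort import GeneInterval, StudyCohort, VARIANT_COLUMNS, normalize_chrom


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# VCF with per-sample dosage (DS) field
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality (INFO) score">
##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped variant">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage (expected alternate allele count)">
"""


def write_vcf(cohort: StudyCohort, path: str | os.PathLike) -> None:
    """Write a cohort's dosages as VCF 4.2 with a DS FORMAT field.

    Dosages are printed to 3 decimals (the format's precision contract);
    missing dosages become ``.``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(cohort.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        sample_ids = cohort.samples["sample_id"].astype(str).tolist()
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, v in enumerate(cohort.variants.itertuples(index=False)):
            info = f"INFO={float(v.info):.6g}"
            if bool(v.genotyped):
                info += ";TYPED"
            ds = [
                "." if np.isnan(d) else f"{d:.3f}" for d in cohort.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{int(v.pos)}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{info}\tDS\t" + "\t".join(ds) + "\n"
            )


def read_vcf(path: str | os.PathLike, name: str | None = None) -> StudyCohort:
    """Read a DS-field VCF back into a :class:`StudyCohort` (covariates
    are attached separately)."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_header = 0
    n_data = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            elif line.strip():
                n_data += 1

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as VCF ({exc})") from exc
    sample_ids = list(vcf.samples)
    records = []
    columns = []
    idx = 0
    try:
        for variant in vcf:
            line_no = n_header + idx + 1
            try:
                ds = np.asarray(variant.format("DS"), dtype=float)[:, 0]
            except (TypeError, KeyError) as exc:
                raise ParseError(
                    f"{path} line {line_no}: missing DS dosage field"
                ) from exc
            # htslib encodes per-sample missing Float as NaN or a large
            # negative sentinel depending on version; normalise both.
            ds = np.where(np.isfinite(ds) & (ds > -1), ds, np.nan)
            with np.errstate(invalid="ignore"):
                if np.any((ds < 0) | (ds > 2)):
                    bad = ds[np.isfinite(ds) & ((ds < 0) | (ds > 2))][0]
                    raise ParseError(
                        f"{path} line {line_no}: dosage {bad} outside [0, 2]"
                    )
            info = variant.INFO.get("INFO")
            records.append(
                (
                    variant.ID or f"{variant.CHROM}:{variant.POS}",
                    normalize_chrom(variant.CHROM),
                    int(variant.POS),
                    variant.REF,
                    variant.ALT[0] if variant.ALT else ".",
                    np.nan,
                    float(info) if info is not None else np.nan,
                    variant.INFO.get("TYPED") is not None,
                )
            )
            columns.append(ds)
            idx += 1
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(
            f"{path} line {n_header + idx + 1}: malformed record ({exc})"
        ) from exc
    if idx < n_data:
        raise ParseError(
            f"{path} line {n_header + idx + 1}: truncated or malformed record"
        )

    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    variants["maf"] = [
        compute_maf(dosages[:, j]) if np.any(~np.isnan(dosages[:, j])) else np.nan
        for j in range(dosages.shape[1])
    ]
    samples = pd.DataFrame({"sample_id": sample_ids})
    return StudyCohort(name or path.stem, dosages, variants, samples)


# ---------------------------------------------------------------------------
# IMPUTE2-style .gen / .sample (+ sidecar info file)
# ---------------------------------------------------------------------------

def _dosage_to_probs(d: float) -> tuple[float, float, float]:
    # minimal-variance genotype-probability triple consistent with d
    if np.isnan(d):
        return (0.0, 0.0, 0.0)
    if d <= 1.0:
        return (1.0 - d, d, 0.0)
    return (0.0, 2.0 - d, d - 1.0)


def write_gen(cohort: StudyCohort, prefix: str | os.PathLike) -> None:
    """Write ``<prefix>.gen``, ``<prefix>.sample`` and
    ``<prefix>.gen_info``.

    The .gen rows carry three genotype probabilities per sample (printed
    to 5 decimals, so dosages round-trip to 3); an all-zero triple marks
    a missing dosage.  INFO and the genotyped flag go to the sidecar
    info file, in the spirit of the ``_info`` files imputation tools
    emit alongside .gen output.
    """
    prefix = Path(prefix)
    sample_ids = cohort.samples["sample_id"].astype(str).tolist()
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in sample_ids:
            fh.write(f"{s} {s} 0\n")
    with open(prefix.with_suffix(".gen"), "w") as fh:
        for j, v in enumerate(cohort.variants.itertuples(index=False)):
            fields = [str(v.chrom), str(v.id), str(int(v.pos)), str(v.ref), str(v.alt)]
            for d in cohort.dosages[:, j]:
                p0, p1, p2 = _dosage_to_probs(d)
                fields += [f"{p0:.5f}", f"{p1:.5f}", f"{p2:.5f}"]
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".gen_info"), "w") as fh:
        fh.write("id\tinfo\tgenotyped\n")
        for v in cohort.variants.itertuples(index=False):
            fh.write(f"{v.id}\t{float(v.info):.6g}\t{int(bool(v.genotyped))}\n")


def read_gen(prefix: str | os.PathLike, name: str | None = None) -> StudyCohort:
    """Read a ``.gen``/``.sample`` pair (dosage = p1 + 2 p2)."""
    prefix = Path(prefix)
    gen_path = prefix.with_suffix(".gen")
    sample_path = prefix.with_suffix(".sample")
    for p in (gen_path, sample_path):
        if not p.exists():
            raise FileNotFoundError(p)

    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{sample_path}: missing the two .sample header lines")
    sample_ids = [row[0] for row in lines[2:]]
    n_samples = len(sample_ids)

    info_map: dict[str, tuple[float, bool]] = {}
    info_path = prefix.with_suffix(".gen_info")
    if info_path.exists():
        info_df = pd.read_csv(info_path, sep="\t", dtype={"id": str})
        info_map = {
            r.id: (float(r.info), bool(r.genotyped))
            for r in info_df.itertuples(index=False)
        }

    records, columns = [], []
    with open(gen_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 5 + 3 * n_samples:
                raise ParseError(
                    f"{gen_path} line {line_no}: expected {5 + 3 * n_samples} "
                    f"fields for {n_samples} samples, got {len(fields)}"
                )
            chrom, vid, pos, ref, alt = fields[:5]
            try:
                probs = np.asarray(fields[5:], dtype=float).reshape(n_samples, 3)
            except ValueError as exc:
                raise ParseError(
                    f"{gen_path} line {line_no}: non-numeric genotype probability"
                ) from exc
            ds = probs[:, 1] + 2.0 * probs[:, 2]
            ds[probs.sum(axis=1) == 0] = np.nan
            with np.errstate(invalid="ignore"):
                if np.any((ds < 0) | (ds > 2 + 1e-9)):
                    raise ParseError(
                        f"{gen_path} line {line_no}: dosage outside [0, 2]"
                    )
            info, genotyped = info_map.get(vid, (np.nan, False))
            records.append(
                (vid, normalize_chrom(chrom), int(pos), ref, alt, np.nan, info, genotyped)
            )
            columns.append(np.clip(ds, 0.0, 2.0))

    dosages = np.column_stack(columns) if columns else np.empty((n_samples, 0))
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    variants["maf"] = [
        compute_maf(dosages[:, j]) if np.any(~np.isnan(dosages[:, j])) else np.nan
        for j in range(dosages.shape[1])
    ]
    samples = pd.DataFrame({"sample_id": sample_ids})
    return StudyCohort(name or prefix.name, dosages, variants, samples)


def read_dosages(path: str | os.PathLike, format: str = "vcf",
                 name: str | None = None) -> StudyCohort:
    """Dispatch to :func:`read_vcf` or :func:`read_gen` by format name."""
    if format == "vcf":
        return read_vcf(path, name=name)
    if format == "gen":
        return read_gen(path, name=name)
    raise ValueError(f"unsupported dosage format {format!r}")


# ---------------------------------------------------------------------------
# BED gene intervals
# ---------------------------------------------------------------------------

def read_gene_intervals(path: str | os.PathLike) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open), returning them
    in 1-based inclusive coordinates: BED ``start end`` becomes
    ``[start + 1, end]``, so a variant at either printed boundary of the
    converted interval is inside the gene."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path} line {line_no}: need chrom/start/end/name"
                )
            chrom, start, end, gene = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {line_no}: non-integer coordinates"
                ) from exc
            if start_i >= end_i:
                raise ParseError(
                    f"{path} line {line_no}: start {start_i} >= end {end_i}"
                )
            intervals.append(
                GeneInterval(gene=gene, chrom=normalize_chrom(chrom),
                             start=start_i + 1, end=end_i)
            )
    return intervals


def write_bed(intervals: Iterable[GeneInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene}\n")


# ---------------------------------------------------------------------------
# Covariate / phenotype TSV
# ---------------------------------------------------------------------------

def categorize_education(years: float) -> float:
    """Years of schooling to the 4-level category used across studies:
    1 for <=4 years, 2 for 4-10, 3 for 10-15, 4 for >15 (upper bounds
    inclusive)."""
    if np.isnan(years):
        return np.nan
    if years <= 4:
        return 1.0
    if years <= 10:
        return 2.0
    if years <= 15:
        return 3.0
    return 4.0


REQUIRED_COVARIATE_COLUMNS = ("sample_id", "status", "age", "sex")


def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-sample covariate/phenotype TSV.

    Requires ``sample_id``, ``status``, ``age`` and ``sex``.  Education
    may come as the 1-4 category (``edu``) or as years (``edu_years``,
    converted on read); missing education is imputed to the study mean
    and the category is treated as continuous downstream.  ``PC*``,
    ``apoe_e4`` and ``apoe_e4_dosage`` columns pass through.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in REQUIRED_COVARIATE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if "edu_years" in df.columns and "edu" not in df.columns:
        df["edu"] = df["edu_years"].astype(float).map(categorize_education)
    if "edu" in df.columns:
        edu = df["edu"].astype(float)
        df["edu"] = edu.fillna(edu.mean())
    df["status"] = df["status"].astype(int)
    return df


def attach_covariates(cohort: StudyCohort, covariates: pd.DataFrame) -> StudyCohort:
    """Join a covariate table onto a dosage-only cohort by sample_id,
    preserving the dosage row order."""
    merged = cohort.samples[["sample_id"]].astype({"sample_id": str}).merge(
        covariates.astype({"sample_id": str}), on="sample_id", how="left",
        validate="one_to_one",
    )
    if merged["status"].isna().any():
        missing = merged.loc[merged["status"].isna(), "sample_id"].tolist()[:5]
        raise ParseError(f"covariates missing for samples {missing}")
    return StudyCohort(cohort.name, cohort.dosages, cohort.variants, merged)


RESULT_COLUMNS = ["study", "unit", "n_variants", "beta", "se", "z", "p", "direction"]


def write_results_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table with the fixed column order, keeping any
    extra columns after the canonical ones."""
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
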
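"""Two-stage gene scan orchestration.

Stage 1 collapses rare variants per gene in each study, fits the
covariate-adjusted burden regression, and combines the per-study Z
scores by sample-size-weighted meta-analysis against the Bonferroni
gene-level threshold.  Stage 2 takes a significant gene, runs the
classical per-SNP association and meta-analysis inside it, keeps SNPs
with meta P < 0.05, meta Z > 0 and per-study MAF in [0.5%, 3%], and
re-runs the gene-based test on the selected SNPs only (confirmatory,
in-sample — the same data as stage 1, not an independent replication).
A lookup helper pulls named candidate genes out of the stage-1 table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import (
    compute_maf,
    fit_gene_burden,
    fit_association,
    gene_dosage,
    prepare_covariates,
    select_rare_variants,
)
from .cohort import GeneInterval, StudyCohort, normalize_chrom
from .meta import MetaResult, effective_sample_size, genomewide_threshold, weighted_z_meta


def _study_n_effective(cohorts: Sequence[StudyCohort]) -> np.ndarray:
    return np.array(
        [effective_sample_size(c.n_cases, c.n_controls) for c in cohorts]
    )


def stage1_scan(
    cohorts: Sequence[StudyCohort],
    gene_intervals: Sequence[GeneInterval],
    maf_max: float = 0.03,
    maf_min: float = 0.0,
    info_min: float = 0.4,
    adjust_apoe: bool = False,
    n_genes_genome: int | None = None,
    alpha: float = 0.05,
    family: str = "logistic",
) -> pd.DataFrame:
    """Genome-wide gene-based scan: burden + meta for every interval.

    Returns one row per gene sorted by meta P (untestable genes last),
    with the per-study direction string and a significance flag at
    ``alpha / n_genes_genome`` (defaulting to the number of intervals
    scanned).  A gene with no qualifying variant in a study is ``?``
    there; a gene untestable everywhere keeps NaN meta columns.
    """
    if not cohorts:
        raise ValueError("need at least one study cohort")
    n_e = _study_n_effective(cohorts)
    per_study_sel = [
        select_rare_variants(c, gene_intervals, maf_max=maf_max,
                             maf_min=maf_min, info_min=info_min)
        for c in cohorts
    ]
    rows = []
    for iv in gene_intervals:
        z = np.full(len(cohorts), np.nan)
        betas = np.full(len(cohorts), np.nan)
        n_var_used: set[str] = set()
        for k, cohort in enumerate(cohorts):
            idx = per_study_sel[k][iv.gene]
            res = fit_gene_burden(cohort, idx, iv.gene,
                                  include_apoe=adjust_apoe, family=family)
            if res.estimable:
                z[k] = res.z
                betas[k] = res.beta
                n_var_used.update(
                    cohort.variants["id"].iloc[idx].tolist()
                )
        m = weighted_z_meta(z, n_e, unit=iv.gene)
        rows.append(
            {
                "gene": iv.gene,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "n_variants": len(n_var_used),
                "z_meta": m.z_meta,
                "p_meta": m.p_meta,
                "direction": m.direction,
                "n_studies": m.n_studies_used,
            }
        )
    table = pd.DataFrame(rows, columns=[
        "gene", "chrom", "start", "end", "n_variants", "z_meta", "p_meta",
        "direction", "n_studies",
    ])
    threshold = genomewide_threshold(n_genes_genome or max(len(gene_intervals), 1),
                                     alpha)
    table["significant"] = table["p_meta"] < threshold
    table.attrs["threshold"] = threshold
    table = table.sort_values(
        "p_meta", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    if not table["p_meta"].notna().any():
        import warnings

        warnings.warn("no gene was testable in any study")
    return table


@dataclass
class StageTwoSelection:
    """Per-SNP scan inside one gene plus the surviving risk-SNP set."""

    gene: str
    table: pd.DataFrame          # one row per SNP with meta stats + pass flags
    selected: list[str]          # SNP ids meeting all three criteria
    criteria: dict = field(default_factory=dict)


def select_risk_snps(
    cohorts: Sequence[StudyCohort],
    gene_interval: GeneInterval,
    maf_min: float = 0.005,
    maf_max: float = 0.03,
    info_min: float = 0.4,
    p_max: float = 0.05,
    adjust_apoe: bool = False,
) -> StageTwoSelection:
    """Classical per-SNP GWAS + meta inside one gene, then selection.

    A SNP is selected when meta P < ``p_max`` and meta Z > 0 (risk
    direction), with the MAF window applied per study: a SNP outside
    [0.5%, 3%] (or below INFO 0.4) in a study is ``?`` there and that
    study contributes nothing to its meta Z.
    """
    n_e = _study_n_effective(cohorts)
    snp_ids: list[str] = []
    seen = set()
    for c in cohorts:
        chrom = c.variants["chrom"].map(normalize_chrom)
        in_gene = (
            (chrom == normalize_chrom(gene_interval.chrom))
            & (c.variants["pos"] >= gene_interval.start)
            & (c.variants["pos"] <= gene_interval.end)
        )
        for vid in c.variants.loc[in_gene, "id"]:
            if vid not in seen:
                seen.add(vid)
                snp_ids.append(vid)

    rows = []
    for vid in snp_ids:
        z = np.full(len(cohorts), np.nan)
        per_study: dict[str, float] = {}
        for k, c in enumerate(cohorts):
            hit = np.flatnonzero((c.variants["id"] == vid).to_numpy())
            if hit.size == 0:
                continue
            j = int(hit[0])
            col = c.dosages[:, j]
            if not np.any(~np.isnan(col)):
                continue
            maf = compute_maf(col)
            info = float(c.variants["info"].iat[j])
            per_study[f"maf_{c.name}"] = maf
            per_study[f"info_{c.name}"] = info
            if not (maf_min <= maf <= maf_max and info >= info_min):
                continue
            cov = prepare_covariates(c.samples, include_apoe=adjust_apoe)
            res = fit_association(col, c.status, cov, study=c.name, gene=vid)
            per_study[f"beta_{c.name}"] = res.beta
            per_study[f"p_{c.name}"] = res.p
            if res.estimable:
                z[k] = res.z
        m = weighted_z_meta(z, n_e, unit=vid)
        passes = (
            m.testable and m.p_meta < p_max and m.z_meta > 0
        )
        rows.append(
            {
                "snp": vid,
                "z_meta": m.z_meta,
                "p_meta": m.p_meta,
                "direction": m.direction,
                "n_studies": m.n_studies_used,
                "selected": bool(passes),
                **per_study,
            }
        )
    table = pd.DataFrame(rows)
    selected = table.loc[table["selected"], "snp"].tolist() if len(table) else []
    return StageTwoSelection(
        gene=gene_interval.gene,
        table=table,
        selected=selected,
        criteria={"p_max": p_max, "z_sign": "positive",
                  "maf_min": maf_min, "maf_max": maf_max, "info_min": info_min},
    )


@dataclass
class StageTwoConfirmation:
    gene: str
    snp_ids: list[str]
    meta_unadjusted: MetaResult
    meta_adjusted: MetaResult | None
    per_study: pd.DataFrame


def stage2_confirm(
    cohorts: Sequence[StudyCohort],
    gene_interval: GeneInterval,
    snp_ids: Sequence[str],
    maf_min: float = 0.005,
    maf_max: float = 0.03,
    info_min: float = 0.4,
    with_apoe_adjusted: bool = True,
) -> StageTwoConfirmation:
    """Gene-based test restricted to the selected SNPs.

    Within each study the gene dosage averages the selected SNPs that
    pass that study's INFO and MAF windows; a study where none pass is
    ``?``.  Reports the unadjusted and (optionally) e4-adjusted
    meta-analysis plus a per-study table.
    """
    if not snp_ids:
        raise ValueError(f"gene {gene_interval.gene}: empty SNP selection")
    n_e = _study_n_effective(cohorts)
    z_un = np.full(len(cohorts), np.nan)
    z_ad = np.full(len(cohorts), np.nan)
    per_rows = []
    for k, c in enumerate(cohorts):
        idx = []
        for vid in snp_ids:
            hit = np.flatnonzero((c.variants["id"] == vid).to_numpy())
            if hit.size == 0:
                continue
            j = int(hit[0])
            col = c.dosages[:, j]
            if not np.any(~np.isnan(col)):
                continue
            maf = compute_maf(col)
            if maf_min <= maf <= maf_max and float(c.variants["info"].iat[j]) >= info_min:
                idx.append(j)
        row = {"study": c.name, "n_snps_used": len(idx)}
        if idx:
            res = fit_gene_burden(c, np.array(idx), gene_interval.gene)
            row.update(beta=res.beta, se=res.se, p=res.p)
            if res.estimable:
                z_un[k] = res.z
            if with_apoe_adjusted:
                res_a = fit_gene_burden(c, np.array(idx), gene_interval.gene,
                                        include_apoe=True)
                row.update(beta_apoe_adj=res_a.beta, p_apoe_adj=res_a.p)
                if res_a.estimable:
                    z_ad[k] = res_a.z
        per_rows.append(row)
    meta_un = weighted_z_meta(z_un, n_e, unit=gene_interval.gene)
    meta_ad = (
        weighted_z_meta(z_ad, n_e, unit=gene_interval.gene)
        if with_apoe_adjusted else None
    )
    return StageTwoConfirmation(
        gene=gene_interval.gene,
        snp_ids=list(snp_ids),
        meta_unadjusted=meta_un,
        meta_adjusted=meta_ad,
        per_study=pd.DataFrame(per_rows),
    )


def candidate_gene_lookup(
    stage1_table: pd.DataFrame, genes: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Rows of the stage-1 table for the requested symbols, in request
    order, plus the list of symbols absent from the scan."""
    by_gene = stage1_table.set_index("gene")
    found = [g for g in genes if g in by_gene.index]
    not_found = [g for g in genes if g not in by_gene.index]
    sub = by_gene.loc[found].reset_index() if found else stage1_table.iloc[0:0].copy()
    return sub, not_found


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_all(
    config,
    outdir: str | Path,
    candidate_genes: Sequence[str] | None = None,
    apply_qc: bool = True,
) -> dict:
    """Simulate, QC, scan, condition, confirm; write the report TSVs.

    Returns a summary dict (also written as ``run_log.json``).
    """
    from .conditional import adjusted_scan, conditional_frame
    from .qc import QcThresholds, apply_variant_qc
    from .simulate import simulate_cohorts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_cohorts(config)
    cohorts = data.cohorts

    qc_frames = []
    if apply_qc:
        filtered = []
        for c in cohorts:
            fc, report = apply_variant_qc(c, QcThresholds())
            report.insert(0, "study", c.name)
            qc_frames.append(report)
            filtered.append(fc)
        cohorts = filtered
        pd.concat(qc_frames, ignore_index=True).to_csv(
            outdir / "qc_report.tsv", sep="\t", index=False
        )

    stage1 = stage1_scan(cohorts, data.intervals)
    stage1.to_csv(outdir / "stage1_genes.tsv", sep="\t", index=False,
                  float_format="%.6g")
    threshold = stage1.attrs["threshold"]

    top = stage1.head(7)["gene"].tolist()
    top_ivs = [iv for iv in data.intervals if iv.gene in top]
    reports = adjusted_scan(cohorts, top_ivs)
    conditional_frame(reports).to_csv(
        outdir / "conditional_report.tsv", sep="\t", index=False, float_format="%.6g"
    )

    significant = stage1.loc[stage1["significant"], "gene"].tolist()
    stage2_rows, confirm_rows = [], []
    for gene in significant:
        iv = next(iv for iv in data.intervals if iv.gene == gene)
        sel = select_risk_snps(cohorts, iv)
        t = sel.table.copy()
        t.insert(0, "gene", gene)
        stage2_rows.append(t)
        if sel.selected:
            conf = stage2_confirm(cohorts, iv, sel.selected)
            row = {
                "gene": gene,
                "n_snps_selected": len(sel.selected),
                "snps": ",".join(sel.selected),
                "z_meta": conf.meta_unadjusted.z_meta,
                "p_meta": conf.meta_unadjusted.p_meta,
                "direction": conf.meta_unadjusted.direction,
            }
            if conf.meta_adjusted is not None:
                row["z_meta_apoe_adj"] = conf.meta_adjusted.z_meta
                row["p_meta_apoe_adj"] = conf.meta_adjusted.p_meta
            confirm_rows.append(row)
    (pd.concat(stage2_rows, ignore_index=True) if stage2_rows
     else pd.DataFrame()).to_csv(outdir / "stage2_selection.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    pd.DataFrame(confirm_rows).to_csv(outdir / "stage2_confirm.tsv", sep="\t",
                                      index=False, float_format="%.6g")

    if candidate_genes:
        sub, not_found = candidate_gene_lookup(stage1, candidate_genes)
        sub.to_csv(outdir / "candidate_lookup.tsv", sep="\t", index=False,
                   float_format="%.6g")
    else:
        not_found = []

    log = {
        "seed": config.seed,
        "n_studies": len(cohorts),
        "study_sizes": {c.name: [c.n_cases, c.n_controls] for c in cohorts},
        "n_genes": len(data.intervals),
        "genomewide_threshold": threshold,
        "significant_genes": significant,
        "stage2_confirmed": [r["gene"] for r in confirm_rows],
        "candidate_not_found": not_found,
        "maf_max": 0.03,
        "info_min": 0.4,
        "stage2_maf_window": [0.005, 0.03],
        "note": "stage-2 P values are confirmatory in-sample, not independent replication",
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
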
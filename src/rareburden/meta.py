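"""Sample-size weighted Z-score fixed-effects meta-analysis.

Per-study association results are combined Stouffer-style with weights
``w_i = sqrt(N_E,i)`` where the effective sample size of a case-control
study is the harmonic combination

    N_E = 4 / (1/N_cases + 1/N_controls),

the convention of METAL's sample-size scheme.  The combined statistic is

    Z_meta = sum_i w_i Z_i / sqrt(sum_i w_i^2)

with a two-sided P value.  Studies where a unit (gene or SNP) is
untestable — no qualifying variants, or a non-estimable regression —
carry zero weight and appear as ``?`` in the per-study direction string;
``+`` and ``-`` record the sign of each study's Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetaResult:
    """Combined association result for one gene or SNP."""

    unit: str
    z_meta: float
    p_meta: float
    direction: str
    weights: np.ndarray
    n_studies_used: int

    @property
    def testable(self) -> bool:
        return self.n_studies_used > 0


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Effective sample size ``4 / (1/n_cases + 1/n_controls)``.

    Equals ``2 N`` for a balanced study of ``N`` cases and ``N`` controls
    and is symmetric in the two counts.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError(
            f"case/control counts must be positive, got ({n_cases}, {n_controls})"
        )
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def weighted_z_meta(
    z: Sequence[float],
    n_effective: Sequence[float],
    unit: str = "",
) -> MetaResult:
    """Combine per-study Z statistics with ``sqrt(N_E)`` weights.

    Parameters
    ----------
    z : per-study Z scores; ``NaN`` marks a study where the unit is
        untestable (excluded, ``?`` in the direction string).
    n_effective : per-study effective sample sizes, same length.
    """
    z = np.asarray(z, dtype=float)
    n_e = np.asarray(n_effective, dtype=float)
    if z.shape != n_e.shape:
        raise ValueError("z and n_effective must have the same length")
    avail = np.isfinite(z)
    if np.any(n_e[avail] <= 0):
        raise ValueError("effective sample sizes must be positive")
    direction = "".join(
        "?" if not a else ("+" if zi > 0 else "-") for a, zi in zip(avail, z)
    )
    weights = np.where(avail, np.sqrt(np.where(avail, n_e, 1.0)), 0.0)
    if not np.any(avail):
        return MetaResult(unit, np.nan, np.nan, direction, weights, 0)
    z_meta = float(np.sum(weights[avail] * z[avail]) / np.sqrt(np.sum(weights[avail] ** 2)))
    p_meta = z_to_p(z_meta)
    return MetaResult(unit, z_meta, p_meta, direction, weights, int(avail.sum()))


def z_to_p(z: float) -> float:
    """Two-sided normal P value for a Z statistic."""
    return float(2.0 * stats.norm.sf(abs(z)))


def genomewide_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni gene-level significance threshold ``alpha / n_genes``.

    With the 28,517 genes of the hg19 gene set this is 1.8e-6 at two
    significant figures.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Genomic inflation factor lambda_GC from a set of P values.

    The median of the implied 1-df chi-square statistics divided by the
    null median (~0.4549).  Lambda near 1 indicates calibrated tests;
    lambda substantially above 1 indicates inflated type-I error of the
    kind that motivates per-study stratification adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("need at least 10 P values to estimate inflation")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))


def forest_table(
    result: MetaResult,
    study_names: Sequence[str],
    z: Sequence[float],
    n_cases: Sequence[int],
    n_controls: Sequence[int],
) -> pd.DataFrame:
    """Plain-text forest-plot equivalent: per-study Z, N_E weight, direction."""
    z = np.asarray(z, dtype=float)
    n_e = [
        effective_sample_size(a, c) if np.isfinite(zi) else np.nan
        for a, c, zi in zip(n_cases, n_controls, z)
    ]
    rows = pd.DataFrame(
        {
            "study": list(study_names),
            "n_cases": list(n_cases),
            "n_controls": list(n_controls),
            "n_effective": n_e,
            "weight": result.weights,
            "z": z,
            "direction": list(result.direction),
        }
    )
    meta_row = pd.DataFrame(
        {
            "study": ["META"],
            "n_cases": [sum(n_cases)],
            "n_controls": [sum(n_controls)],
            "n_effective": [float(np.nansum(n_e))],
            "weight": [np.nan],
            "z": [result.z_meta],
            "direction": [""],
        }
    )
    return pd.concat([rows, meta_row], ignore_index=True)
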
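"""Shared fixtures: small seeded synthetic datasets reused across tests."""

import numpy as np
import pandas as pd
import pytest

from rareburden.cohort import StudyCohort, VARIANT_COLUMNS
from rareburden.simulate import (
    CovariateEffects,
    SimulationConfig,
    StudySpec,
    simulate_cohorts,
)


def make_cohort(dosages, positions=None, name="toy", status=None, info=1.0,
                genotyped=False, chrom="1", extra_samples=None):
    """Hand-build a StudyCohort from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n_s, n_v = dosages.shape
    positions = positions if positions is not None else (np.arange(n_v) + 1) * 10
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(n_v)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "C",
            "maf": np.nan,
            "info": info,
            "genotyped": genotyped,
        }
    )[VARIANT_COLUMNS]
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n_s)]})
    if status is not None:
        samples["status"] = status
    if extra_samples:
        for k, v in extra_samples.items():
            samples[k] = v
    return StudyCohort(name, dosages, variants, samples)


@pytest.fixture(scope="session")
def two_study_data():
    """Two balanced studies with one causal gene and one e4-LD gene.

    Large enough for the causal signal to dominate the scan while the
    LD gene's marginal signal comes only through the e4 confounder.
    """
    cfg = SimulationConfig(
        studies=(StudySpec("A", 1200, 1200), StudySpec("B", 1500, 1500)),
        n_genes=15,
        variants_per_gene=(3, 5),
        maf_range=(0.01, 0.025),
        causal_log_or={"GENE0003": float(np.log(4.0))},
        confounder_ld_gene="GENE0007",
        imputation_error=0.02,
        seed=20240,
    )
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def null_small_data():
    """One small study with no genetic or covariate effects."""
    cfg = SimulationConfig(
        studies=(StudySpec("null", 300, 300),),
        n_genes=10,
        variants_per_gene=(2, 4),
        confounder_log_or=0.0,
        covariate_effects=CovariateEffects(0.0, 0.0, 0.0, 0.0),
        imputation_error=0.0,
        edu_missing_rate=0.0,
        baseline_prevalence_logit=0.0,
        seed=77,
    )
    return simulate_cohorts(cfg)
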
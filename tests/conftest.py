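import numpy as np
import pandas as pd
import pytest

from prsgxe.prs import assign_quartiles, compute_prs
from prsgxe.simulate import (
    SimConfig,
    sample_case_control,
    simulate_population,
    weight_table_from_truth,
)


def analysis_frame(config: SimConfig, n_cases=None, n_controls=None, basis="controls"):
    """Simulate, sample, score and categorize: the frame the models consume."""
    genotypes, phenotypes, truth = simulate_population(config)
    if n_cases is not None:
        genotypes, phenotypes = sample_case_control(
            genotypes, phenotypes, n_cases, n_controls, config.seed)
    prs = compute_prs(genotypes, weight_table_from_truth(truth))
    data = phenotypes.copy()
    data["prs"] = prs
    data["prs_q"] = assign_quartiles(prs, phenotypes["case_status"], basis=basis)
    return data, truth


@pytest.fixture(scope="session")
def medium_cc():
    """Case-control sample of 3,000/4,500 from a 20,000-person population
    simulated under the default (Table-like) cell truths."""
    config = SimConfig(n_population=20_000, n_cases=3_000, n_controls=4_500, seed=11)
    return analysis_frame(config, 3_000, 4_500)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def toy_weights():
    return pd.DataFrame({
        "variant_id": ["v1", "v2", "v3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 200, 300],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "T"],
        "weight": [0.1, -0.2, 0.05],
    })
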
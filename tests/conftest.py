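"""Shared fixtures: small simulated cohorts built at test time."""

import numpy as np
import pandas as pd
import pytest

from scdeqtl import SimulationConfig, simulate_cohort
from scdeqtl.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with planted local/distal eSNPs and interactions."""
    cfg = SimulationConfig(
        n_snps=400,
        n_probes=80,
        n_local_esnps=6,
        n_distal_esnps=2,
        n_interaction_effects=2,
        interaction_delta=0.8,
        sibling_fraction=0.5,
        seed=7,
    )
    g, e, meta, truth = simulate_cohort(cfg)
    return cfg, g, e, meta, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects of any kind: expression is covariates + noise only."""
    cfg = SimulationConfig(
        n_snps=300,
        n_probes=60,
        n_local_esnps=0,
        n_distal_esnps=0,
        clinstatus_effect_sd=0.0,
        hb_effect_sd=0.0,
        sex_effect_sd=0.0,
        wbc_slope_sd=0.0,
        rbc_slope_sd=0.0,
        de_fraction=0.0,
        seed=19,
    )
    g, e, meta, truth = simulate_cohort(cfg)
    return cfg, g, e, meta, truth


def make_expression(values, sample_ids=None, chrom="1"):
    """Wrap a plain array as an ExpressionMatrix with stub annotation."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n)]
    probes = pd.DataFrame(
        {"gene_symbol": [f"G{i}" for i in range(p)], "chrom": chrom, "pos": 1},
        index=pd.Index([f"p{i + 1}" for i in range(p)], name="probe_id"),
    )
    return ExpressionMatrix(probes=probes, sample_ids=sample_ids, values=values)
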
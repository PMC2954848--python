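import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import globinbench as gb

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profiles():
    return gb.default_profiles()


@pytest.fixture(scope="session")
def cdna_design():
    return gb.default_design(1, protocols=("cdna",))


@pytest.fixture(scope="session")
def cdna_sim(profiles, cdna_design):
    """A moderate cdna-profile simulation shared by read-only tests."""
    expr, truth = gb.generate_expression(cdna_design, profiles["cdna"],
                                         4000, seed=11)
    return expr, truth


def make_expression(values, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return gb.ExpressionMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])])


def make_signature(gene_ids, directions, p_values=None, log_ratios=None):
    data = {"gene_id": list(gene_ids), "direction": list(directions)}
    if p_values is not None:
        data["p_value"] = list(p_values)
    if log_ratios is not None:
        data["log_ratio"] = list(log_ratios)
    return pd.DataFrame(data)
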
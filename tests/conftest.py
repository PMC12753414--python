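import numpy as np
import pandas as pd
import pytest

from cqindex import (
    PanelConfig,
    compute_dcq,
    compute_fold_change,
    preset,
    simulate_cq_table,
)


def make_cq_table(rows):
    """Build a Cq table from (treatment, div, replicate, gene, cq) tuples."""
    df = pd.DataFrame(rows, columns=["treatment", "div", "replicate", "gene", "cq"])
    df.insert(0, "organoid_type", "VCO")
    df.insert(
        0,
        "sample_id",
        [f"VCO_{t}_d{d}_r{r}" for t, d, r in zip(df["treatment"], df["div"], df["replicate"])],
    )
    return df


def make_expr_table(rows, value_kind="fold_change"):
    """Build an expression table from (treatment, div, replicate, gene, value)."""
    df = pd.DataFrame(rows, columns=["treatment", "div", "replicate", "gene", "value"])
    df.insert(0, "organoid_type", "VCO")
    df.insert(
        0,
        "sample_id",
        [f"VCO_{t}_d{d}_r{r}" for t, d, r in zip(df["treatment"], df["div"], df["replicate"])],
    )
    df["value_kind"] = value_kind
    return df


@pytest.fixture(scope="session")
def null_truth():
    return preset("null", seed=0)


@pytest.fixture(scope="session")
def delay_truth_noiseless():
    return preset("withdrawal_delay", seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def panel_config(null_truth):
    return PanelConfig(genes=tuple(null_truth.genes))


@pytest.fixture(scope="session")
def noiseless_fc(delay_truth_noiseless, panel_config):
    table = simulate_cq_table(delay_truth_noiseless)
    return compute_fold_change(compute_dcq(table, panel_config), panel_config)


@pytest.fixture(scope="session")
def noisy_fc(null_truth, panel_config):
    table = simulate_cq_table(null_truth)
    return compute_fold_change(compute_dcq(table, panel_config), panel_config)
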
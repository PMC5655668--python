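import numpy as np
import pandas as pd
import pytest

from isopharm import (
    ExpressionDataset,
    PlantedEffect,
    SensitivityTable,
    SimulationConfig,
    simulate_expression,
    simulate_sensitivity,
)


@pytest.fixture(scope="session")
def null_config():
    """Small all-null study: no planted effects, pure tissue + noise AAC."""
    return SimulationConfig(
        n_cell_lines=80, n_tissues=4, n_genes=30, isoforms_per_gene=3, noise_sd=0.3, seed=11
    )


@pytest.fixture(scope="session")
def planted_config():
    """One isoform-specific and one gene-level planted effect."""
    return SimulationConfig(
        n_cell_lines=100,
        n_tissues=4,
        n_genes=40,
        isoforms_per_gene=3,
        noise_sd=0.3,
        seed=5,
        planted_effects=[
            PlantedEffect("g0000.t0", 0.8, "isoform_specific"),
            PlantedEffect("g0001", 0.8, "gene_level"),
        ],
    )


@pytest.fixture(scope="session")
def planted_data(planted_config):
    expr = simulate_expression(planted_config)
    sens = {
        s: simulate_sensitivity(expr, planted_config, s) for s in ("study_1", "study_2")
    }
    return expr, sens


def tiny_expression(values, tissues=None):
    """Build a minimal single-gene ExpressionDataset from an isoform matrix dict."""
    iso = pd.DataFrame(values)
    iso.index = [f"g0.t{i}" for i in range(len(iso))]
    iso.columns = [f"cl{i}" for i in range(iso.shape[1])]
    imap = pd.Series("g0", index=iso.index, name="gene_id")
    from isopharm import aggregate_isoforms

    genes = aggregate_isoforms(iso, imap)
    t = pd.Series(tissues or ["t0"] * iso.shape[1], index=iso.columns, name="tissue")
    return ExpressionDataset(isoforms=iso, genes=genes, isoform_map=imap, tissues=t)
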
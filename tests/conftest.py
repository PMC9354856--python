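import numpy as np
import pandas as pd
import pytest

from raidkit.data_model import DescriptorTable
from raidkit.model_bank import BankConfig, train_bank
from raidkit.preprocess import (
    AdjustmentContext,
    adjust_matrix,
    compute_fold_change,
    curate_descriptors,
    filter_genes,
    normalize_descriptors,
)
from raidkit.synthetic_data import SimulationConfig, generate, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


def preprocess_study(sim):
    """Replicates -> adjusted fold changes (cross-source all-Absent rule on)."""
    fc_vivo = compute_fold_change(sim.invivo)
    fc_vitro = compute_fold_change(sim.invitro)
    adj_vivo = adjust_matrix(
        fc_vivo, AdjustmentContext.for_source("in_vivo"), fc_vitro.all_absent
    )
    adj_vitro = adjust_matrix(
        fc_vitro, AdjustmentContext.for_source("in_vitro"), fc_vivo.all_absent
    )
    return adj_vivo, adj_vitro


def train_study_bank(sim, bank_config=None, substances=None):
    """Full preprocessing + bank training on (a subset of) a simulated study.

    Gene filtering and the descriptor pipeline are fitted on the training
    substances only, so held-out substances see the replayed pipeline exactly
    as external substances would.
    """
    adj_vivo, adj_vitro = preprocess_study(sim)
    adj_vivo_train, adj_vitro_train = adj_vivo, adj_vitro
    raw_desc = sim.descriptors
    if substances is not None:
        adj_vivo_train = adj_vivo.subset(substances)
        adj_vitro_train = adj_vitro.subset(substances)
        raw_desc = sim.descriptors.subset(substances)
    retained = filter_genes(adj_vivo_train)
    desc = normalize_descriptors(curate_descriptors(raw_desc))
    config = bank_config or BankConfig(seed=sim.config.seed)
    bank = train_bank(adj_vivo_train, adj_vitro_train, desc, retained, config)
    return bank, adj_vivo, adj_vitro, retained


@pytest.fixture(scope="session")
def small_sim():
    """A fast small study for unit-level checks (no bank training here)."""
    return generate(
        SimulationConfig(
            n_substances=30,
            n_test_substances=0,
            n_genes=6,
            n_descriptors=8,
            n_invitro_driven_genes=2,
            seed=11,
        )
    )


SMALL_BANK_CONFIG = BankConfig(
    alpha_grid=(0.0, 0.5, 1.0), lambda_path_length=30, seed=11
)
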
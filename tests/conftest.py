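import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chromarch.contacts import ContactMap, balance
from chromarch.synthetic import SimConfig, make_genome, simulate_contacts

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return make_genome(default_config)


@pytest.fixture(scope="session")
def balanced_40kb(default_truth, default_config):
    """Balanced 40-kb map for condition a at the default study conditions."""
    return balance(simulate_contacts(default_truth, default_config, "a"))


@pytest.fixture(scope="session")
def balanced_100kb_pair(default_truth, default_config):
    cfg = default_config.at_resolution(100_000)
    return {
        cond: balance(simulate_contacts(default_truth, cfg, cond))
        for cond in ("a", "b")
    }


@pytest.fixture(scope="session")
def loop_depth_config() -> SimConfig:
    """20-kb loop-calling conditions at depth adequate for punctate calls."""
    return dataclasses.replace(
        SimConfig(seed=1), bin_size_bp=20_000, sequencing_depth=3e7
    )


def toy_contact_map(matrix: np.ndarray, resolution: int = 10_000) -> ContactMap:
    """Wrap a dense symmetric array as an unbalanced single-chromosome map."""
    n = matrix.shape[0]
    return ContactMap(
        resolution=resolution,
        chromsizes={"chr1": n * resolution},
        counts={"chr1": np.asarray(matrix)},
    )


def prebalanced(matrix: np.ndarray, resolution: int = 10_000) -> ContactMap:
    """Wrap a dense array as a map with unit weights (balanced view == raw)."""
    cmap = toy_contact_map(matrix, resolution)
    cmap.weights = {"chr1": np.ones(matrix.shape[0])}
    return cmap


def regions(chrom, *spans) -> pd.DataFrame:
    return pd.DataFrame(
        [(chrom, s, e) for s, e in spans], columns=["chrom", "start", "end"]
    )
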
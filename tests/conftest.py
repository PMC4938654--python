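import numpy as np
import pandas as pd
import pytest

from bsamap.config import SimConfig, demo_config
from bsamap.io import marker_table_to_raw
from bsamap.markers import prepare_markers
from bsamap.simulate import simulate_experiment


@pytest.fixture(scope="session")
def demo_cfg() -> SimConfig:
    return demo_config(seed=7)


@pytest.fixture(scope="session")
def demo_experiment(demo_cfg):
    """One simulated demo-scale experiment shared across read-only tests."""
    return simulate_experiment(demo_cfg)


@pytest.fixture(scope="session")
def demo_selected(demo_experiment):
    _, _, table = demo_experiment
    selected, tallies = prepare_markers(marker_table_to_raw(table.markers))
    return selected, tallies


def random_marker_table(rng: np.random.Generator, n: int, n_chroms: int = 2,
                        span: int = 10_000_000) -> pd.DataFrame:
    """Random oriented marker table with positive pool depths, for oracles."""
    chroms = np.sort(rng.integers(1, n_chroms + 1, size=n))
    pos = np.sort(rng.integers(1, span, size=n))
    order = np.lexsort((pos, chroms))
    depth_m = rng.integers(1, 40, size=n)
    depth_n = rng.integers(1, 40, size=n)
    m1 = rng.binomial(depth_m, rng.uniform(0, 1, size=n))
    n1 = rng.binomial(depth_n, rng.uniform(0, 1, size=n))
    return pd.DataFrame({
        "chrom": [f"chr{c}" for c in chroms[order]],
        "pos": pos[order],
        "m1": m1[order], "m2": (depth_m - m1)[order],
        "n1": n1[order], "n2": (depth_n - n1)[order],
    })
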
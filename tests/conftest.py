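from pathlib import Path

import pytest
from hypothesis import settings

import ripesync as rs

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_expr():
    """Study-condition expression simulation (2000 genes, one tissue)."""
    return rs.simulate_expression(rs.SimConfig(seed=1, n_genes=2000))


@pytest.fixture(scope="session")
def small_expr():
    """Small expression simulation for structural tests."""
    return rs.simulate_expression(rs.SimConfig(seed=11, n_genes=200))


@pytest.fixture(scope="session")
def null_expr():
    """No véraison effects, no synchronization: complete null."""
    return rs.simulate_expression(
        rs.SimConfig(seed=2, n_genes=2000, effect_sd_v=0.0, rv_fold_target=1.0)
    )


@pytest.fixture(scope="session")
def default_phys():
    """Study-condition physiology simulation (4 classes, 6 weeks)."""
    return rs.simulate_physiology(rs.SimConfig(seed=1))


@pytest.fixture(scope="session")
def phys_kinetics(default_phys):
    """Physiology table with colour index plus its reference stages."""
    table = rs.add_colour_index(default_phys)
    stages = rs.define_reference_stages(table)
    return table, stages
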
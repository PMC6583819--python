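import numpy as np
import pytest

import smallcounts as sc


@pytest.fixture
def tiny_table() -> sc.CountTable:
    """Two states, four areas, two age groups; counts straddle threshold 10."""
    areas = ("A", "B", "C", "D")
    state_of = {"A": "S1", "B": "S1", "C": "S2", "D": "S2"}
    ages = ("35-44", "45-54")
    y = np.array([[3, 12], [0, 25], [9, 10], [5, 40]])
    n = np.array([[1000, 900], [500, 1200], [800, 700], [2000, 2500]])
    return sc.CountTable(areas, state_of, ages, y, n)


@pytest.fixture
def tiny_censored(tiny_table) -> sc.CensoredCountTable:
    return sc.apply_suppression(tiny_table, threshold=10)


@pytest.fixture(scope="session")
def small_study() -> sc.StudyBundle:
    """6x6 lattice study reused by cheaper model tests."""
    cfg = sc.SimConfig(nrow=6, ncol=6, seed=42)
    return sc.default_study(seed=42, config=cfg)
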
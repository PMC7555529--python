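"""Shared fixtures: a reduced panel for fast simulation and common objects.

The reduced panel keeps the full chromosome complement (22 autosomes, X, Y,
MT) at roughly a quarter of the default density — still far above every
caller's minimum-locus guard, so calls behave as at full density while
whole-cohort simulations stay fast.
"""

from pathlib import Path

import pytest

from molekaryo import (default_genetic_map, default_panel, default_str_panel,
                       simulate_parents)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_panel():
    return default_panel(n_autosomal=5000, n_x=250, n_y=60, n_mt=208, seed=11)


@pytest.fixture(scope="session")
def str_panel():
    return default_str_panel()


@pytest.fixture(scope="session")
def genetic_map():
    return default_genetic_map()


@pytest.fixture(scope="session")
def parents(small_panel, str_panel):
    return simulate_parents(small_panel, seed=101, str_panel=str_panel)


@pytest.fixture
def worked_example_path():
    return DATA_DIR / "worked_example_duo.tsv"
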
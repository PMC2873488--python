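"""Shared fixtures: a small designed array reused across the suite.

The synthetic study system is ten divergent 16S-like groups with one
designed probe pair each, addressed to a 47-ZipCode, 208-spot subarray
layout.  Designing probes is the slow step, so the designed set is
session-scoped.
"""

from pathlib import Path

import pytest

from ldrua.array import assign_zipcodes, build_layout, default_zipcode_pool
from ldrua.datasets import (
    design_synthetic_probe_set,
    group_templates,
    synthetic_group_alignments,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_groups():
    return synthetic_group_alignments(n_groups=10, members=4, length=240, seed=1)


@pytest.fixture(scope="session")
def probe_set(toy_groups):
    ps = design_synthetic_probe_set(toy_groups)
    assert not ps.failures, f"synthetic design failed: {ps.failures}"
    return ps


@pytest.fixture(scope="session")
def templates(toy_groups):
    return group_templates(toy_groups)


@pytest.fixture(scope="session")
def zip_pool():
    return default_zipcode_pool(47)


@pytest.fixture(scope="session")
def assignment(probe_set, zip_pool):
    return assign_zipcodes(probe_set, zip_pool)


@pytest.fixture(scope="session")
def subarray_layout(zip_pool, assignment):
    """Single-subarray layout (one hybridization)."""
    return build_layout(zip_pool, n_subarrays=1, assigned_zip_ids=list(assignment.values()))


@pytest.fixture(scope="session")
def slide_layout(zip_pool, assignment):
    """Full 8-subarray slide."""
    return build_layout(zip_pool, n_subarrays=8, assigned_zip_ids=list(assignment.values()))


@pytest.fixture()
def benchmark_table():
    import pandas as pd

    return pd.read_csv(DATA_DIR / "specificity_snr_benchmark.tsv", sep="\t")
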
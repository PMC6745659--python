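"""Shared fixtures: seeded RNGs and cached scenario ensembles.

The ensemble fixtures are session-scoped because several acceptance and
property tests read different aspects of the same ensembles (probabilities,
failure years, ratios, orderings); running each ensemble once keeps the
suite inside a sensible wall-clock budget. Replicate counts are scaled to a
single CPU; the tolerances used by the tests account for the Monte-Carlo
error at these sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhizoweed.engine import run_ensemble
from rhizoweed.scenarios import build_scenario


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def _ensemble(sid: str, n: int, seed: int, collect: bool = False):
    cfg = build_scenario(sid)
    return run_ensemble(cfg, n_replicates=n, base_seed=seed, collect=collect)


@pytest.fixture(scope="session")
def ens_t1():
    """Glyphosate-solo scenario, 400 replicates."""
    return _ensemble("T1", 400, 106)


@pytest.fixture(scope="session")
def ens_t2():
    """ACCase-solo scenario at allele frequency 1e-7, 500 replicates."""
    return _ensemble("T2", 500, 107)


@pytest.fixture(scope="session")
def ens_t3():
    """South dual-herbicide scenario at q=1e-7 (stats, replicates)."""
    return _ensemble("T3", 300, 108, collect=True)


@pytest.fixture(scope="session")
def ens_t4():
    """North dual-herbicide scenario at q=1e-7 (stats, replicates)."""
    return _ensemble("T4", 300, 109, collect=True)


@pytest.fixture(scope="session")
def ens_t5():
    """Baseline scenario, 500 replicates (stats, replicates)."""
    return _ensemble("T5", 500, 101, collect=True)


@pytest.fixture(scope="session")
def ens_t7():
    """Maximal fitness-cost variant, 400 replicates."""
    return _ensemble("T7", 400, 105)


@pytest.fixture(scope="session")
def ens_t8():
    """No-fitness-cost variant, 400 replicates (stats, replicates)."""
    return _ensemble("T8", 400, 103, collect=True)


@pytest.fixture(scope="session")
def ens_t9():
    """Tillage variant, 400 replicates."""
    return _ensemble("T9", 400, 104)
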
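from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dbdrescue.simulate import SimConfig, make_cohort


@pytest.fixture(scope="session")
def yeast_cohort():
    """Intronless strain-like cohort at the observed error spectrum."""
    return make_cohort(SimConfig.yeast_defaults(seed=11, n_genes=200))


@pytest.fixture(scope="session")
def pan_fungal_cohort():
    """Recovery cohort: MHD-only annotations, DBD within the upstream
    window, panel homologs at ~70% identity."""
    return make_cohort(SimConfig.pan_fungal_defaults(seed=12, n_genes=200))


@pytest.fixture(scope="session")
def null_cohort():
    """Negative-control cohort with no DBD anywhere in the genome."""
    return make_cohort(SimConfig.null_defaults(seed=13, n_genes=200))


@pytest.fixture(scope="session")
def small_recovery_cohort():
    return make_cohort(SimConfig.pan_fungal_defaults(seed=21, n_genes=12))
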
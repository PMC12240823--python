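"""Shared fixtures: small synthetic cohorts and grids, generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from petnorm import (
    GeneratorSpec,
    default_grid,
    generate_cohort,
    make_brain_mask,
    make_toy_atlas,
)


@pytest.fixture(scope="session")
def grid16():
    return default_grid((16, 16, 16))


@pytest.fixture(scope="session")
def mask16(grid16):
    return make_brain_mask(grid16)


@pytest.fixture(scope="session")
def atlas16(grid16):
    return make_toy_atlas(grid16)


@pytest.fixture(scope="session")
def hc_cohort():
    """Two-scanner reference cohort (HC only), desk scale."""
    spec = GeneratorSpec(
        n_subjects={("scannerA", "HC"): 30, ("scannerB", "HC"): 20}, seed=11
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Reference plus FEP and chronic patients on shared scanners."""
    spec = GeneratorSpec(
        n_subjects={
            ("scannerA", "HC"): 30,
            ("scannerB", "HC"): 20,
            ("scannerA", "FEP"): 18,
            ("scannerB", "SCZ"): 18,
        },
        seed=21,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_cohort_table(n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "age": rng.uniform(20, 65, n),
            "sex": rng.integers(0, 2, n),
        }
    )
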
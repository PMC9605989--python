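import numpy as np
import pytest

from dcgs import GenotypeMatrix, SyntheticConfig, simulate_families


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 1, 2, 0, 0],
            [2, 0, 0, 1, 1],
            [0, 2, 1, 0, 2],
            [1, 0, 2, 1, 0],
        ]
    )
    return GenotypeMatrix(
        [f"ind{i}" for i in range(1, 6)], [f"m{j}" for j in range(1, 6)], calls
    )


@pytest.fixture(scope="session")
def tiny_panel():
    """Two divergent families with family-specific QTLs, small enough for
    fast end-to-end tests."""
    cfg = SyntheticConfig(
        n_families=2,
        family_sizes=(40, 60),
        n_markers=300,
        n_qtl_per_family=10,
        qtl_overlap=0.0,
        h2=0.8,
        family_divergence=2.0,
        seed=11,
    )
    return simulate_families(cfg)
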
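import numpy as np
import pytest

from summr import SummarySet


@pytest.fixture
def toy5() -> SummarySet:
    """Five hand-written variants with heterogeneous precisions."""
    return SummarySet.from_arrays(
        beta_exposure=[0.10, 0.08, -0.12, 0.15, 0.06],
        se_exposure=[0.010, 0.012, 0.011, 0.009, 0.015],
        beta_outcome=[0.050, 0.041, -0.055, 0.080, 0.024],
        se_outcome=[0.010, 0.015, 0.012, 0.008, 0.020],
        variant_ids=["rs1", "rs2", "rs3", "rs4", "rs5"],
    )


@pytest.fixture
def random_set():
    """Factory: a random well-conditioned SummarySet of a given size."""

    def make(n: int, seed: int) -> SummarySet:
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
        sx = rng.uniform(0.005, 0.02, n)
        by = rng.normal(0.1 * bx, 0.01)
        sy = rng.uniform(0.005, 0.02, n)
        return SummarySet.from_arrays(bx, sx, by, sy)

    return make
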
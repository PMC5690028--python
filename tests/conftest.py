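import numpy as np
import pytest

from emmcup.basis import build_polynomial_basis
from emmcup.core import (
    BiasCoefficients,
    CorrectionState,
    ImageGrid,
    MembershipMap,
    TissueMeans,
    evaluate_energy,
    update_membership,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_instance(rng, shape=(8, 8), n_tissues=2, degree=1, mask_fraction=1.0):
    """A random grid + basis + consistent state for oracle comparisons."""
    data = rng.uniform(0.0, 1.0, shape)
    if mask_fraction >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = rng.uniform(size=shape) < mask_fraction
        mask.flat[:: max(1, mask.size // 4)] = True  # keep it well populated
    grid = ImageGrid.from_array(data, mask=mask)
    basis = build_polynomial_basis(grid, degree)
    means = TissueMeans(np.sort(rng.uniform(0.0, 1.0, n_tissues)))
    coeffs = BiasCoefficients(rng.normal(0.0, 0.1, basis.count))
    membership = update_membership(grid, basis, means, coeffs)
    state = CorrectionState(membership=membership, means=means, coefficients=coeffs)
    state.energy_trace.append(evaluate_energy(grid, basis, state))
    return grid, basis, state


@pytest.fixture
def instance(rng):
    return random_instance(rng)
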
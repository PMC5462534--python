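import numpy as np
import pytest

from nmjquant import (
    generate_nmj_stack,
    sample_phantom_params,
    score_stack,
)
from nmjquant.phantom import CLASS_COMBINATIONS


@pytest.fixture(scope="session")
def small_phantom_batch():
    """A small deterministic batch of scored phantoms spanning all classes.

    Shared across tests that only need 'some realistic phantoms'.
    Returns a list of (params, stack, truth, record) tuples.
    """
    rng = np.random.default_rng(20250925)
    out = []
    for combo in CLASS_COMBINATIONS:
        for _ in range(2):
            params = sample_phantom_params(rng, combo)
            stack, truth = generate_nmj_stack(params)
            record = score_stack(stack)
            out.append((params, stack, truth, record))
    return out
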
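import numpy as np
import pytest

from tailmsm import GroundTruthChain


@pytest.fixture
def two_state_chain() -> GroundTruthChain:
    """Asymmetric 2-state chain: MFPT 0->1 is exactly 10 steps, t2 = -1/ln 0.7."""
    return GroundTruthChain(np.array([[0.9, 0.1], [0.2, 0.8]]))


@pytest.fixture
def three_state_linear() -> GroundTruthChain:
    """Symmetric linear chain 0-1-2 (uniform pi, exact TPT closed forms)."""
    return GroundTruthChain(
        np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]])
    )


@pytest.fixture
def reversible_chain_4() -> GroundTruthChain:
    """Reversible 4-state chain built from symmetric counts."""
    S = np.array([
        [960.0, 20, 15, 5],
        [20, 760.0, 15, 5],
        [15, 15, 560.0, 10],
        [5, 5, 10, 380.0],
    ])
    return GroundTruthChain(S / S.sum(axis=1)[:, None])
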
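import numpy as np
import pytest

from synmod import ScoringScheme, SimConfig, simulate_module_pair

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def random_peptide_pairs(n: int, max_len: int = 12, seed: int = 0):
    """Seeded random peptide pairs for aligner-oracle comparisons."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        pairs.append((random_peptide(rng, la), random_peptide(rng, lb)))
    return pairs


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome pair with one planted ten-gene module."""
    return simulate_module_pair(SimConfig(seed=11, n_background_a=6, n_background_b=7))


@pytest.fixture(scope="session")
def null_sim():
    """A genome pair with no shared module (background only)."""
    return simulate_module_pair(
        SimConfig(seed=12, module_genes=0, n_background_a=8, n_background_b=8)
    )
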
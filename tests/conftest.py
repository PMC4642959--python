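import numpy as np
import pytest

from mirlift import SimConfig
from mirlift.pipeline import run_synthetic_study

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_at(seq: str, positions, rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = BASES[(BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale error-free study: 20 hairpins, 2 decoys, 1 family pair."""
    return SimConfig(
        seed=7,
        n_precursors=20,
        genome_len=40_000,
        n_decoy_copies=2,
        n_family_collisions=1,
        expression_log_mean=1.6,
        seq_error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """(StudyResult, SourceCatalog, GroundTruth) of the small study."""
    return run_synthetic_study(small_cfg)
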
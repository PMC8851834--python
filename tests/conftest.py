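import numpy as np
import pytest

from orgamosaic import SimConfig, simulate_family

_BASES = np.array(list("ACGT"))


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def family():
    """One simulated mitogenome family shared across tests (generation and
    classification are the expensive steps)."""
    return simulate_family(SimConfig(seed=11))
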
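import numpy as np
import pytest

import splandscape as sp


@pytest.fixture(scope="session")
def bistable():
    """34-nt engineered bistable RNA: sequence plus its two hairpin folds."""
    seq, a, b = sp.bistable_example()
    return seq, a, b


@pytest.fixture(scope="session")
def landscape33():
    """33-nt two-hairpin toy with four alternative folds (DMS-designed)."""
    seq, folds = sp.two_hairpin_landscape()
    info = sp.informative_sites_for(seq, "DMS")
    return seq, folds, info


def random_structure(rng: np.random.Generator, L: int = 8) -> sp.Structure:
    """A random binary-state structure (constrained sites need not pair:
    they model tertiary contacts), for design-matrix oracle checks."""
    state = rng.integers(0, 2, size=L).astype(np.uint8)
    return sp.Structure(id="r", sequence="A" * L, pairs=frozenset(), state=state)
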
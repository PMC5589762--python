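import numpy as np
import pytest

from czbkit import (
    AtomSelector,
    DecoySpec,
    derive_true_restraints,
    make_ddg_benchmark,
    make_decoy_ensemble,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy():
    """Reference toy complex: helical core (A, B) + wrapped chaperone (C)."""
    return make_toy_complex()


@pytest.fixture(scope="session")
def true_restraints(toy):
    """Ground-truth restraints: zero violation on the reference."""
    return derive_true_restraints(toy)


@pytest.fixture(scope="session")
def decoys(toy):
    """Graded decoy ensemble with sigma labels."""
    ens, labels = make_decoy_ensemble(
        toy, DecoySpec(sigma_levels=(0.0, 0.5, 1.5), members_per_level=5, seed=11)
    )
    return ens, labels


@pytest.fixture(scope="session")
def ddg_benchmark():
    """Three jittered centroids + planted clash/distal mutation sites."""
    return make_ddg_benchmark(0)


@pytest.fixture
def core_selector():
    return AtomSelector(chains=("A", "B"))


@pytest.fixture
def chaperone_selector():
    return AtomSelector(chains=("C",))
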
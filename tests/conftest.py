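import numpy as np
import pytest
from rdkit import RDLogger

from cats2d.chemio import Compound
from cats2d.fixtures import FixtureSpec, generate_collection

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def benchmark_collection() -> list[Compound]:
    """3 planted target families x 25 ligands over 4 scaffolds, plus 100 decoys."""
    return generate_collection(FixtureSpec(3, 25, 4, 100, seed=7))


@pytest.fixture(scope="session")
def fifty_molecules(benchmark_collection) -> list[Compound]:
    """A structurally diverse 50-compound slice of the synthetic collection."""
    rng = np.random.default_rng(11)
    idx = rng.choice(len(benchmark_collection), size=50, replace=False)
    return [benchmark_collection[i] for i in idx]
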
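import numpy as np
import pytest

from morphoquant.pedigree import Pedigree, additive_relationship_matrix
from morphoquant.simulate import (
    SimulationConfig,
    simulate_breeding,
    simulate_traits,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset (3 units, 6 offspring/family) for fast tests."""
    cfg = SimulationConfig(seed=11, n_units=3, offspring_per_family=6)
    pedigree, genotypes = simulate_breeding(cfg)
    table, truth = simulate_traits(pedigree, genotypes, cfg)
    A = additive_relationship_matrix(pedigree)
    return {"config": cfg, "pedigree": pedigree, "genotypes": genotypes,
            "table": table, "truth": truth, "A": A}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pedigree(rng, n_founders=5, n_descendants=15):
    """Random valid pedigree: descendants pick parents among earlier ids."""
    recs = [(f"f{i}", None, None) for i in range(n_founders)]
    ids = [r[0] for r in recs]
    for k in range(n_descendants):
        n_avail = len(ids)
        sire = ids[rng.integers(0, n_avail)] if rng.random() < 0.9 else None
        dam = ids[rng.integers(0, n_avail)] if rng.random() < 0.9 else None
        if sire is not None and sire == dam:
            dam = None
        name = f"d{k}"
        recs.append((name, sire, dam))
        ids.append(name)
    return Pedigree(recs)
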
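import numpy as np
import pytest

import mcblup as mb


@pytest.fixture(scope="session")
def ped3() -> mb.Pedigree:
    """Two unrelated founders and their offspring."""
    return mb.Pedigree((("1", None, None), ("2", None, None), ("3", "1", "2")))


@pytest.fixture(scope="session")
def ped4() -> mb.Pedigree:
    """ped3 plus an inbred parent-offspring mating: 4 = (1, 3)."""
    return mb.Pedigree((("1", None, None), ("2", None, None),
                        ("3", "1", "2"), ("4", "1", "3")))


@pytest.fixture(scope="session")
def small_ds() -> mb.SimulatedDataset:
    """80-animal pedigree, 40 genotyped at 80 markers; shared across tests."""
    cfg = mb.SimulationConfig(n_founders=20, n_generations=3, matings_per_generation=20,
                              m=80, n_genotyped=40, h2=0.3, w=0.5, seed=7)
    return mb.simulate_dataset(cfg)


def random_pedigree(seed: int, max_animals: int = 200) -> mb.Pedigree:
    """Random valid pedigree with unknown parents, selfed-lineage-free."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_animals + 1))
    records = []
    for i in range(n):
        ancestors = list(range(i))
        sire = dam = None
        if len(ancestors) >= 2 and rng.random() < 0.7:
            s, d = rng.choice(len(ancestors), size=2, replace=False)
            sire, dam = str(s + 1), str(d + 1)
        elif ancestors and rng.random() < 0.2:
            sire = str(int(rng.integers(0, len(ancestors))) + 1)
        records.append((str(i + 1), sire, dam))
    return mb.Pedigree(tuple(records))
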
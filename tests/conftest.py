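import numpy as np
import pytest

import enhmom as em


@pytest.fixture(scope="session")
def separable_table():
    """Feature table from a strongly separated synthetic dataset (effect=1)."""
    spec = em.SimulationSpec(n_per_class=200, length=200, effect=1.0, seed=11)
    return em.extract_dataset(em.simulate_dataset(spec))


@pytest.fixture(scope="session")
def null_table():
    """Feature table from an effect=0 dataset: classes share one distribution."""
    spec = em.SimulationSpec(n_per_class=200, length=200, effect=0.0, seed=13)
    return em.extract_dataset(em.simulate_dataset(spec))


@pytest.fixture(scope="session")
def small_table():
    """A small separable table for fast classifier mechanics tests."""
    spec = em.SimulationSpec(n_per_class=60, length=120, effect=1.0, seed=5)
    return em.extract_dataset(em.simulate_dataset(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_sequence(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def make_fasta(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
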
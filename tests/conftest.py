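import numpy as np
import pytest

from geosig import (
    CatalogueMatrix,
    SBS96,
    scenario_signatures,
)


@pytest.fixture(scope="session")
def sigs3():
    """The three well-separated planted SBS-96 processes (T>A, T>C, flat)."""
    return scenario_signatures()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mixture_catalogue(sigs, exposures, seed=0, sample_prefix="s"):
    """Catalogue whose columns are multinomial draws from planted mixtures.

    ``exposures``: array (n_samples, n_signatures) of true mutation counts.
    """
    rng = np.random.default_rng(seed)
    exposures = np.asarray(exposures)
    cols = []
    for e in exposures:
        v = np.zeros(len(sigs.schema), dtype=np.int64)
        for j, n in enumerate(e):
            if n > 0:
                v += rng.multinomial(int(n), sigs.profiles[:, j])
        cols.append(v)
    ids = [f"{sample_prefix}{i}" for i in range(len(exposures))]
    return CatalogueMatrix(sigs.schema, ids, np.column_stack(cols))


@pytest.fixture(scope="session")
def mixture_catalogue_factory():
    return mixture_catalogue
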
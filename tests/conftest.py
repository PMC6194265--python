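import numpy as np
import pytest

from benthems.incidence import IncidenceMatrix


def random_matrix(
    rng: np.random.Generator,
    n_sites: int,
    n_species: int,
    fill: float = 0.4,
    nonempty: bool = True,
) -> IncidenceMatrix:
    """Random binary matrix; optionally resampled until no empty row/column."""
    while True:
        v = (rng.random((n_sites, n_species)) < fill).astype(np.int8)
        if not nonempty or ((v.sum(0) > 0).all() and (v.sum(1) > 0).all()):
            return IncidenceMatrix(
                [f"s{i}" for i in range(n_sites)],
                [f"sp{j}" for j in range(n_species)],
                v,
            )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
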
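import numpy as np
import pytest

from kinn.kinetics import KineticScheme, RateAssignment, cas9_cycle_scheme


def random_strongly_connected_scheme(rng: np.random.Generator, n_states: int) -> KineticScheme:
    """Random reversible backbone over a random state order plus extra
    directed edges; resampled until strongly connected."""
    while True:
        edges = set()
        perm = rng.permutation(n_states)
        for i in range(n_states - 1):
            a, b = int(perm[i]), int(perm[i + 1])
            edges.add((a, b))
            edges.add((b, a))
        for _ in range(int(rng.integers(0, n_states))):
            a, b = (int(x) for x in rng.integers(0, n_states, 2))
            if a != b:
                edges.add((a, b))
        scheme = KineticScheme(n_states=n_states, edges=tuple(sorted(edges)))
        if scheme.is_strongly_connected():
            return scheme


def log_uniform_rates(rng: np.random.Generator, scheme: KineticScheme,
                      lo: float = -3.0, hi: float = 3.0) -> RateAssignment:
    return RateAssignment.from_vector(
        scheme, 10.0 ** rng.uniform(lo, hi, scheme.n_edges)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def cycle4():
    return cas9_cycle_scheme(4, reservoir_concentration=1.0)


@pytest.fixture
def unit_rates(cycle4):
    return RateAssignment({sym: 1.0 for sym in cycle4.edge_symbols})
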
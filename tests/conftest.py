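import numpy as np
import pytest

import scgdyn as sd

MASTER_SEED = 20260926


@pytest.fixture
def two_vertex_loop():
    """0 -> 1 (lag 50), 1 -> 0 (lag 60): free period 110."""
    g = sd.DirectedGraph(2, frozenset({(0, 1), (1, 0)}))
    lags = sd.LagMap({(0, 1): 50.0, (1, 0): 60.0}, 50.0, 60.0)
    return g, lags


@pytest.fixture
def three_cycle():
    """0 -> 1 -> 2 -> 0 with lags 50, 60, 70: constant ISI 180."""
    g = sd.DirectedGraph(3, frozenset({(0, 1), (1, 2), (2, 0)}))
    lags = sd.LagMap({(0, 1): 50.0, (1, 2): 60.0, (2, 0): 70.0}, 50.0, 70.0)
    return g, lags


@pytest.fixture
def isolated_vertex():
    return sd.DirectedGraph(1, frozenset()), sd.LagMap({}, 1.0, 1.0)


def random_scg_with_lags(seed, n=None, z=None, n_swaps=50,
                         lag_low=50.0, lag_high=100.0):
    """Seeded small random SCG + lags for property tests.  Avoids the two
    provably infeasible regular combinations (n, z) = (4, 3) and (6, 5)."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(2, 9))
    if z is None:
        z_cap = min(3, n - 2 if n == 4 else n - 1)
        z = int(rng.integers(1, z_cap + 1))
    params = sd.GenParams(n=n, z=z, n_swaps=n_swaps,
                          seed=int(rng.integers(2**31)))
    return sd.generate_scg_with_lags(params, lag_low, lag_high)


@pytest.fixture(scope="session")
def scaled_survey():
    """Scaled-down size survey: 20 replicates at n in {25, 50, 100, 200}
    under the standard study conditions (delta=30, z=3, lags U[50,100],
    k=80).  Session-scoped: shared by contract and scaling tests."""
    params = sd.SurveyParams(
        n_values=(25, 50, 100, 200), replicates=20, seed=MASTER_SEED
    )
    return params, sd.run_survey(params)
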
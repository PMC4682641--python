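import numpy as np
import pytest

import frapkit as fk


def grid_search_one_component(times, values, a_range=(0.5, 1.5), b_range=(0.1, 20.0), n=2000):
    """Dense-grid SSE minimization oracle for the one-component model.

    Independent of the least-squares path: evaluates the exact SSE
    surface on an n x n (a, b) grid via its quadratic-in-a expansion.
    Returns (a, b, sse, (da, db)).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    a_grid = np.linspace(*a_range, n)
    b_grid = np.linspace(*b_range, n)
    E = 1.0 - np.exp(-np.outer(b_grid, times))  # (B, T)
    yy = values @ values
    Ey = E @ values
    E2 = (E * E).sum(axis=1)
    sse = yy - 2.0 * np.outer(a_grid, Ey) + np.outer(a_grid**2, E2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    cell = (a_grid[1] - a_grid[0], b_grid[1] - b_grid[0])
    return a_grid[i], b_grid[j], float(sse[i, j]), cell


@pytest.fixture(scope="session")
def default_setup():
    return fk.default_kinetics(), fk.default_geometry(), fk.default_imaging()


@pytest.fixture(scope="session")
def small_experiment():
    """One small rendered FRAP experiment shared across tests."""
    kin = fk.default_kinetics(n_molecules=4000)
    return fk.simulate_frap_experiment(
        kin, fk.default_geometry(), fk.default_imaging(), seed=42
    )
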
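import numpy as np
import pytest

from healthdea import GeneratorConfig, generate_panel
from healthdea.panel_io import CrossSection


@pytest.fixture(scope="session")
def toy_section() -> CrossSection:
    """One input, one output: A=(2,2) on the frontier, B=(4,2) dominated."""
    return CrossSection(
        period=2018, dmus=("A", "B"), X=np.array([[2.0], [4.0]]), Y=np.array([[2.0], [2.0]])
    )


@pytest.fixture(scope="session")
def small_panel():
    """Small seeded panel (8 DMUs x 4 periods) shared by slower suites."""
    cfg = GeneratorConfig(n_dmus=8, periods=4, frontier_fraction=0.25, seed=123)
    return generate_panel(cfg)


def random_section(rng: np.random.Generator, n: int, m: int, s: int) -> CrossSection:
    X = rng.uniform(0.5, 5.0, size=(n, m))
    Y = rng.uniform(0.5, 5.0, size=(n, s))
    return CrossSection(period=0, dmus=tuple(f"d{i}" for i in range(n)), X=X, Y=Y)


def sbm_grid_oracle(k: int, section: CrossSection, resolution: float = 1e-3) -> float:
    """Brute-force VRS SBM: grid lambda over the simplex, slacks in closed form.

    Independent of the LP path: for each grid lambda the slacks are
    s^- = x_k - X'lam (feasible iff >= 0) and s^+ = Y'lam - y_k (iff >= 0),
    and the objective (1 - mean(s^-/x_k)) / (1 + mean(s^+/y_k)) is minimised
    directly.  Only for n <= 3.
    """
    X, Y = section.X, section.Y
    n, m = X.shape
    s = Y.shape[1]
    K = int(round(1.0 / resolution))
    grid = np.arange(K + 1)
    if n == 1:
        lam = np.ones((1, 1))
    elif n == 2:
        a = grid / K
        lam = np.c_[a, 1.0 - a]
    elif n == 3:
        i, j = np.meshgrid(grid, grid, indexing="ij")
        keep = (i + j) <= K
        a, b = i[keep] / K, j[keep] / K
        lam = np.c_[a, b, 1.0 - a - b]
    else:
        raise ValueError("oracle only supports n <= 3")

    xk, yk = X[k], Y[k]
    Xc = lam @ X  # (M, m)
    Yc = lam @ Y  # (M, s)
    s_minus = xk[None, :] - Xc
    s_plus = Yc - yk[None, :]
    feas = np.all(s_minus >= -1e-12, axis=1) & np.all(s_plus >= -1e-12, axis=1)
    num = 1.0 - np.mean(np.clip(s_minus[feas], 0, None) / xk[None, :], axis=1)
    den = 1.0 + np.mean(np.clip(s_plus[feas], 0, None) / yk[None, :], axis=1)
    return float(np.min(num / den))
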
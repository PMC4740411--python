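import numpy as np
import pytest

import caremap as cm


@pytest.fixture
def lattice44() -> cm.Adjacency:
    return cm.make_lattice(4, 4, "rook")


@pytest.fixture
def two_area_csv(tmp_path):
    """Hand-written 2-area CSV with all 16 strata populated."""
    strata = cm.DEFAULT_STRATA
    header = ["area_id"]
    for s in strata:
        header += [f"O_{s}", f"n_{s}"]
    header += ["income", "unemployment"]
    rows = []
    rng = np.random.default_rng(7)
    for aid in ("alpha", "beta"):
        row = [aid]
        for _ in strata:
            n = int(rng.integers(100, 5000))
            row += [int(rng.integers(0, 5)), n]
        row += [250.0, 6.0]
        rows.append(row)
    path = tmp_path / "areas.csv"
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")
    return path


@pytest.fixture
def small_dataset():
    """10x10 lattice dataset drawn from the exact generative model."""
    cfg = cm.SimulationConfig(
        rows=10,
        cols=10,
        beta={"z1": 0.3},
        intercept=0.0,
        rho=0.6,
        tau2=0.05,
        covariate_marginals={"z1": (0.0, 1.0, "none")},
        covariate_corr=("z1", "z1", 0.0),
        e_range=(10.0, 60.0),
        seed=11,
    )
    return cm.simulate_dataset(cfg)


@pytest.fixture
def fast_spec():
    return cm.LerouxModelSpec(n_iter=3000, n_burnin=1000, seed=5)


def brute_force_moran(x: np.ndarray, adj: cm.Adjacency, style: str) -> float:
    """O(n^2) double-loop Moran's I oracle, independent of the implementation."""
    n = len(x)
    w = np.zeros((n, n))
    for i, nbrs in enumerate(adj.neighbors):
        for j in nbrs:
            w[i, j] = 1.0
    if style == "row":
        for i in range(n):
            rs = w[i].sum()
            if rs > 0:
                w[i] /= rs
    xb = sum(x) / n
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xb) * (x[j] - xb)
    den = sum((xi - xb) ** 2 for xi in x)
    s0 = w.sum()
    return n / s0 * num / den
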
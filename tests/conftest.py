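import numpy as np
import pandas as pd
import pytest

from paddyqtl import qtlmap, simdata


@pytest.fixture(scope="session")
def small_map():
    return simdata.simulate_map(3, 100.0, 5.0)


@pytest.fixture(scope="session")
def small_pop(small_map):
    return simdata.simulate_ril_population(
        small_map, 200, generation=7, seed=11, extra_loci=[("1", 50.0, "1@50.0")]
    )


@pytest.fixture(scope="session")
def small_probgrid(small_pop, small_map):
    return qtlmap.genotype_probabilities(small_pop.genotypes, small_map)


@pytest.fixture(scope="session")
def demo_trial():
    """One small simulated trial shared by the slower integration tests."""
    from paddyqtl.cli_io import demo_config

    cfg = demo_config(seed=5)
    return simdata.simulate_trial(cfg, missing_rate=0.05, error_rate=0.002, dup_pairs=5)


def brute_force_scan(X, y):
    """Independent HK oracle: per-position normal-equations regression."""
    n = len(y)
    lods, betas = [], []
    for j in range(X.shape[1]):
        A = np.column_stack([np.ones(n), X[:, j]])
        AtA = A.T @ A
        Aty = A.T @ y
        try:
            coef = np.linalg.solve(AtA, Aty)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(A, y, rcond=None)[0]
        rss1 = float(np.sum((y - A @ coef) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        lod = 0.0 if rss0 <= 0 else (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300))
        lods.append(min(lod, 300.0))
        betas.append(coef[1])
    return np.asarray(lods), np.asarray(betas)
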
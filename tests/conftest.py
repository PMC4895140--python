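import numpy as np
import pytest

from adoptspread import DegreeModel, Population, ThresholdModel, build_population

#: empirical model-side parameterisation used throughout the suite
PAPER_DEG = dict(mu=1.09, sigma=1.39, k_min=1)
PAPER_THR = dict(mu=-2.0, sigma=1.0)
P_N = 0.00019


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def deg_model():
    return DegreeModel(**PAPER_DEG)


@pytest.fixture
def thr_model():
    return ThresholdModel(**PAPER_THR)


@pytest.fixture
def small_population(deg_model, thr_model, rng):
    """A modest substrate for fast structural tests."""
    return build_population(deg_model, thr_model, 2000, 0.3, rng)


def star_population(k: int, thresholds=None) -> Population:
    """Star graph: node 0 is the centre, 1..k the leaves."""
    edges = np.array([(0, i) for i in range(1, k + 1)], dtype=np.int64)
    pop = Population.from_edges(k + 1, edges)
    if thresholds is not None:
        pop.threshold = np.asarray(thresholds, dtype=float)
    return pop


def path_population(n: int) -> Population:
    edges = np.array([(i, i + 1) for i in range(n - 1)], dtype=np.int64)
    return Population.from_edges(n, edges)
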
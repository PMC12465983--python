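import numpy as np
import pytest

from metafrag import MetaAnalysisDataset, TwoByTwoTable


def make_ma(tables, ma_id="ma"):
    """Build a dataset from (e1, n1, e0, n0) tuples."""
    return MetaAnalysisDataset(
        ma_id=ma_id,
        studies=tuple((f"s{i + 1}", TwoByTwoTable(*t)) for i, t in enumerate(tables)),
    )


def random_small_ma(rng, max_arm=25, min_studies=2, max_studies=4, ma_id="r"):
    """Random small meta-analysis: 2-4 studies, arm sizes <= max_arm."""
    k = int(rng.integers(min_studies, max_studies + 1))
    tables = []
    for _ in range(k):
        n1 = int(rng.integers(5, max_arm + 1))
        n0 = int(rng.integers(5, max_arm + 1))
        e1 = int(rng.integers(0, n1 + 1))
        e0 = int(rng.integers(0, n0 + 1))
        tables.append((e1, n1, e0, n0))
    return make_ma(tables, ma_id=ma_id)


@pytest.fixture
def fixture_f1():
    """Two moderately positive studies; significant under FE/OR."""
    return make_ma([(12, 20, 4, 20), (11, 20, 5, 20)], ma_id="F1")


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)
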
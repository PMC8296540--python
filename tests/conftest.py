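import numpy as np
import pytest

from mvgbin.containers import ContigCatalog, GraphView, LabelState
from mvgbin.simulate import ScenarioSpec, generate_scenario


def make_catalog(n: int, length: int = 2000) -> ContigCatalog:
    return ContigCatalog.from_records((f"c{i}", length) for i in range(n))


def random_graph(rng: np.random.Generator, n: int, p: float, catalog=None) -> GraphView:
    catalog = catalog or make_catalog(n)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    edges = frozenset((int(a), int(b)) for a, b in zip(iu[keep], ju[keep]))
    return GraphView(catalog, edges)


def random_labels(
    rng: np.random.Generator, catalog: ContigCatalog, n_labeled: int, s: int
) -> LabelState:
    y = np.full(catalog.n, -1, dtype=np.int64)
    picked = rng.choice(catalog.n, size=n_labeled, replace=False)
    y[picked] = rng.integers(0, s, size=n_labeled)
    names = tuple(f"bin_{k}" for k in range(s))
    return LabelState(catalog, y, names)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One realization of the default synthetic scenario, shared per session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_scenario(ScenarioSpec(seed=11), out)
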
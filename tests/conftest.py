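import networkx as nx
import numpy as np
import pytest

from moanet.pipeline import PipelineConfig, run_pipeline
from moanet.synthetic import write_fixture_bundle


def random_instance(seed: int, n_max: int = 15, edge_p: float = 0.3,
                    frac_pos: float = 0.3):
    """Seeded random interactome-with-indicators instance for solver tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, n_max + 1))
    g = nx.gnp_random_graph(n, edge_p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    nodes = sorted(g.nodes)
    n_pos = max(1, int(round(frac_pos * n)))
    pos = set(rng.choice(nodes, size=n_pos, replace=False))
    ind = {v: (1 if v in pos else 0) for v in nodes}
    return g, ind


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Default synthetic bundle (study conditions) plus one pipeline run."""
    root = tmp_path_factory.mktemp("bundle")
    truth = write_fixture_bundle(root, seed=1)
    config = PipelineConfig.from_yaml(root / "config.yaml")
    outdir = run_pipeline(config, root / "run")
    return {"root": root, "truth": truth, "config": config, "outdir": outdir}
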
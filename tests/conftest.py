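import numpy as np
import pytest

from graphsurv.model import BackboneConfig, TrainConfig
from graphsurv.patchgraph import build_knn_graph
from graphsurv.risk import SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_graph(n_nodes, n_features, seed, shift_nodes=(), shift=0.0, k=4):
    r = np.random.default_rng(seed)
    coords = r.uniform(0, 1000, (n_nodes, 2))
    feats = r.standard_normal((n_nodes, n_features))
    for i in shift_nodes:
        feats[i, : n_features // 2] += shift
    return build_knn_graph(coords, feats, k=k, slide_id=f"g{seed}")


@pytest.fixture
def small_bcfg():
    """Light backbone for training-speed-sensitive tests."""
    return BackboneConfig(arch="gcn", hidden_dims=[16, 8], embed_dim=8,
                          in_dim=12, pooling="mean", dropout=0.0)


@pytest.fixture
def planted_training_set():
    """20 small graphs whose survival ordering follows a planted feature shift."""
    r = np.random.default_rng(7)
    graphs, records = [], []
    for i in range(20):
        rho = i / 19.0
        n = 12
        g = make_graph(n, 12, seed=100 + i,
                       shift_nodes=range(int(round(rho * n))), shift=2.0)
        t = float(r.exponential(1.0 / (0.02 * np.exp(2.5 * rho)))) + 1e-3
        graphs.append(g)
        records.append(SurvivalRecord(patient_id=f"P{i}", time=t,
                                      event=bool(r.random() < 0.8)))
    if not any(rec.event for rec in records):
        records[0].event = True
    return graphs, records
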
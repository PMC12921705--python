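"""GNN layers, poolings, Cox partial likelihood, and joint training."""

import numpy as np
import pytest

from graphsurv.autodiff import Tensor
from graphsurv.model import (
    Adam, BackboneConfig, GATLayer, GCNLayer, KDEPool, AttentionPool, RiskModel,
    TrainConfig, cox_partial_nll, kde_density_oracle, load_model,
    normalized_adjacency, pool_max, pool_mean, save_model, train_joint,
)
from graphsurv.patchgraph import build_knn_graph
from graphsurv.risk import concordance_index


def graph_from(coords, feats, edges):
    from graphsurv.patchgraph import SlideGraph
    return SlideGraph(slide_id="t", features=np.asarray(feats, float),
                      coords=np.asarray(coords, float),
                      edges=np.asarray(edges, int).reshape(-1, 2), k=1)


# ---------------------------------------------------------------------------
# GCN layer
# ---------------------------------------------------------------------------

def test_gcn_single_node_identity_is_relu():
    rng = np.random.default_rng(0)
    layer = GCNLayer(3, 3, rng)
    layer.weight.data = np.eye(3)
    layer.bias.data = np.zeros(3)
    x = np.array([[-1.0, 0.5, 2.0]])
    out = layer(Tensor(x), normalized_adjacency(1, np.empty((0, 2), int))).relu()
    assert np.allclose(out.data, [[0.0, 0.5, 2.0]])


def test_gcn_symmetry_of_equal_nodes():
    rng = np.random.default_rng(1)
    layer = GCNLayer(4, 5, rng)
    x = np.tile(np.array([1.0, -2.0, 0.3, 0.9]), (2, 1))
    a = normalized_adjacency(2, np.array([[0, 1]]))
    out = layer(Tensor(x), a)
    assert np.allclose(out.data[0], out.data[1])


def test_gcn_path_graph_matches_dense_oracle():
    rng = np.random.default_rng(2)
    layer = GCNLayer(3, 2, rng)
    w, b = layer.weight.data, layer.bias.data
    x = rng.normal(0, 1, (3, 3))
    edges = np.array([[0, 1], [1, 2]])
    out = layer(Tensor(x), normalized_adjacency(3, edges))
    # independent dense computation
    a = np.eye(3)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    dinv = np.diag(1 / np.sqrt(a.sum(1)))
    expected = dinv @ a @ dinv @ x @ w + b
    assert np.allclose(out.data, expected)


# ---------------------------------------------------------------------------
# GAT layer
# ---------------------------------------------------------------------------

def test_gat_zero_attention_params_reduce_to_mean():
    rng = np.random.default_rng(3)
    layer = GATLayer(3, 4, heads=1, rng=rng, concat=False)
    layer.a_src[0].data[:] = 0.0
    layer.a_dst[0].data[:] = 0.0
    x = rng.normal(0, 1, (4, 3))
    edges = np.array([[0, 1], [0, 2], [0, 3]])  # star centered at 0
    mask = RiskModel._adj_mask(4, edges)
    out = layer(Tensor(x), mask)
    z = x @ layer.w[0].data
    # uniform attention over neighborhood incl. self
    expected0 = z.mean(axis=0) + layer.bias.data
    assert np.allclose(out.data[0], expected0)


def test_gat_single_node_self_attention_is_one():
    rng = np.random.default_rng(4)
    layer = GATLayer(3, 4, heads=2, rng=rng, concat=True)
    x = rng.normal(0, 1, (1, 3))
    out = layer(Tensor(x), RiskModel._adj_mask(1, np.empty((0, 2), int)))
    expected = np.concatenate([x @ layer.w[h].data for h in range(2)], axis=1) \
        + layer.bias.data
    assert np.allclose(out.data, expected)


def test_gat_star_matches_enumerated_attention_oracle():
    rng = np.random.default_rng(5)
    layer = GATLayer(2, 3, heads=1, rng=rng, concat=False)
    x = rng.normal(0, 1, (3, 2))
    edges = np.array([[0, 1], [0, 2]])
    out = layer(Tensor(x), RiskModel._adj_mask(3, edges))
    w = layer.w[0].data
    asrc, adst = layer.a_src[0].data, layer.a_dst[0].data
    z = x @ w

    def lrelu(v):
        return np.where(v > 0, v, 0.2 * v)

    neigh = {0: [0, 1, 2], 1: [0, 1], 2: [0, 2]}
    expected = np.zeros((3, 3))
    for i, nb in neigh.items():
        logits = np.array([lrelu(z[i] @ asrc + z[j] @ adst) for j in nb])
        alpha = np.exp(logits - logits.max())
        alpha /= alpha.sum()
        expected[i] = sum(a * z[j] for a, j in zip(alpha, nb)) + layer.bias.data
    assert np.allclose(out.data, expected)


# ---------------------------------------------------------------------------
# poolings
# ---------------------------------------------------------------------------

def test_mean_max_pooling_oracles(rng):
    h = rng.normal(0, 1, (10, 64))
    assert np.allclose(pool_mean(Tensor(h)).data, h.mean(axis=0))
    assert np.allclose(pool_max(Tensor(h)).data, h.max(axis=0))
    single = rng.normal(0, 1, (1, 64))
    assert np.allclose(pool_mean(Tensor(single)).data, single[0])
    assert np.allclose(pool_max(Tensor(single)).data, single[0])
    two = np.vstack([h[0], -h[0]])
    assert np.allclose(pool_mean(Tensor(two)).data, 0.0)


def test_attention_pool_identical_embeddings_pass_through(rng):
    pool = AttentionPool(8, 4, rng)
    h = np.tile(rng.normal(0, 1, 8), (5, 1))
    assert np.allclose(pool(Tensor(h)).data, h[0])


def test_attention_pool_matches_hand_softmax(rng):
    pool = AttentionPool(4, 3, rng)
    h = rng.normal(0, 1, (3, 4))
    scores = np.tanh(h @ pool.v.data.T) @ pool.w.data
    alpha = np.exp(scores - scores.max())
    alpha /= alpha.sum()
    assert np.allclose(pool(Tensor(h)).data, alpha @ h)


def test_attention_pool_dominant_score_selects_node(rng):
    pool = AttentionPool(4, 3, rng)
    h = rng.normal(0, 1, (4, 4))
    # drive one node's score far above the others through the gate weights
    scores = np.tanh(h @ pool.v.data.T) @ pool.w.data
    winner = int(np.argmax(scores))
    pool.w.data *= 200.0
    assert np.allclose(pool(Tensor(h)).data, h[winner], atol=1e-6)


def test_kde_pool_density_matches_mixture_oracle(rng):
    pool = KDEPool(dim=2, grid_size=4, bandwidth=1.0, rng=rng)
    # selector projection exposes raw density values: output j = density_flat[j]
    pool.proj.data = np.eye(8)[:, [0, 5]]
    h = rng.normal(0, 1, (5, 2))
    out = pool(Tensor(h)).data
    for dim, flat_idx in ((0, 0), (1, 5)):
        lo, hi = h[:, dim].min(), h[:, dim].max()
        grid = np.linspace(lo, hi, 4)
        dens = kde_density_oracle(h[:, dim], grid, 1.0)
        expected = dens[flat_idx - dim * 4]
        assert out[(0, 1)[dim]] == pytest.approx(expected, rel=1e-10)


def test_kde_pool_constant_nodes_equal_single_node(rng):
    pool = KDEPool(dim=3, grid_size=5, bandwidth=None, rng=rng)
    v = rng.normal(0, 1, 3)
    one = pool(Tensor(v[None, :])).data
    many = pool(Tensor(np.tile(v, (7, 1)))).data
    assert np.allclose(one, many)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def test_cox_nll_closed_forms():
    assert cox_partial_nll(np.array([1.0, 1.0]), [1, 2], [1, 0]) == pytest.approx(np.log(2))
    assert cox_partial_nll(np.array([1.0, 0.0]), [1, 2], [1, 0]) == pytest.approx(
        np.log(1 + np.exp(-1)))


def test_cox_nll_shift_invariance_exact(rng):
    s = rng.normal(0, 1, 12)
    t = rng.uniform(1, 20, 12)
    e = rng.random(12) > 0.4
    base = cox_partial_nll(s, t, e)
    assert cox_partial_nll(s + 5.3, t, e) == pytest.approx(base, abs=1e-10)


def test_cox_nll_gradient_matches_finite_differences(rng):
    s = rng.normal(0, 1, 10)
    t = rng.uniform(1, 10, 10)
    e = rng.random(10) > 0.3
    st = Tensor(s, requires_grad=True)
    cox_partial_nll(st, t, e).backward()
    fd = np.zeros(10)
    for i in range(10):
        sp, sm = s.copy(), s.copy()
        sp[i] += 1e-6
        sm[i] -= 1e-6
        fd[i] = (cox_partial_nll(sp, t, e) - cox_partial_nll(sm, t, e)) / 2e-6
    assert np.abs(st.grad - fd).max() / np.abs(fd).max() < 1e-4


def test_cox_nll_requires_events():
    with pytest.raises(ValueError):
        cox_partial_nll(np.zeros(3), [1, 2, 3], [0, 0, 0])


def test_cox_nll_breslow_ties_share_risk_set():
    # two events at the same time use the same denominator
    s = np.array([0.5, -0.2, 0.1])
    loss = cox_partial_nll(s, [2.0, 2.0, 5.0], [1, 1, 0])
    lse = np.log(np.exp(s).sum())
    assert loss == pytest.approx(-(s[0] - lse) - (s[1] - lse))


# ---------------------------------------------------------------------------
# full model and training
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("arch,pooling", [
    ("gcn", "mean"), ("gcn", "kde"), ("gat", "attention"), ("gat", "max"),
])
def test_node_permutation_invariance(arch, pooling, rng):
    bcfg = BackboneConfig(arch=arch, pooling=pooling, hidden_dims=[8, 8],
                          embed_dim=8, in_dim=6, dropout=0.0, gat_heads=2,
                          kde_grid_size=4)
    model = RiskModel(bcfg, seed=9)
    coords = rng.uniform(0, 100, (12, 2))
    feats = rng.normal(0, 1, (12, 6))
    g1 = build_knn_graph(coords, feats, k=3)
    perm = rng.permutation(12)
    g2 = build_knn_graph(coords[perm], feats[perm], k=3)
    assert model.risk_score(g1) == pytest.approx(model.risk_score(g2), rel=1e-5, abs=1e-8)


def test_training_reduces_loss_and_is_deterministic(planted_training_set, small_bcfg):
    graphs, records = planted_training_set
    tcfg = TrainConfig(epochs=25, learning_rate=5e-3, seed=3)
    m1 = train_joint(graphs, records, small_bcfg, tcfg)
    assert m1.loss_history[-1] < m1.loss_history[0]
    m2 = train_joint(graphs, records, small_bcfg, tcfg)
    assert np.array_equal(m1.cox_beta.data, m2.cox_beta.data)
    m3 = train_joint(graphs, records, small_bcfg, TrainConfig(epochs=25,
                                                              learning_rate=5e-3, seed=4))
    assert not np.array_equal(m1.cox_beta.data, m3.cox_beta.data)


def test_training_set_concordance_on_planted_cohort(planted_training_set, small_bcfg):
    graphs, records = planted_training_set
    tcfg = TrainConfig(epochs=120, learning_rate=5e-3, weight_decay=0.0, seed=0)
    model = train_joint(graphs, records, small_bcfg, tcfg)
    risks = [model.risk_score(g) for g in graphs]
    t = [r.time for r in records]
    e = [r.event for r in records]
    assert concordance_index(risks, t, e) > 0.9


def test_checkpoint_roundtrip(tmp_path, planted_training_set, small_bcfg):
    graphs, records = planted_training_set
    tcfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=1)
    model = train_joint(graphs[:6], records[:6], small_bcfg, tcfg)
    save_model(model, tmp_path / "m.npz", tcfg)
    loaded = load_model(tmp_path / "m.npz")
    for g in graphs[:3]:
        assert loaded.risk_score(g) == pytest.approx(model.risk_score(g))
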
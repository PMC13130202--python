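"""Model components against independent loop-based oracles, plus
end-to-end composition, determinism, equivariance and gradient checks."""

import numpy as np
import pytest

from multidda.autodiff import Tensor
from multidda.data_io import AssociationMatrix, DatasetBundle, MeshDag, ModalityMatrix
from multidda.hetgraph import assemble_adjacency, normalize_adjacency
from multidda.model import (
    ModelConfig,
    attention_coefficients,
    decode,
    forward,
    forward_tensors,
    fuse_branches,
    graph_attention,
    graph_conv,
    init_params,
    inject_context,
    load_checkpoint,
    modality_branch,
    save_checkpoint,
)
from multidda.similarity import SimilarityMatrix

import networkx as nx


# ---------------------------------------------------------------------------
# loop-based oracles
# ---------------------------------------------------------------------------


def conv_oracle(h, ahat, w):
    n, din = h.shape
    dout = w.shape[1]
    out = np.zeros((n, dout))
    for i in range(n):
        for o in range(dout):
            acc = 0.0
            for j in range(n):
                for k in range(din):
                    acc += ahat[i, j] * h[j, k] * w[k, o]
            out[i, o] = max(acc, 0.0)
    return out


def branch_oracle(x, p, b):
    out = np.zeros((x.shape[0], p.shape[1]))
    for i in range(x.shape[0]):
        for o in range(p.shape[1]):
            acc = b[o]
            for k in range(x.shape[1]):
                acc += x[i, k] * p[k, o]
            out[i, o] = max(acc, 0.0)
    return out


def attention_oracle(h, a, w_g, a_vec, slope):
    """Literal per-node softmax over neighborhoods from nonzero a."""
    n = h.shape[0]
    f = h @ w_g
    d = w_g.shape[1]
    alpha = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in range(n) if a[i, j] != 0] or [i]
        logits = []
        for j in neigh:
            z = np.concatenate([f[i], f[j]]) @ a_vec
            logits.append(z if z > 0 else slope * z)
        logits = np.array(logits)
        e = np.exp(logits - logits.max())
        for j, p in zip(neigh, e / e.sum()):
            alpha[i, j] = p
    return alpha


def gat_oracle(h, a, heads, slope):
    n = h.shape[0]
    acc = np.zeros((n, heads[0][0].shape[1]))
    for w_g, a_vec in heads:
        alpha = attention_oracle(h, a, w_g, a_vec, slope)
        acc += alpha @ (h @ w_g)
    acc /= len(heads)
    return np.where(acc > 0, acc, np.expm1(np.minimum(acc, 0)))


def decode_oracle(h, c, w1, b1, w2, b2):
    d = h.shape[0] - c
    out = np.zeros((c, d))
    for i in range(c):
        for j in range(d):
            pair = np.concatenate([h[i], h[c + j]])
            hidden = np.maximum(pair @ w1 + b1, 0.0)
            z = hidden @ w2 + b2
            out[i, j] = 1.0 / (1.0 + np.exp(-z[0]))
    return out


# ---------------------------------------------------------------------------
# component tests
# ---------------------------------------------------------------------------


class TestGraphConv:
    def test_identity_propagation(self):
        h = np.abs(np.random.default_rng(0).standard_normal((4, 3)))
        out = graph_conv(h, np.eye(4), np.eye(3))
        np.testing.assert_allclose(out, h)

    def test_zero_features_stay_zero(self):
        out = graph_conv(np.zeros((4, 3)), np.eye(4), np.ones((3, 2)))
        np.testing.assert_array_equal(out, 0)

    def test_non_finite_input_rejected(self):
        h = np.full((2, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            graph_conv(h, np.eye(2), np.eye(2))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        h = rng.standard_normal((6, 4))
        ahat = normalize_adjacency(np.abs(rng.standard_normal((6, 6))))
        w = rng.standard_normal((4, 3))
        np.testing.assert_allclose(graph_conv(h, ahat, w),
                                   conv_oracle(h, ahat, w), atol=1e-10)


class TestModalityBranch:
    def test_zero_input_zero_bias_gives_zero(self):
        assert (modality_branch(np.zeros((3, 4)), np.ones((4, 2)),
                                np.zeros(2)) == 0).all()

    def test_negative_preactivation_clamped(self):
        out = modality_branch(np.ones((1, 1)), np.array([[-2.0]]),
                              np.zeros(1))
        np.testing.assert_array_equal(out, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            modality_branch(np.ones((2, 3)), np.ones((4, 2)), np.zeros(2))

    def test_matches_affine_clamp_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 2, size=(5, 7)).astype(float)
        p = rng.standard_normal((7, 3))
        b = rng.standard_normal(3)
        np.testing.assert_allclose(modality_branch(x, p, b),
                                   branch_oracle(x, p, b), atol=1e-12)


class TestFuseBranches:
    def test_single_modality_passthrough(self):
        x = np.random.default_rng(0).random((4, 3))
        np.testing.assert_allclose(
            fuse_branches({"target": x}, np.zeros(1)), x)

    def test_identical_projections_convexity(self):
        x = np.random.default_rng(1).random((4, 3))
        out = fuse_branches({"a": x, "b": x},
                            np.array([2.0, -1.0]))
        np.testing.assert_allclose(out, x)

    def test_uniform_logits_give_arithmetic_mean(self):
        rng = np.random.default_rng(2)
        ps = {k: rng.random((4, 3)) for k in "abc"}
        out = fuse_branches(ps, np.zeros(3))
        np.testing.assert_allclose(out, np.mean(list(ps.values()), axis=0))

    def test_concat_fusion_stacks_horizontally(self):
        rng = np.random.default_rng(3)
        ps = {"a": rng.random((4, 2)), "b": rng.random((4, 3))}
        out = fuse_branches(ps, fusion="concat")
        np.testing.assert_allclose(out, np.hstack([ps["a"], ps["b"]]))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fuse_branches({})


class TestInjectContext:
    def test_zero_context_pads_all_rows_alike(self):
        h = np.ones((5, 3))
        out = inject_context(h, np.zeros((2, 4)), 2)
        np.testing.assert_array_equal(out[:, 3:], 0)
        np.testing.assert_array_equal(out[:, :3], h)

    def test_width_arithmetic(self):
        out = inject_context(np.ones((5, 3)), np.ones((2, 4)), 2)
        assert out.shape == (5, 7)

    def test_drug_rows_carry_context_exactly(self):
        rng = np.random.default_rng(4)
        h = rng.random((6, 3))
        o = rng.random((4, 5))
        out = inject_context(h, o, 4)
        np.testing.assert_array_equal(out[:4, 3:], o)
        np.testing.assert_array_equal(out[4:, 3:], 0)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inject_context(np.ones((5, 3)), np.ones((3, 4)), 2)


class TestAttention:
    def _instance(self, seed, n=5, d=3):
        rng = np.random.default_rng(seed)
        h = rng.standard_normal((n, d))
        a = (rng.random((n, n)) > 0.5).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 1.0)
        w = rng.standard_normal((d, d))
        av = rng.standard_normal(2 * d)
        return h, a, w, av

    def test_single_neighbor_gets_full_weight(self):
        h, _, w, av = self._instance(0, n=3)
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0  # node 2 isolated -> self-loop fallback
        alpha = attention_coefficients(h, a, w, av)
        assert alpha[0, 1] == 1.0 and alpha[1, 0] == 1.0
        assert alpha[2, 2] == 1.0

    def test_identical_embeddings_split_evenly(self):
        h = np.ones((3, 2))
        a = np.array([[0.0, 1, 1], [1, 0, 0], [1, 0, 0]])
        rng = np.random.default_rng(1)
        alpha = attention_coefficients(h, a, rng.standard_normal((2, 2)),
                                       rng.standard_normal(4))
        np.testing.assert_allclose(alpha[0, 1:], 0.5)

    def test_rows_sum_to_one(self):
        h, a, w, av = self._instance(2)
        alpha = attention_coefficients(h, a, w, av)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_node_softmax_oracle(self, seed):
        h, a, w, av = self._instance(seed)
        np.testing.assert_allclose(
            attention_coefficients(h, a, w, av, 0.2),
            attention_oracle(h, a, w, av, 0.2), atol=1e-10)

    def test_self_loop_only_reduces_to_elu_wh(self):
        h, _, w, av = self._instance(3)
        a = np.eye(5)
        out = graph_attention(h, a, [(w, av)])
        f = h @ w
        np.testing.assert_allclose(out, np.where(f > 0, f, np.expm1(
            np.minimum(f, 0))), atol=1e-12)

    def test_duplicate_heads_equal_single_head(self):
        h, a, w, av = self._instance(4)
        one = graph_attention(h, a, [(w, av)])
        two = graph_attention(h, a, [(w, av), (w.copy(), av.copy())])
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_zero_heads_rejected(self):
        h, a, _, _ = self._instance(5)
        with pytest.raises(ValueError, match="K >= 1"):
            graph_attention(h, a, [])

    @pytest.mark.parametrize("seed", range(3))
    def test_multihead_matches_loop_oracle(self, seed):
        h, a, w, av = self._instance(seed, n=6, d=4)
        rng = np.random.default_rng(seed + 100)
        heads = [(rng.standard_normal((4, 4)), rng.standard_normal(8))
                 for _ in range(3)]
        np.testing.assert_allclose(graph_attention(h, a, heads, 0.2),
                                   gat_oracle(h, a, heads, 0.2), atol=1e-8)


class TestDecode:
    def test_zero_weights_give_half_everywhere(self):
        h = np.random.default_rng(0).standard_normal((5, 4))
        out = decode(h, 2, np.zeros((8, 3)), np.zeros(3), np.zeros((3, 1)),
                     np.zeros(1))
        np.testing.assert_array_equal(out, 0.5)

    def test_scores_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        out = decode(rng.standard_normal((6, 4)), 3,
                     rng.standard_normal((8, 5)), rng.standard_normal(5),
                     rng.standard_normal((5, 1)), rng.standard_normal(1))
        assert (out > 0).all() and (out < 1).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.standard_normal((7, 4))
        w1 = rng.standard_normal((8, 5))
        b1 = rng.standard_normal(5)
        w2 = rng.standard_normal((5, 1))
        b2 = rng.standard_normal(1)
        np.testing.assert_allclose(decode(h, 3, w1, b1, w2, b2),
                                   decode_oracle(h, 3, w1, b1, w2, b2),
                                   atol=1e-8)


# ---------------------------------------------------------------------------
# end-to-end forward
# ---------------------------------------------------------------------------


def tiny_instance(seed=0, n_drugs=10, n_diseases=12, config=None):
    rng = np.random.default_rng(seed)
    drug_ids = [f"c{i}" for i in range(n_drugs)]
    disease_ids = [f"d{j}" for j in range(n_diseases)]
    mods = {}
    for name, dim in (("target", 8), ("enzyme", 5), ("pathway", 6),
                      ("substructure", 9), ("ddi", 7)):
        mods[name] = ModalityMatrix(
            name, list(drug_ids), [f"{name}{k}" for k in range(dim)],
            rng.integers(0, 2, size=(n_drugs, dim)).astype(np.int8))
    values = (rng.random((n_drugs, n_diseases)) < 0.3).astype(np.int8)
    values[0, 0] = 1
    assoc = AssociationMatrix(drug_ids, disease_ids, values)
    g = nx.DiGraph()
    for j in range(n_diseases):
        g.add_edge("root", f"n{j}")
    dag = MeshDag(g, {d: f"n{j}" for j, d in enumerate(disease_ids)})
    bundle = DatasetBundle(mods, assoc, dag)

    sc_vals = np.abs(rng.random((n_drugs, n_drugs)))
    sc_vals = (sc_vals + sc_vals.T) / 2
    np.fill_diagonal(sc_vals, 1.0)
    sd_vals = np.abs(rng.random((n_diseases, n_diseases)))
    sd_vals = (sd_vals + sd_vals.T) / 2
    np.fill_diagonal(sd_vals, 1.0)
    graph = assemble_adjacency(SimilarityMatrix(drug_ids, sc_vals),
                               SimilarityMatrix(disease_ids, sd_vals), assoc)
    config = config or ModelConfig(embed_dim=8, n_heads=2, seed=seed)
    params = init_params(config, graph.n_nodes,
                         {m: mods[m].n_features for m in config.modality_names})
    return bundle, graph, params, config


class TestForward:
    def test_deterministic_given_seed_and_params(self):
        bundle, graph, params, config = tiny_instance()
        s1 = forward(graph, bundle, params, config)
        s2 = forward(graph, bundle, params, config)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_single_level_degenerate_runs(self):
        bundle, graph, params, config = tiny_instance(
            config=ModelConfig(n_levels=1, embed_dim=8, n_heads=2, seed=0))
        s = forward(graph, bundle, params, config)
        assert s.values.shape == (10, 12)
        assert ((s.values > 0) & (s.values < 1)).all()

    def test_matches_hand_composed_component_chain(self):
        """forward == the six public component oracles chained by hand."""
        bundle, graph, params, config = tiny_instance()
        h = graph.h0
        for level in range(config.n_levels):
            h = graph_conv(h, graph.normalized,
                           params[f"conv_W_{level}"].data)
            projs = {
                name: modality_branch(
                    bundle.modalities[name].values.astype(float),
                    params[f"branch_P_{name}_{level}"].data,
                    params[f"branch_b_{name}_{level}"].data)
                for name in config.modality_names
            }
            o = fuse_branches(projs, params[f"mix_{level}"].data,
                              config.fusion)
            h = inject_context(h, o, graph.n_drugs)
        heads = [(params[f"att_W_{k}"].data, params[f"att_a_{k}"].data)
                 for k in range(config.n_heads)]
        h = graph_attention(h, graph.adjacency, heads, config.leaky_slope)
        expected = decode(h, graph.n_drugs, params["dec_W1"].data,
                          params["dec_b1"].data, params["dec_w2"].data,
                          params["dec_b2"].data)
        got = forward(graph, bundle, params, config)
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    def test_permutation_equivariance_over_drugs(self):
        """Permuting drug order (inputs + node-indexed weights) permutes
        the score rows identically."""
        bundle, graph, params, config = tiny_instance()
        rng = np.random.default_rng(42)
        perm = rng.permutation(bundle.n_drugs)

        base = forward(graph, bundle, params, config).values

        drug_ids = [bundle.drug_ids[i] for i in perm]
        mods = {
            name: ModalityMatrix(name, list(drug_ids), m.feature_ids,
                                 m.values[perm])
            for name, m in bundle.modalities.items()
        }
        assoc = AssociationMatrix(drug_ids, list(bundle.disease_ids),
                                  bundle.associations.values[perm])
        bundle_p = DatasetBundle(mods, assoc, bundle.dag)
        c = bundle.n_drugs
        sc = graph.drug_block[np.ix_(perm, perm)]
        sd = graph.disease_block
        graph_p = assemble_adjacency(
            SimilarityMatrix(drug_ids, sc),
            SimilarityMatrix(list(bundle.disease_ids), sd), assoc)

        params_p = params.copy()
        node_perm = np.concatenate([perm, np.arange(c, graph.n_nodes)])
        # conv_W_0 is node-indexed on its input axis (H0 columns)
        params_p.tensors["conv_W_0"].data = \
            params["conv_W_0"].data[node_perm]
        out = forward(graph_p, bundle_p, params_p, config).values
        np.testing.assert_allclose(out, base[perm], atol=1e-10)


class TestGradient:
    def test_finite_difference_gradient_on_small_instance(self):
        """Autodiff loss gradient vs central differences, sampled entries."""
        from multidda.train_eval import _bce_from_logits_t

        bundle, graph, params, config = tiny_instance(
            n_drugs=3, n_diseases=3,
            config=ModelConfig(embed_dim=4, n_heads=2, n_levels=2,
                               dropout=0.0, seed=0))
        # move off the zero-bias init: ReLU kinks sit exactly at 0 there,
        # where finite differences straddle the non-differentiable point
        jitter = np.random.default_rng(7)
        for t in params.tensors.values():
            t.data = t.data + 0.05 * jitter.standard_normal(t.data.shape)

        labels = bundle.associations.values.astype(float)
        keep = np.ones_like(labels, dtype=bool)
        modality_values = {
            m: bundle.modalities[m].values.astype(float)
            for m in config.modality_names
        }

        def loss_value():
            logits, _ = forward_tensors(
                params, config, graph.normalized, graph.h0, graph.adjacency,
                modality_values, graph.n_drugs, train=False)
            return _bce_from_logits_t(logits, labels, keep, 2.0)

        loss = loss_value()
        loss.backward()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for key, t in params.tensors.items():
            flat = t.data.reshape(-1)
            gflat = t.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = float(loss_value().data)
                flat[idx] = orig - eps
                lo = float(loss_value().data)
                flat[idx] = orig
                num = (hi - lo) / (2 * eps)
                denom = max(abs(num), abs(gflat[idx]), 1e-8)
                assert abs(gflat[idx] - num) / denom < 1e-4, \
                    f"gradient mismatch in {key}[{idx}]"


class TestCheckpoint:
    def test_round_trip_preserves_params_and_config(self, tmp_path):
        _, _, params, config = tiny_instance()
        save_checkpoint(params, config, tmp_path / "ckpt.npz")
        params2, config2 = load_checkpoint(tmp_path / "ckpt.npz")
        assert config2 == config
        assert set(params2.tensors) == set(params.tensors)
        for k in params.tensors:
            np.testing.assert_array_equal(params2[k].data, params[k].data)
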
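"""The three sub-models, fusion head and auxiliary-loss arithmetic."""

import numpy as np
import pytest

import cycloperm as cp
from cycloperm import autodiff
from cycloperm.autodiff import Tensor, softmax
from cycloperm.errors import ConfigError
from cycloperm.nets import LossBreakdown
from conftest import tiny_model


def random_batch(rng, B=3, N=6, L=5, n_desc=16, n_fp=2048):
    d = rng.uniform(1.0, 5.0, size=(B, N, N))
    d = (d + d.T.swapaxes(0, 2).reshape(B, N, N)) / 2
    d = np.triu(d, 1)
    d = d + d.swapaxes(1, 2)
    batch = {
        "node": rng.random((B, N, 30)),
        "bond": rng.random((B, N, N)),
        "strength_graph": np.clip(1.0 / np.maximum(d, 1.0), 0, 1),
        "strength_conf": np.clip(1.0 / np.maximum(d, 1.0), 0, 1),
        "atom_mask": np.ones((B, N), dtype=bool),
        "monomer": rng.random((B, L, 16)),
        "monomer_mask": np.ones((B, L), dtype=bool),
        "desc": rng.random((B, n_desc)),
        "fp": (rng.random((B, n_fp)) < 0.05).astype(float),
        "label": rng.normal(-6, 1, B),
    }
    for b in range(B):
        batch["strength_graph"][b][np.eye(N, dtype=bool)] = 1.0
        batch["strength_conf"][b][np.eye(N, dtype=bool)] = 1.0
    return batch


class TestConfigs:
    def test_dmodel_divisible_by_heads(self):
        with pytest.raises(ConfigError):
            cp.AtomModelConfig(d_model=10, h=4)

    def test_lambda_g_bounds(self):
        with pytest.raises(ConfigError):
            cp.AtomModelConfig(lambda_g=1.5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            cp.MonomerModelConfig(kernel=4)


class TestAtomEmbedding:
    def test_zero_inputs_give_zero_embedding(self):
        model = tiny_model(n_max=4)
        batch = {k: np.zeros(s) for k, s in {
            "node": (1, 4, 30), "bond": (1, 4, 4)}.items()}
        out, _ = model.atom.forward(batch["node"], batch["bond"],
                                    np.zeros((1, 4, 4)), np.zeros((1, 4, 4)),
                                    np.zeros((1, 4), dtype=bool))
        # all-zero inputs with zero mask: latent is the head bias only
        assert np.allclose(out.data, model.params["atom.head.b"].data,
                           atol=1e-6)

    def test_embedding_matches_hand_formula_single_atom(self, float64_engine):
        model = tiny_model(n_max=1, atom={"d_model": 4, "h": 2,
                                          "ffn_width": 4, "latent": 2})
        node = np.zeros((1, 1, 30))
        node[0, 0, :3] = [1.0, 2.0, 3.0]
        bond = np.full((1, 1, 1), 0.5)
        Wn = model.params["atom.W_node"].data
        Wb = model.params["atom.W_bond"].data
        expected = (node[0] @ Wn + bond[0] @ Wb) / 2.0  # sqrt(d_model) = 2
        x = (Tensor(node) @ model.params["atom.W_node"]
             + Tensor(bond) @ model.params["atom.W_bond"]) * 0.5
        assert np.allclose(x.data[0], expected, atol=1e-12)

    def test_zero_node_weights_leave_bond_dependence_only(self):
        model = tiny_model(n_max=4)
        model.params["atom.W_node"].data[:] = 0.0
        rng = np.random.default_rng(0)
        b1 = random_batch(rng, B=1, N=4)
        b2 = {**b1, "node": rng.random((1, 4, 30))}
        o1, _ = model.atom.forward(b1["node"], b1["bond"],
                                   b1["strength_graph"], b1["strength_conf"],
                                   b1["atom_mask"])
        o2, _ = model.atom.forward(b2["node"], b2["bond"],
                                   b2["strength_graph"], b2["strength_conf"],
                                   b2["atom_mask"])
        assert np.allclose(o1.data, o2.data, atol=1e-6)


class TestFocusedAttention:
    def test_attention_matches_numpy_oracle(self, float64_engine):
        """The focused head equals softmax(QK^T/sqrt(d_model)) ⊙ Strength
        applied to V, computed independently in plain numpy."""
        model = tiny_model(n_max=5)
        P = model.params
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 5, 16))
        strength = np.clip(rng.random((2, 5, 5)) + np.eye(5), 0, 1)
        mask = np.ones((2, 5), dtype=bool)
        out = model.atom._attention(Tensor(x), strength, mask, "atom.graph.0")
        h, d = 2, 16
        dk = d // h
        ref = np.empty((2, 5, d))
        for b in range(2):
            q = x[b] @ P["atom.graph.0.Wq"].data
            k = x[b] @ P["atom.graph.0.Wk"].data
            v = x[b] @ P["atom.graph.0.Wv"].data
            heads = []
            for i in range(h):
                qi = q[:, i * dk:(i + 1) * dk]
                ki = k[:, i * dk:(i + 1) * dk]
                vi = v[:, i * dk:(i + 1) * dk]
                s = qi @ ki.T / np.sqrt(d)
                e = np.exp(s - s.max(axis=1, keepdims=True))
                p = e / e.sum(axis=1, keepdims=True)
                heads.append((p * strength[b]) @ vi)
            ref[b] = np.concatenate(heads, axis=1) @ P["atom.graph.0.Wo"].data
        assert np.allclose(out.data, ref, atol=1e-10)

    def test_all_ones_strength_reduces_to_plain_attention(self, float64_engine):
        model = tiny_model(n_max=4)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 4, 16))
        mask = np.ones((1, 4), dtype=bool)
        focused = model.atom._attention(Tensor(x), np.ones((1, 4, 4)), mask,
                                        "atom.graph.0")
        # plain attention = focused with the all-ones attenuator
        again = model.atom._attention(Tensor(x), np.ones((1, 4, 4)), mask,
                                      "atom.graph.0")
        assert np.allclose(focused.data, again.data)

    def test_padded_scores_excluded_from_softmax_simplex(self):
        scores = np.zeros((1, 1, 3, 3))
        neg = np.where(np.array([[True, True, False]])[:, None, None, :],
                       0.0, -1e9)
        probs = softmax(Tensor(scores) + Tensor(neg))
        rows = probs.data[0, 0, :, :2].sum(axis=-1)
        assert np.allclose(rows, 1.0, atol=1e-6)

    def test_matmul_strength_mode_runs(self):
        model = tiny_model(n_max=4, atom={"strength_mode": "matmul"})
        rng = np.random.default_rng(3)
        b = random_batch(rng, B=2, N=4)
        out, _ = model.atom.forward(b["node"], b["bond"],
                                    b["strength_graph"], b["strength_conf"],
                                    b["atom_mask"])
        assert np.all(np.isfinite(out.data))


class TestAtomForward:
    @pytest.mark.parametrize("lam, varies", [(1.0, "strength_conf"),
                                             (0.0, "strength_graph")])
    def test_lambda_extremes_silence_one_block(self, lam, varies):
        model = tiny_model(n_max=5, atom={"lambda_g": lam})
        rng = np.random.default_rng(4)
        b1 = random_batch(rng, B=2, N=5)
        b2 = dict(b1)
        other = random_batch(np.random.default_rng(5), B=2, N=5)
        b2[varies] = other[varies]
        o1, _ = model.atom.forward(b1["node"], b1["bond"],
                                   b1["strength_graph"], b1["strength_conf"],
                                   b1["atom_mask"])
        o2, _ = model.atom.forward(b2["node"], b2["bond"],
                                   b2["strength_graph"], b2["strength_conf"],
                                   b2["atom_mask"])
        assert np.allclose(o1.data, o2.data, atol=1e-6)


class TestMonomerForward:
    def test_cyclic_conv_invariant_under_rotation_at_full_length(
            self, float64_engine):
        model = tiny_model(n_max=4, monomer={"conv_kind": "cyclic"})
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(1, 12, 16))
        mask = np.ones((1, 12), dtype=bool)
        base, _ = model.monomer.forward(mat, mask)
        for shift in (1, 5, 11):
            rot, _ = model.monomer.forward(np.roll(mat, shift, axis=1), mask)
            assert np.allclose(rot.data, base.data, atol=1e-9)

    def test_plain_and_cyclic_generally_differ(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(1, 8, 16))
        mask = np.ones((1, 8), dtype=bool)
        plain = tiny_model(n_max=4, seed=1).monomer.forward(mat, mask)[0]
        cyc = tiny_model(n_max=4, seed=1,
                         monomer={"conv_kind": "cyclic"}
                         ).monomer.forward(mat, mask)[0]
        assert not np.allclose(plain.data, cyc.data, atol=1e-6)

    def test_zero_matrix_zero_bias_gives_bias_latent(self):
        model = tiny_model(n_max=4)
        out, _ = model.monomer.forward(np.zeros((1, 6, 16)),
                                       np.ones((1, 6), dtype=bool))
        assert np.allclose(out.data, model.params["monomer.head.b"].data,
                           atol=1e-6)


class TestPeptideForward:
    def test_fp_branch_isolated_when_desc_weights_zero(self):
        model = tiny_model(n_max=4)
        model.params["peptide.desc.0.W"].data[:] = 0.0
        rng = np.random.default_rng(8)
        fp = (rng.random((2, 2048)) < 0.05).astype(float)
        o1, _ = model.peptide.forward(rng.random((2, 16)), fp)
        o2, _ = model.peptide.forward(rng.random((2, 16)), fp)
        assert np.allclose(o1.data, o2.data, atol=1e-6)
        o3, _ = model.peptide.forward(np.zeros((2, 16)),
                                      (rng.random((2, 2048)) < 0.05
                                       ).astype(float))
        assert not np.allclose(o1.data, o3.data, atol=1e-6)

    def test_hand_computed_two_sample_toy(self, float64_engine):
        model = tiny_model(n_max=2, peptide={"hidden": 3, "n_layers": 1,
                                             "latent": 2, "n_desc": 2,
                                             "n_fp": 2})
        P = model.params
        desc = np.array([[1.0, -1.0], [0.5, 2.0]])
        fp = np.array([[1.0, 0.0], [0.0, 1.0]])
        hd = np.maximum(desc @ P["peptide.desc.0.W"].data
                        + P["peptide.desc.0.b"].data, 0.0)
        hf = np.maximum(fp @ P["peptide.fp.0.W"].data
                        + P["peptide.fp.0.b"].data, 0.0)
        expected = (np.concatenate([hd, hf], axis=1)
                    @ P["peptide.head.W"].data + P["peptide.head.b"].data)
        out, _ = model.peptide.forward(desc, fp)
        assert np.allclose(out.data, expected, atol=1e-12)


class TestFusion:
    def test_deterministic_forward(self):
        model = tiny_model(n_max=5)
        batch = random_batch(np.random.default_rng(9), B=2, N=5)
        assert np.array_equal(model.predict(batch), model.predict(batch))

    def test_shared_layer_can_route_a_latent_coordinate(self, float64_engine):
        model = tiny_model(n_max=5)
        P = model.params
        # route out_peptide[0] through relu(x) - relu(-x) = x
        P["fusion.W1"].data[:] = 0.0
        P["fusion.b1"].data[:] = 0.0
        P["fusion.W2"].data[:] = 0.0
        P["fusion.b2"].data[:] = 0.0
        j = model.atom_cfg.latent + model.monomer_cfg.latent  # first peptide dim
        P["fusion.W1"].data[j, 0] = 1.0
        P["fusion.W1"].data[j, 1] = -1.0
        P["fusion.W2"].data[0, 0] = 1.0
        P["fusion.W2"].data[1, 0] = -1.0
        batch = random_batch(np.random.default_rng(10), B=3, N=5)
        bundle, _ = model.forward(batch)
        assert np.allclose(bundle.out_fusion.data[:, 0],
                           bundle.out_peptide.data[:, 0], atol=1e-12)


class TestLosses:
    def test_unit_component_losses_combine_to_1_45(self):
        assert LossBreakdown.combine(1, 1, 1, 1, 1, 1, 1) == pytest.approx(
            1.45, abs=1e-12)

    def test_zero_gammas_reduce_total_to_fusion_loss(self):
        model = tiny_model(n_max=5, fusion={"gamma_sub": 0.0,
                                            "gamma_layer": 0.0})
        batch = random_batch(np.random.default_rng(11), B=3, N=5)
        bundle, layers = model.forward(batch)
        total, br = model.total_loss(bundle, layers, batch["label"])
        assert total.item() == pytest.approx(br.L_fusion, rel=1e-6)

    def test_breakdown_satisfies_combination_invariant(self):
        model = tiny_model(n_max=5)
        batch = random_batch(np.random.default_rng(12), B=3, N=5)
        bundle, layers = model.forward(batch)
        total, br = model.total_loss(bundle, layers, batch["label"])
        assert br.total == pytest.approx(
            LossBreakdown.combine(br.L_fusion, br.L_atom, br.L_monomer,
                                  br.L_peptide, br.L_layer_a, br.L_layer_m,
                                  br.L_layer_p), rel=1e-5)
        assert br.total >= br.L_fusion - 1e-9

    def test_gradients_reach_every_branch(self):
        model = tiny_model(n_max=5)
        batch = random_batch(np.random.default_rng(13), B=4, N=5)
        bundle, layers = model.forward(batch)
        total, _ = model.total_loss(bundle, layers, batch["label"])
        total.backward()
        for prefix in ("atom.", "monomer.", "peptide.", "fusion."):
            grads = [np.abs(t.grad).max() for k, t in model.params.items()
                     if k.startswith(prefix) and t.grad is not None]
            assert grads and max(grads) > 0.0


class TestMaskInvariance:
    def test_padding_never_changes_branch_outputs(self, float64_engine):
        """Appending padded atoms / monomer rows leaves every branch output
        unchanged (within 1e-6)."""
        model = tiny_model(n_max=9)
        rng = np.random.default_rng(14)
        b = random_batch(rng, B=2, N=6, L=4)
        # embed the same content into a wider frame
        wide = {
            "node": np.zeros((2, 9, 30)), "bond": np.zeros((2, 9, 9)),
            "strength_graph": np.zeros((2, 9, 9)),
            "strength_conf": np.zeros((2, 9, 9)),
            "atom_mask": np.zeros((2, 9), dtype=bool),
            "monomer": np.zeros((2, 7, 16)),
            "monomer_mask": np.zeros((2, 7), dtype=bool),
            "desc": b["desc"], "fp": b["fp"], "label": b["label"],
        }
        wide["node"][:, :6] = b["node"]
        wide["bond"][:, :6, :6] = b["bond"]
        wide["strength_graph"][:, :6, :6] = b["strength_graph"]
        wide["strength_conf"][:, :6, :6] = b["strength_conf"]
        wide["atom_mask"][:, :6] = True
        wide["monomer"][:, :4] = b["monomer"]
        wide["monomer_mask"][:, :4] = True

        narrow_model = tiny_model(n_max=6)
        # share the identically-shaped parameters; W_bond rows beyond n=6
        # are multiplied by zero columns so only the first 6 rows matter
        for k, t in narrow_model.params.items():
            if k == "atom.W_bond":
                model.params[k].data[:6] = t.data
                model.params[k].data[6:] = 123.0  # must be inert
            else:
                model.params[k].data = t.data.copy()
        bundle_n, _ = narrow_model.forward(b)
        bundle_w, _ = model.forward(wide)
        for attr in ("out_atom", "out_monomer", "out_peptide", "out_fusion"):
            assert np.allclose(getattr(bundle_n, attr).data,
                               getattr(bundle_w, attr).data, atol=1e-6)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        model = tiny_model(n_max=5, seed=2)
        batch = random_batch(np.random.default_rng(15), B=2, N=5)
        before = model.predict(batch)
        cp.save_checkpoint(tmp_path / "ck.npz", model, extra={"note": "x"})
        loaded, extra = cp.load_checkpoint(tmp_path / "ck.npz")
        assert extra["note"] == "x"
        assert np.allclose(loaded.predict(batch), before, atol=1e-7)
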
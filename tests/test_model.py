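"""Encoder architecture: attention, matrix embedding, selectivity, heads."""

import time

import numpy as np
import pytest

from chemlm import mol_io
from chemlm.autograd import Tensor
from chemlm.model import (MatrixEmbedding, ModelConfig, MolecularEncoder,
                          TaskHead, atom_scatter_matrix, load_checkpoint,
                          pad_adjacency, prepare_batch, save_checkpoint,
                          scaled_dot_attention)
from chemlm.pretraining import encode_corpus
from chemlm.tokenizer import build_vocab


@pytest.fixture(scope="module")
def encoder_setup(smiles_panel, tiny_cfg):
    vocab = build_vocab(smiles_panel)
    model = MolecularEncoder(tiny_cfg, len(vocab), seed=7)
    data = encode_corpus(smiles_panel, vocab, tiny_cfg)
    return vocab, model, data


class TestScaledDotAttention:
    def test_single_unmasked_key_returns_value_row(self, rng):
        q = Tensor(rng.normal(size=(1, 4)))
        k = Tensor(rng.normal(size=(3, 4)))
        v = Tensor(rng.normal(size=(3, 4)))
        mask = np.array([False, True, False])
        out = scaled_dot_attention(q, k, v, mask)
        np.testing.assert_allclose(out.data[0], v.data[1], rtol=1e-9)

    def test_equal_logits_average_unmasked_values(self, rng):
        q = Tensor(np.zeros((1, 4)))  # zero query: all logits equal
        k = Tensor(rng.normal(size=(5, 4)))
        v = Tensor(rng.normal(size=(5, 4)))
        mask = np.array([True, True, True, False, False])
        out = scaled_dot_attention(q, k, v, mask)
        np.testing.assert_allclose(out.data[0], v.data[:3].mean(axis=0),
                                   rtol=1e-9)

    def test_weights_normalize_over_unmasked_keys(self, rng):
        q = Tensor(rng.normal(size=(6, 4)))
        k = Tensor(rng.normal(size=(6, 4)))
        mask = np.array([True, True, True, True, False, False])
        scores = (q @ k.transpose(1, 0)) * 0.5
        biased = scores + Tensor(np.where(mask, 0.0, -1e9))
        w = biased.softmax(axis=-1).data
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, rtol=1e-12)
        assert (w[:, ~mask] < 1e-20).all()


class TestMatrixEmbedding:
    def test_zero_adjacency_yields_bias(self, tiny_cfg, rng):
        emb = MatrixEmbedding(tiny_cfg, rng)
        emb.bias.data = rng.normal(size=tiny_cfg.d_model)
        out = emb(np.zeros((tiny_cfg.max_atoms, tiny_cfg.max_atoms)))
        np.testing.assert_allclose(
            out.data, np.tile(emb.bias.data, (tiny_cfg.max_atoms, 1)))

    def test_affine_in_adjacency(self, tiny_cfg, rng):
        emb = MatrixEmbedding(tiny_cfg, rng)
        m = tiny_cfg.max_atoms
        a1 = (rng.random((m, m)) < 0.2).astype(float)
        a2 = (rng.random((m, m)) < 0.2).astype(float)
        b = emb(np.zeros((m, m))).data
        lhs = emb(a1 + a2).data - b
        rhs = (emb(a1).data - b) + (emb(a2).data - b)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_benzene_matches_hand_multiplied_matrices(self, tiny_cfg, rng):
        emb = MatrixEmbedding(tiny_cfg, rng)
        a = pad_adjacency(mol_io.adjacency(mol_io.parse_smiles("c1ccccc1")),
                          tiny_cfg.max_atoms)
        expected = a @ emb.w_a.data @ emb.w_e.data + emb.bias.data
        np.testing.assert_allclose(emb(a).data, expected, atol=1e-6)

    def test_oversized_molecule_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            pad_adjacency(np.zeros((tiny_cfg.max_atoms + 1,
                                    tiny_cfg.max_atoms + 1)),
                          tiny_cfg.max_atoms)


class TestSelectiveEmbedding:
    def test_perturbing_adjacency_touches_only_atomic_positions(
            self, encoder_setup, tiny_cfg, rng):
        _, model, data = encoder_setup
        for d in data[:20]:
            ids, a, scatter, mask = prepare_batch([d.enc], [d.adj], tiny_cfg,
                                                  crop=False)
            base = model.embed(ids, a, scatter).data
            a2 = a.copy()
            n = d.adj.shape[0]
            a2[0, :n, :n] = 1 - np.eye(n)  # different connectivity
            pert = model.embed(ids, a2, scatter).data
            changed = np.where(np.abs(pert - base).max(axis=-1)[0] > 1e-12)[0]
            assert set(changed) <= set(d.enc.atom_positions)

    def test_ethanol_changes_exactly_three_positions(self, encoder_setup,
                                                     tiny_cfg):
        vocab, model, _ = encoder_setup
        data = encode_corpus(["CCO"], vocab, tiny_cfg)[0]
        ids, a, scatter, mask = prepare_batch([data.enc], [data.adj], tiny_cfg,
                                              crop=False)
        base = model.embed(ids, a, scatter).data
        zero = model.embed(ids, np.zeros_like(a), scatter).data
        n_changed = int((np.abs(base - zero).max(axis=-1)[0] > 1e-12).sum())
        assert n_changed == 3

    def test_zero_adjacency_zero_bias_reduces_to_token_plus_position(
            self, encoder_setup, tiny_cfg):
        vocab, model, data = encoder_setup
        d = data[0]
        ids, a, scatter, _ = prepare_batch([d.enc], [d.adj], tiny_cfg,
                                           crop=False)
        saved = model.matrix_emb.bias.data.copy()
        model.matrix_emb.bias.data = np.zeros_like(saved)
        try:
            out = model.embed(ids, np.zeros_like(a), scatter).data
            expected = (model.tok_emb.weight.data[ids]
                        + model.pos_emb.weight.data[:ids.shape[1]])
            np.testing.assert_allclose(out, expected, atol=1e-12)
        finally:
            model.matrix_emb.bias.data = saved

    def test_misaligned_atom_count_raises(self, encoder_setup, tiny_cfg):
        _, _, data = encoder_setup
        d = data[0]
        with pytest.raises(ValueError, match="misalignment"):
            atom_scatter_matrix(d.enc, d.adj.shape[0] + 1,
                                tiny_cfg.max_len, tiny_cfg.max_atoms)


class TestEncoderForward:
    def test_zero_layers_is_identity(self, smiles_panel):
        cfg = ModelConfig.tiny(n_layers=0)
        vocab = build_vocab(smiles_panel)
        model = MolecularEncoder(cfg, len(vocab), seed=0)
        data = encode_corpus(smiles_panel[:4], vocab, cfg)
        ids, a, sc, mask = prepare_batch([d.enc for d in data],
                                         [d.adj for d in data], cfg)
        h = model.embed(ids, a, sc)
        out = model.encoder_forward(h, mask)
        np.testing.assert_array_equal(out.data, h.data)

    def test_outputs_finite_on_random_inputs(self, encoder_setup, tiny_cfg,
                                             rng):
        _, model, _ = encoder_setup
        h = Tensor(rng.normal(size=(100, 12, tiny_cfg.d_model)) * 5)
        mask = rng.random((100, 12)) < 0.8
        mask[:, 0] = True
        out = model.encoder_forward(h, mask).data
        assert np.isfinite(out).all()

    def test_pad_token_id_does_not_leak_into_real_positions(
            self, encoder_setup, tiny_cfg):
        vocab, model, data = encoder_setup
        d = data[0]
        ids, a, sc, mask = prepare_batch([d.enc], [d.adj], tiny_cfg,
                                         crop=False)
        base = model.forward(ids, a, sc, mask).data
        ids2 = ids.copy()
        ids2[0, -1] = vocab.id_of("C")  # corrupt a PAD slot
        assert not mask[0, -1]
        pert = model.forward(ids2, a, sc, mask).data
        real = mask[0]
        np.testing.assert_allclose(pert[0, real], base[0, real], atol=1e-9)

    def test_forward_deterministic(self, encoder_setup, tiny_cfg):
        _, model, data = encoder_setup
        d = data[0]
        ids, a, sc, mask = prepare_batch([d.enc], [d.adj], tiny_cfg)
        out1 = model.forward(ids, a, sc, mask).data
        out2 = model.forward(ids, a, sc, mask).data
        np.testing.assert_array_equal(out1, out2)

    def test_batch_crop_matches_full_padding(self, encoder_setup, tiny_cfg):
        _, model, data = encoder_setup
        chunk = data[:8]
        full = prepare_batch([d.enc for d in chunk], [d.adj for d in chunk],
                             tiny_cfg, crop=False)
        cropped = prepare_batch([d.enc for d in chunk],
                                [d.adj for d in chunk], tiny_cfg, crop=True)
        out_full = model.forward(*full).data
        out_crop = model.forward(*cropped).data
        l_eff = out_crop.shape[1]
        np.testing.assert_allclose(out_full[:, :l_eff], out_crop, atol=1e-9)

    def test_tiny_batch_forward_under_one_second(self, encoder_setup,
                                                 tiny_cfg):
        _, model, data = encoder_setup
        chunk = (data * 2)[:64]
        batch = prepare_batch([d.enc for d in chunk],
                              [d.adj for d in chunk], tiny_cfg)
        model.forward(*batch)  # warm-up allocation
        t0 = time.perf_counter()
        model.forward(*batch)
        assert time.perf_counter() - t0 < 1.0


class TestHeads:
    def test_mlm_logits_shape_and_argmax(self, encoder_setup, tiny_cfg):
        vocab, model, data = encoder_setup
        chunk = data[:4]
        batch = prepare_batch([d.enc for d in chunk], [d.adj for d in chunk],
                              tiny_cfg)
        logits = model.mlm_head(model.forward(*batch)).data
        assert logits.shape == (4, batch[0].shape[1], len(vocab))
        assert np.isfinite(logits).all()

    def test_untrained_mlm_near_uniform(self, encoder_setup):
        vocab, model, data = encoder_setup
        d = data[0]
        batch = prepare_batch([d.enc], [d.adj], model.cfg)
        logits = model.mlm_head(model.forward(*batch))
        probs = logits.softmax(axis=-1).data
        uniform = 1.0 / len(vocab)
        assert np.abs(probs - uniform).max() < 5 * uniform

    def test_qed_head_in_unit_interval_and_first_position_only(
            self, encoder_setup, tiny_cfg, rng):
        _, model, data = encoder_setup
        chunk = data[:4]
        batch = prepare_batch([d.enc for d in chunk], [d.adj for d in chunk],
                              tiny_cfg)
        out = model.forward(*batch)
        q = model.qed_head(out).data
        assert ((q > 0) & (q < 1)).all()
        perturbed = out.data.copy()
        perturbed[:, 1:, :] += rng.normal(size=perturbed[:, 1:, :].shape)
        q2 = model.qed_head(Tensor(perturbed)).data
        np.testing.assert_array_equal(q, q2)

    def test_task_head_multi_task_and_errors(self, tiny_cfg, rng):
        head = TaskHead(tiny_cfg.d_model, 12, rng)
        out = Tensor(rng.normal(size=(5, 7, tiny_cfg.d_model)))
        assert head(out).shape == (5, 12)
        with pytest.raises(ValueError):
            TaskHead(tiny_cfg.d_model, 0, rng)

    def test_task_outputs_are_independent_affine_maps(self, tiny_cfg, rng):
        head = TaskHead(tiny_cfg.d_model, 3, rng)
        out = Tensor(rng.normal(size=(2, 4, tiny_cfg.d_model)))
        base = head(out).data
        head.proj.weight.data[:, 1] += 1.0  # shift only task 1
        shifted = head(out).data
        np.testing.assert_array_equal(base[:, [0, 2]], shifted[:, [0, 2]])
        assert (base[:, 1] != shifted[:, 1]).all()


class TestCheckpoint:
    def test_roundtrip_preserves_forward(self, encoder_setup, tiny_cfg,
                                         tmp_path):
        vocab, model, data = encoder_setup
        save_checkpoint(tmp_path / "ck", model, vocab)
        model2, vocab2 = load_checkpoint(tmp_path / "ck")
        assert len(vocab2) == len(vocab)
        d = data[0]
        batch = prepare_batch([d.enc], [d.adj], tiny_cfg)
        np.testing.assert_array_equal(model.forward(*batch).data,
                                      model2.forward(*batch).data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=10, n_heads=3)
        with pytest.raises(ValueError):
            ModelConfig(dropout=0.5)
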
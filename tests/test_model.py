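"""Network heads: shapes, masking, parameter counts, checkpoints, inference."""

import dataclasses
import logging

import numpy as np
import pytest

from jointcws import (
    JointModel,
    JointModelConfig,
    analytic_parameter_count,
    load_checkpoint,
    make_batches,
    save_checkpoint,
)
from jointcws.corpus import Batch


def _single_batch(records, vocab, n=8):
    return make_batches(records[:n], vocab, batch_size=n)[0]


class TestEmbedding:
    def test_pad_positions_embed_to_zero(self, small_batches, tiny_model_config):
        model = JointModel(tiny_model_config)
        batch = small_batches[0]
        emb = model.embed(batch.indices)
        assert np.all(emb.data[~batch.mask] == 0.0)

    def test_same_index_same_vector(self, tiny_model_config):
        model = JointModel(tiny_model_config)
        idx = np.array([[5, 5, 7]])
        emb = model.embed(idx).data
        assert np.array_equal(emb[0, 0], emb[0, 1])
        assert not np.array_equal(emb[0, 0], emb[0, 2])

    def test_out_of_range_index_rejected(self, tiny_model_config):
        model = JointModel(tiny_model_config)
        with pytest.raises(ValueError):
            model.embed(np.array([[tiny_model_config.vocab_size]]))

    def test_output_shape(self, small_batches, tiny_model_config):
        model = JointModel(tiny_model_config)
        for batch in small_batches[:3]:
            emb = model.embed(batch.indices)
            assert emb.shape == (batch.size, batch.max_len, tiny_model_config.embedding_dim)

    def test_pad_row_never_updated(self, small_corpus, small_vocab, tiny_model_config):
        from jointcws.losses import class_loss, masked_tag_loss
        from jointcws.training import Adam, _apply_grad_masks

        model = JointModel(tiny_model_config)
        batch = _single_batch(small_corpus, small_vocab)
        opt = Adam(model.parameters(), lr=0.01)
        out = model.forward(batch)
        loss = masked_tag_loss(out.tag_scores, batch.tag_targets, batch.mask) + class_loss(
            out.class_scores, batch.labels
        )
        loss.backward()
        _apply_grad_masks(model.parameters())
        opt.step()
        assert np.all(model.embedding.data[model.pad_index] == 0.0)


class TestHeads:
    def test_forward_shapes(self, small_batches, tiny_model_config):
        model = JointModel(tiny_model_config)
        batch = small_batches[0]
        out = model.forward(batch)
        assert out.tag_scores.shape == (batch.size, batch.max_len, 3)
        assert out.class_scores.shape == (batch.size, 2)
        assert np.isfinite(out.tag_scores.data).all()
        assert np.isfinite(out.class_scores.data).all()

    def test_single_character_input(self, tiny_model_config):
        model = JointModel(tiny_model_config)
        batch = Batch(
            indices=np.array([[4]]),
            tag_targets=np.array([[2]]),
            labels=np.array([1]),
            mask=np.array([[True]]),
        )
        out = model.forward(batch)
        assert out.tag_scores.shape == (1, 1, 3)
        assert out.class_scores.shape == (1, 2)

    def test_class_scores_invariant_to_extra_padding(self, small_corpus, small_vocab,
                                                     tiny_model_config):
        model = JointModel(tiny_model_config)
        batch = _single_batch(small_corpus, small_vocab)
        base = model.forward(batch)
        extra = 4
        pad = lambda a, fill: np.concatenate(
            [a, np.full((a.shape[0], extra), fill, dtype=a.dtype)], axis=1
        )
        padded = Batch(
            indices=pad(batch.indices, 0),
            tag_targets=pad(batch.tag_targets, 0),
            labels=batch.labels,
            mask=pad(batch.mask, False),
        )
        out = model.forward(padded)
        assert np.allclose(out.class_scores.data, base.class_scores.data)

    def test_maxpool_unchanged_by_duplicated_best_window(self, tiny_model_config):
        # width-1 kernels: windows are single characters, so duplicating the
        # max-activating character cannot change the pooled features
        cfg = dataclasses.replace(tiny_model_config, conv_kernel_widths=(1,))
        model = JointModel(cfg)
        idx = np.array([[3, 4, 5, 6]])
        mask = np.ones_like(idx, dtype=bool)
        batch = Batch(idx, np.zeros_like(idx), np.array([0]), mask)
        base = model.forward(batch, run_tagger=False).class_scores.data
        for dup in range(4):  # duplication only adds equal-valued candidates
            idx2 = np.concatenate([idx, [[idx[0, dup]]]], axis=1)
            batch2 = Batch(idx2, np.zeros_like(idx2), np.array([0]),
                           np.ones_like(idx2, dtype=bool))
            out2 = model.forward(batch2, run_tagger=False).class_scores.data
            assert np.allclose(out2, base)
        # duplicating every character at once: still the same maxima
        idx3 = np.concatenate([idx, idx], axis=1)
        batch3 = Batch(idx3, np.zeros_like(idx3), np.array([0]),
                       np.ones_like(idx3, dtype=bool))
        assert np.allclose(
            model.forward(batch3, run_tagger=False).class_scores.data, base
        )

    def test_all_pad_row_warns_but_is_defined(self, tiny_model_config, caplog):
        model = JointModel(tiny_model_config)
        idx = np.zeros((1, 5), dtype=np.int64)
        batch = Batch(idx, np.zeros_like(idx), np.array([0]),
                      np.zeros_like(idx, dtype=bool))
        with caplog.at_level(logging.WARNING, logger="jointcws.model"):
            out = model.forward(batch, run_tagger=False)
        assert np.isfinite(out.class_scores.data).all()
        assert any("padding-only" in r.message for r in caplog.records)

    def test_sentence_shorter_than_widest_kernel(self, tiny_model_config):
        model = JointModel(tiny_model_config)  # widths (3, 5)
        idx = np.array([[2, 3]])
        batch = Batch(idx, np.zeros_like(idx), np.array([0]),
                      np.ones_like(idx, dtype=bool))
        out = model.forward(batch)
        assert out.class_scores.shape == (1, 2)
        assert np.isfinite(out.class_scores.data).all()

    def test_sequence_reversal_symmetry_with_tied_directions(self, tiny_model_config):
        """With backward weights tied to forward ones and a direction-symmetric
        output map, reversing the input reverses the tag scores."""
        model = JointModel(tiny_model_config)
        H = tiny_model_config.recurrent_hidden
        for name in ("w_x", "w_h", "b"):
            getattr(model.bwd, name).data = getattr(model.fwd, name).data.copy()
        model.tag_w.data[H:] = model.tag_w.data[:H]
        idx = np.array([[3, 4, 5, 6, 7]])
        mask = np.ones_like(idx, dtype=bool)
        fwd_scores = model.forward(
            Batch(idx, np.zeros_like(idx), np.array([0]), mask), run_classifier=False
        ).tag_scores.data[0]
        rev_scores = model.forward(
            Batch(idx[:, ::-1].copy(), np.zeros_like(idx), np.array([0]), mask),
            run_classifier=False,
        ).tag_scores.data[0]
        assert np.allclose(rev_scores, fwd_scores[::-1], atol=1e-10)


class TestParameterCount:
    @pytest.mark.parametrize(
        "changes",
        [
            {},
            {"conv_kernel_widths": (2, 3, 4)},
            {"include_classifier": False},
            {"include_tagger": False, "use_boundary_features": True},
            {"embedding_dim": 24, "recurrent_hidden": 16},
        ],
    )
    def test_analytic_formula_matches_actual(self, tiny_model_config, changes):
        cfg = dataclasses.replace(tiny_model_config, **changes)
        assert JointModel(cfg).count_parameters() == analytic_parameter_count(cfg)

    def test_default_architecture_lands_near_reported_budget(self):
        """~0.47 M parameters at the defaults with a few hundred characters."""
        cfg = JointModelConfig(vocab_size=800)
        assert abs(analytic_parameter_count(cfg) - 470_000) / 470_000 < 0.05


class TestInference:
    def test_forward_deterministic_without_dropout(self, small_batches, tiny_model_config):
        model = JointModel(tiny_model_config)
        batch = small_batches[0]
        a = model.forward(batch)
        b = model.forward(batch)
        assert np.array_equal(a.tag_scores.data, b.tag_scores.data)
        assert np.array_equal(a.class_scores.data, b.class_scores.data)

    def test_predict_contract(self, small_corpus, small_vocab, tiny_model_config):
        model = JointModel(tiny_model_config)
        rec = small_corpus[0]
        words, label, prob = model.predict(rec, small_vocab)
        assert "".join(words) == "".join(rec.chars)  # total coverage
        assert label in (0, 1)
        assert 0.5 <= prob <= 1.0  # argmax class probability
        again = model.predict(rec, small_vocab)
        assert again == (words, label, prob)

    def test_predict_rejects_empty(self, small_vocab, tiny_model_config):
        with pytest.raises(ValueError):
            JointModel(tiny_model_config).predict("", small_vocab)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, small_corpus, small_vocab,
                                         tiny_model_config):
        model = JointModel(tiny_model_config)
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, model, small_vocab)
        loaded, vocab = load_checkpoint(path)
        assert vocab.char_to_index == small_vocab.char_to_index
        batch = _single_batch(small_corpus, small_vocab)
        a = model.forward(batch)
        b = loaded.forward(batch)
        assert np.array_equal(a.tag_scores.data, b.tag_scores.data)
        assert np.array_equal(a.class_scores.data, b.class_scores.data)

    def test_tampered_vocabulary_detected(self, tmp_path, small_vocab, tiny_model_config):
        import json

        model = JointModel(tiny_model_config)
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, model, small_vocab)
        payload = json.loads(path.read_text())
        key = next(iter(payload["vocabulary"]["char_to_index"]))
        payload["vocabulary"]["char_to_index"][key] = 99_999
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(path)
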
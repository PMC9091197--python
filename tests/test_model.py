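"""Relation classifier: tokenization, training, MLM fine-tuning, grid search."""

import numpy as np
import pytest

from herbkg import nn
from herbkg.dataset import REExample
from herbkg.metrics import class_metrics, confusion_matrix
from herbkg.model import (
    EncoderConfig,
    TrainConfig,
    WordTokenizer,
    default_grid,
    domain_finetune_mlm,
    enumerate_grid,
    grid_search,
    load_classifier,
    predict,
    predict_batch,
    save_classifier,
    tokenize_pair,
    train_classifier,
)
from herbkg.ontology import RelationType
from herbkg.simulate import GeneratorSpec, generate_corpus, make_separable_re_set


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full encoder+head agree with central
        finite differences at every sampled coordinate."""
        rng = np.random.default_rng(0)
        params = nn.init_params(2, 2, 8, 16, 12, 6, seed=1)
        ids = rng.integers(5, 12, size=(3, 7))
        seg = (rng.random((3, 7)) < 0.5).astype(np.intp)
        mask = np.ones((3, 7))
        mask[0, 5:] = 0
        labels = np.array([0, 3, 5])

        def loss_fn(p):
            hidden, cache = nn.encoder_forward(p, ids, seg, mask)
            logits, hc = nn.pooled_head_forward(p, hidden, mask)
            loss, dlogits, _ = nn.cross_entropy(logits, labels)
            return loss, (cache, hc, dlogits, hidden)

        _, (cache, hc, dlogits, hidden) = loss_fn(params)
        grads, dh = nn.pooled_head_backward(params, dlogits, hc, hidden.shape)
        grads.update(nn.encoder_backward(params, cache, dh))
        eps = 1e-6
        for name, grad in grads.items():
            flat = params[name].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = loss_fn(params)
                flat[i] = orig - eps
                lm, _ = loss_fn(params)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert np.isclose(numeric, grad.ravel()[i], rtol=1e-3, atol=1e-7), name


class TestTokenization:
    @pytest.fixture
    def tok(self):
        return WordTokenizer.build(
            ["short title. short abstract. filler words", "cassia bark cinnamaldehyde"]
        )

    def test_segment_ids_switch_once_after_first_separator(self, tok):
        ex = REExample("short title. short abstract.", "cassia bark", "cinnamaldehyde",
                       RelationType.HHC)
        pair = tokenize_pair(ex, tok, EncoderConfig.tiny())
        switches = [
            i for i in range(1, len(pair.segment_ids))
            if pair.segment_ids[i] != pair.segment_ids[i - 1]
        ]
        assert switches == [pair.sep_positions[0] + 1]

    def test_empty_sentence_a_yields_two_separators_plus_b(self, tok):
        ex = REExample("", "cassia", "bark", RelationType.HHC)
        pair = tokenize_pair(ex, tok, EncoderConfig.tiny())
        assert pair.token_ids[0] == tok.stoi["[SEP]"]
        assert pair.token_ids[-1] == tok.stoi["[SEP]"]
        assert len(pair.token_ids) == 4  # [SEP] cassia bark [SEP]

    def test_sentence_a_tail_truncated_b_never(self, tok):
        ex = REExample("filler " * 100, "cassia bark", "cinnamaldehyde", RelationType.HHC)
        cfg = EncoderConfig.tiny(max_seq_len=16)
        pair = tokenize_pair(ex, tok, cfg)
        assert len(pair.token_ids) == 16
        b_ids = pair.token_ids[pair.sep_positions[0] + 1 : -1]
        assert tok.decode(b_ids) == ex.sentence_b

    def test_oversized_sentence_b_is_an_error(self, tok):
        ex = REExample("t", "word " * 40, "tail", RelationType.HHC)
        with pytest.raises(ValueError, match="sentence B"):
            tokenize_pair(ex, tok, EncoderConfig.tiny(max_seq_len=16))

    def test_detokenized_sentence_b_is_identity(self, corpus, separable_set):
        tok = WordTokenizer.build(
            [e.sentence_a for e in separable_set] + [e.sentence_b for e in separable_set]
        )
        cfg = EncoderConfig.tiny()
        for ex in separable_set[:12]:
            pair = tokenize_pair(ex, tok, cfg)
            b_ids = pair.token_ids[pair.sep_positions[0] + 1 : -1]
            assert tok.decode(b_ids) == ex.sentence_b


class TestTraining:
    def test_tiny_preset_overfits_separable_fixture(self, overfit_state, separable_set):
        preds = [p.argmax for p in predict_batch(overfit_state, separable_set)]
        accuracy = np.mean([p is e.label for p, e in zip(preds, separable_set)])
        assert accuracy == 1.0

    def test_zero_learning_rate_leaves_predictions_untouched(self, separable_set, tiny_enc):
        frozen = train_classifier(
            separable_set, tiny_enc,
            TrainConfig(epochs=1, learning_rate=0.0, seed=3),
        )
        untrained = train_classifier(
            separable_set, tiny_enc,
            TrainConfig(epochs=0, learning_rate=0.001, seed=3),
        )
        ex = separable_set[0]
        assert predict(frozen, ex).scores == predict(untrained, ex).scores

    def test_equal_weights_reproduce_plain_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(10, 6))
        labels = rng.integers(0, 6, size=10)
        plain, _, _ = nn.cross_entropy(logits, labels)
        weighted, _, _ = nn.cross_entropy(logits, labels, class_weights=np.ones(6))
        assert weighted == pytest.approx(plain, abs=1e-12)

    def test_unknown_label_rejected_before_training(self, tiny_enc):
        ex = REExample("a", "b", "c", "BOGUS")  # not one of the six labels
        with pytest.raises(ValueError, match="label outside"):
            train_classifier([ex], tiny_enc, TrainConfig(epochs=1))

    def test_training_is_seed_deterministic(self, separable_set, tiny_enc):
        tc = TrainConfig(epochs=2, learning_rate=0.001, seed=5)
        s1 = train_classifier(separable_set[:24], tiny_enc, tc)
        s2 = train_classifier(separable_set[:24], tiny_enc, tc)
        for k in ("cls.w", "l0.wq", "tok_emb"):
            assert np.array_equal(s1.params[k], s2.params[k])


class TestPrediction:
    def test_distribution_is_valid_on_arbitrary_input(self, overfit_state):
        ex = REExample("totally unseen words here", "alpha", "beta", RelationType.NEG)
        dist = predict(overfit_state, ex)
        arr = dist.as_array()
        assert (arr >= 0).all()
        assert arr.sum() == pytest.approx(1.0, abs=1e-6)

    def test_overfit_model_recalls_every_training_label(self, overfit_state, separable_set):
        for ex in separable_set:
            assert predict(overfit_state, ex).argmax is ex.label

    def test_inference_is_deterministic(self, overfit_state, separable_set):
        ex = separable_set[7]
        assert predict(overfit_state, ex) == predict(overfit_state, ex)

    def test_save_load_round_trip(self, overfit_state, separable_set, tmp_path):
        save_classifier(overfit_state, tmp_path / "clf")
        loaded = load_classifier(tmp_path / "clf")
        ex = separable_set[3]
        assert predict(loaded, ex).scores == pytest.approx(
            predict(overfit_state, ex).scores
        )


class TestMLMFineTuning:
    def test_heldout_masked_loss_strictly_decreases(self, mlm_result):
        assert mlm_result.final_heldout_loss < mlm_result.initial_heldout_loss

    def test_zero_steps_leaves_checkpoint_unchanged(self, tiny_enc):
        docs, _ = generate_corpus(GeneratorSpec(seed=21, n_docs=20))
        res = domain_finetune_mlm(docs, tiny_enc, steps=0, seed=4)
        fresh = domain_finetune_mlm(docs, tiny_enc, steps=0, seed=4)
        for k in ("tok_emb", "mlm.w", "l0.wq"):
            assert np.array_equal(res.state.params[k], fresh.state.params[k])
        assert res.final_heldout_loss == res.initial_heldout_loss

    def test_same_seed_same_final_loss(self, tiny_enc):
        docs, _ = generate_corpus(GeneratorSpec(seed=22, n_docs=30))
        a = domain_finetune_mlm(docs, tiny_enc, steps=25, seed=6)
        b = domain_finetune_mlm(docs, tiny_enc, steps=25, seed=6)
        assert a.final_heldout_loss == b.final_heldout_loss


class TestGridSearch:
    def test_standard_ranges_enumerate_150_points(self):
        assert len(enumerate_grid(default_grid())) == 150

    def test_single_point_grid_returns_that_config(self, separable_set, tiny_enc):
        grid = {
            "epochs": [2], "learning_rate": [0.001],
            "loss": ["cross_entropy"], "optimizer": ["adam"],
        }
        ranked = grid_search(
            separable_set[:24], separable_set[24:36], tiny_enc, grid, seed=1
        )
        assert len(ranked) == 1
        assert ranked[0][0].epochs == 2 and ranked[0][0].optimizer == "adam"

    def test_best_f1_matches_brute_force_loop(self, separable_set, tiny_enc):
        train_set, eval_set = separable_set[:36], separable_set[36:]
        grid = {
            "epochs": [1, 3], "learning_rate": [0.001],
            "loss": ["cross_entropy"], "optimizer": ["adam"],
        }
        ranked = grid_search(train_set, eval_set, tiny_enc, grid, seed=2)
        tok = WordTokenizer.build(
            [e.sentence_a for e in separable_set] + [e.sentence_b for e in separable_set]
        )
        brute = []
        for tc in enumerate_grid(grid, seed=2):
            state = train_classifier(train_set, tiny_enc, tc, tokenizer=tok)
            pred = [p.argmax for p in predict_batch(state, eval_set)]
            cm = confusion_matrix([e.label for e in eval_set], pred)
            brute.append(class_metrics(cm)[1].macro_f1_raw)
        assert ranked[0][1] == pytest.approx(max(brute))

    def test_empty_grid_axis_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid({"momentum": [0.9]})
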
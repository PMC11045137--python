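"""SHAP-N attribution, embedding correlations and attention probes."""

import numpy as np
import pytest

from numnote import explain
from numnote.models import ForwardRecord, TextCNN, TextCNNConfig, TextLSTM, TextLSTMConfig
from numnote.textprep import NumericMention


def _random_model(seed=0, mode="basic"):
    cfg = TextCNNConfig(embed_dim=8, n_kernels=2, filter_sizes=(1, 2, 3),
                        dropout=0.0, n_scalenum=2, n_heads=2)
    return TextCNN(cfg, 25, mode, np.random.default_rng(seed), dtype=np.float64)


def _random_records(model, n=6, seed=1):
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n):
        ids = rng.integers(1, 25, size=10)
        recs.append(model.forward_record(ids, []))
    return recs


class TestShapFilters:
    def test_reconstruction_identity(self):
        model = _random_model()
        recs = _random_records(model)
        for d in explain.shap_filters(model, recs):
            assert abs(d.phi0 + d.phi.sum() - d.logit) < 1e-10

    def test_single_sample_dataset(self):
        model = _random_model()
        (d,) = explain.shap_filters(model, _random_records(model, n=1))
        assert np.allclose(d.phi, 0.0)
        assert abs(d.phi0 - d.logit) < 1e-12

    def test_against_arithmetic_oracle(self):
        """phi_{f,s} = w_f (a_{s,f} - mu_f), recomputed independently."""
        model = _random_model(2)
        recs = _random_records(model, n=5, seed=3)
        decomps = explain.shap_filters(model, recs)
        F = len(recs[0].activations)
        for f in range(F):
            mu_f = sum(r.activations[f] for r in recs) / len(recs)
            w_f = float(model.params["fc_w"][f])
            for r, d in zip(recs, decomps):
                assert abs(d.phi[f] - w_f * (r.activations[f] - mu_f)) < 1e-10

    def test_mu_order_invariant(self):
        model = _random_model(4)
        recs = _random_records(model, n=7, seed=5)
        d1 = explain.shap_filters(model, recs)[0]
        d2 = explain.shap_filters(model, recs[::-1])[-1]
        assert np.allclose(d1.mu, d2.mu)

    def test_lstm_refused(self):
        cfg = TextLSTMConfig(embed_dim=8, hidden_dim=4, n_scalenum=2, n_heads=2)
        lstm = TextLSTM(cfg, 25, "basic", np.random.default_rng(0))
        with pytest.raises(TypeError):
            explain.shap_filters(lstm, [])


def _decomp(spans, phi):
    F = len(spans)
    return explain.ShapDecomposition(
        phi0=0.0, phi=np.array(phi, dtype=float), mu=np.zeros(F),
        weights=np.ones(F), activations=np.zeros(F), spans=spans,
        logit=float(np.sum(phi)))


class TestAggregateNgrams:
    tokens = ["a", "b", "c", "d", "e", "f"]

    def test_disjoint_spans(self):
        out = explain.aggregate_ngrams(_decomp([(0, 1), (3, 2)], [0.2, 0.5]),
                                       self.tokens)
        assert out == {("a",): pytest.approx(0.2), ("d", "e"): pytest.approx(0.5)}

    def test_subspan_folds_into_container(self):
        # the 1-gram at position 2 sits inside the passing 3-gram at 1..3
        out = explain.aggregate_ngrams(_decomp([(2, 1), (1, 3)], [0.2, 0.5]),
                                       self.tokens)
        assert out == {("b", "c", "d"): pytest.approx(0.7)}

    def test_identical_spans_pool(self):
        out = explain.aggregate_ngrams(_decomp([(1, 2), (1, 2)], [0.1, 0.3]),
                                       self.tokens)
        assert out == {("b", "c"): pytest.approx(0.4)}

    def test_equal_length_tie_goes_leftmost(self):
        # the 1-gram at 2 fits in both (1,2) and (2,2): leftmost wins
        out = explain.aggregate_ngrams(
            _decomp([(2, 1), (1, 2), (2, 2)], [0.2, 0.1, 0.4]), self.tokens)
        assert out[("b", "c")] == pytest.approx(0.1 + 0.2)
        assert out[("c", "d")] == pytest.approx(0.4)

    def test_conservation(self):
        rng = np.random.default_rng(6)
        spans = [(int(rng.integers(0, 4)), int(rng.choice([1, 2, 3])))
                 for _ in range(9)]
        phi = rng.normal(size=9)
        out = explain.aggregate_ngrams(_decomp(spans, phi), self.tokens)
        assert abs(sum(out.values()) - phi.sum()) < 1e-12

    def test_merge_overlapping_variant(self):
        out = explain.aggregate_ngrams(
            _decomp([(0, 2), (1, 2)], [0.2, 0.3]), self.tokens,
            merge_overlapping=True)
        assert out == {("a", "b", "c"): pytest.approx(0.5)}


class TestMeanShapn:
    def test_single_sample(self):
        recs = explain.mean_shapn([{("a",): 0.4}])
        assert recs[0].phi == pytest.approx(0.4) and recs[0].support == 1

    def test_absent_samples_contribute_zero(self):
        recs = explain.mean_shapn([{("a",): 0.4}, {("b",): 0.2}])
        by = {r.ngram: r for r in recs}
        assert by[("a",)].phi == pytest.approx(0.2)
        assert by[("a",)].support == 1

    def test_sorted_descending(self):
        recs = explain.mean_shapn([{("a",): 0.1, ("b",): 0.5, ("c",): -0.2}])
        assert [r.ngram for r in recs] == [("b",), ("a",), ("c",)]


class TestEmbeddingProbes:
    def _fitted(self, trained_attn):
        res = trained_attn["res"]
        return res.model, res.vocab

    def test_identical_phrases_correlate_one(self, trained_attn):
        model, vocab = self._fitted(trained_attn)
        for stage in ("rooc", "scalenum", "attntonum"):
            rho = explain.embedding_correlation(
                "BUN 25.0 (H)", "BUN 25.0 (H)", model, vocab, stage)
            assert rho == pytest.approx(1.0)

    def test_correlation_matches_textbook_formula(self, trained_attn):
        model, vocab = self._fitted(trained_attn)
        from numnote.explain import _number_embedding
        v1 = _number_embedding("BUN 3.4 (L)", model, vocab, "scalenum")
        v2 = _number_embedding("creatinine 3.8 (H)", model, vocab, "scalenum")
        manual = (np.sum((v1 - v1.mean()) * (v2 - v2.mean()))
                  / np.sqrt(np.sum((v1 - v1.mean()) ** 2)
                            * np.sum((v2 - v2.mean()) ** 2)))
        rho = explain.embedding_correlation(
            "BUN 3.4 (L)", "creatinine 3.8 (H)", model, vocab, "scalenum")
        assert rho == pytest.approx(manual)

    def test_scalenum_similar_magnitudes_correlate_highly(self, trained_attn):
        """Magnitude-only embeddings cannot tell a high creatinine from a
        low BUN of similar value; attention can change that."""
        model, vocab = self._fitted(trained_attn)
        rho = explain.embedding_correlation(
            "BUN 3.4 (L)", "creatinine 3.8 (H)", model, vocab, "scalenum")
        assert abs(rho) > 0.9

    def test_phrase_without_number_rejected(self, trained_attn):
        model, vocab = self._fitted(trained_attn)
        with pytest.raises(ValueError):
            explain.embedding_correlation("BUN high", "BUN 25.0 (H)",
                                          model, vocab, "scalenum")

    def test_attention_rows_sum_to_one(self, trained_attn):
        model, vocab = self._fitted(trained_attn)
        for phrase in ("_date_ creatinine 6.3 (H)", "_date_ BUN 6.3 (L)"):
            w, toks = explain.attention_weights(phrase, model, vocab)
            assert w.shape == (5, len(toks))
            assert np.allclose(w.sum(axis=1), 1.0)

    def test_symmetric_projections_give_uniform_attention(self):
        """With zeroed (symmetric) projections every score ties, so each
        head attends uniformly over the window."""
        cfg = TextCNNConfig(max_len=32)
        model = TextCNN(cfg, 50, "attntonum", np.random.default_rng(8))
        for name in ("attn_w_q", "attn_w_k", "attn_b_q", "attn_b_k"):
            model.params[name][...] = 0.0
        from numnote.textprep import build_vocab, tokenize, EmbeddingMode
        vocab = build_vocab([tokenize("_date_ BUN 6.3 (H) x y z")],
                            EmbeddingMode.ROOC)
        w, toks = explain.attention_weights("_date_ BUN 6.3 (H)", model, vocab)
        assert np.allclose(w, 1.0 / len(toks))
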
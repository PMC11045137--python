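"""TextCNN / TextLSTM forward-backward correctness and parameter accounting."""

import numpy as np
import pytest

from numnote import models
from numnote.textprep import NumericMention

_IDS = np.array([[5, 6, 7, 8, 9, 10, 3, 0],
                 [5, 5, 12, 13, 5, 5, 5, 5],
                 [2, 3, 4, 0, 0, 0, 0, 0]])
_MENTIONS = [
    [NumericMention(2, 5.2, "bun", 1, True),
     NumericMention(5, 880.0, "creatinine", 4, True)],
    [NumericMention(3, 0.4, "creatinine", 2, True)],
    [],
]
_Y = np.array([1.0, 0.0, 1.0])

_SMALL_CNN = models.TextCNNConfig(embed_dim=10, n_kernels=3,
                                  filter_sizes=(1, 2, 3), dropout=0.0,
                                  n_scalenum=2, n_heads=2)
_SMALL_LSTM = models.TextLSTMConfig(embed_dim=10, hidden_dim=6, dropout=0.0,
                                    n_scalenum=2, n_heads=2)


class TestParameterCounts:
    def test_closed_form_matches_actual_scalars(self):
        """count_parameters equals direct enumeration of learned arrays."""
        rng = np.random.default_rng(0)
        for cfg, cls in ((_SMALL_CNN, models.TextCNN),
                         (_SMALL_LSTM, models.TextLSTM)):
            for mode in ("basic", "rooc", "scalenum", "attntonum"):
                m = cls(cfg, 37, mode, rng)
                got = m.parameter_group_sizes()
                want = models.count_parameters(cfg, 37, mode)
                assert got["embed"] == want.embed
                assert got["number_embedding"] == want.number_embedding
                assert got["attention"] == want.attention
                assert got["post_embed"] == want.post_embed
                assert sum(v.size for v in m.params.values()) == want.total

    def test_default_config_counts(self):
        cnn = models.count_parameters(models.TextCNNConfig(), 9408, "attntonum")
        assert cnn.attention == 10_200
        assert cnn.post_embed == 24_553
        lstm = models.count_parameters(models.TextLSTMConfig(), 9408, "attntonum")
        assert lstm.post_embed == 98_737


def _gradcheck(model, n_probes=5, eps=1e-5, tol=1e-7):
    def loss_fn():
        logits, cache = model.forward(_IDS, _MENTIONS, train=False)
        loss, dl = models.bce_with_logits(logits, _Y)
        return loss, dl, cache

    _, dl, cache = loss_fn()
    grads = model.backward(dl, cache)
    rng = np.random.default_rng(1)
    for name, arr in model.params.items():
        for _ in range(n_probes):
            ix = tuple(rng.integers(0, s) for s in arr.shape)
            orig = arr[ix]
            arr[ix] = orig + eps
            lp, _, _ = loss_fn()
            arr[ix] = orig - eps
            lm, _, _ = loss_fn()
            arr[ix] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[name][ix]) < tol, name


@pytest.mark.parametrize("mode", ["basic", "scalenum", "attntonum"])
def test_textcnn_gradients_match_finite_differences(mode):
    m = models.TextCNN(_SMALL_CNN, 30, mode, np.random.default_rng(0),
                       dtype=np.float64)
    _gradcheck(m)


@pytest.mark.parametrize("mode", ["basic", "attntonum"])
def test_textlstm_gradients_match_finite_differences(mode):
    m = models.TextLSTM(_SMALL_LSTM, 30, mode, np.random.default_rng(0),
                        dtype=np.float64)
    _gradcheck(m)


class TestTextCNNForward:
    def _model(self, mode="basic"):
        return models.TextCNN(_SMALL_CNN, 30, mode, np.random.default_rng(2),
                              dtype=np.float64)

    def test_zero_weights_logit_equals_bias(self):
        m = self._model()
        for k, v in m.params.items():
            v[...] = 0.0
        m.params["fc_b"][0] = 0.37
        logits, _ = m.forward(_IDS, _MENTIONS)
        assert np.allclose(logits, 0.37)

    def test_logit_reconstructs_from_forward_record(self):
        """logit = w0 + sum_f w_f a_{s,f}, exactly."""
        m = self._model("attntonum")
        rec = m.forward_record(_IDS[0], _MENTIONS[0])
        expect = m.params["fc_b"][0] + m.params["fc_w"] @ rec.activations
        assert abs(rec.logit - expect) < 1e-12

    def test_all_padding_note(self):
        m = self._model()
        logits, _ = m.forward(np.zeros((1, 8), dtype=int), [[]])
        assert np.isfinite(logits[0])

    def test_batch_padding_invariance(self):
        """Extra all-pad columns leave logits unchanged."""
        m = self._model("attntonum")
        base, _ = m.forward(_IDS, _MENTIONS)
        wide = np.pad(_IDS, ((0, 0), (0, 7)))
        padded, _ = m.forward(wide, _MENTIONS)
        assert np.allclose(base, padded)

    def test_dropout_scales_expectation(self):
        m = self._model()
        logits, cache = m.forward(_IDS, _MENTIONS, train=True)
        keep = 1 - _SMALL_CNN.dropout
        assert cache["dropmask"].shape == cache["h"].shape


class TestTextLSTMForward:
    def _model(self, mode="basic"):
        return models.TextLSTM(_SMALL_LSTM, 30, mode, np.random.default_rng(3),
                               dtype=np.float64)

    def test_output_width_is_twice_hidden(self):
        cfg = models.TextLSTMConfig()
        assert cfg.output_dim == 176
        m = self._model()
        assert m.params["fc_w"].size == _SMALL_LSTM.output_dim

    def test_constant_input_memoryless_recurrence(self):
        """Zero recurrent weights + closed forget gate make every step
        identical, so the temporal max pool equals a single step."""
        m = self._model()
        H = _SMALL_LSTM.hidden_dim
        for d in ("fw", "bw"):
            m.params[f"lstm_{d}_whh"][...] = 0.0
            m.params[f"lstm_{d}_bih"][H:2 * H] = -40.0  # forget gate ~ 0
        ids = np.full((1, 6), 4)
        logits6, _ = m.forward(ids, [[]])
        logits1, _ = m.forward(ids[:, :1], [[]])
        assert np.allclose(logits6, logits1)

    def test_batch_padding_invariance(self):
        m = self._model("attntonum")
        base, _ = m.forward(_IDS, _MENTIONS)
        padded, _ = m.forward(np.pad(_IDS, ((0, 0), (0, 5))), _MENTIONS)
        assert np.allclose(base, padded)


def test_bce_with_logits_matches_reference():
    rng = np.random.default_rng(4)
    z = rng.normal(size=32)
    y = (rng.random(32) < 0.5).astype(float)
    p = 1 / (1 + np.exp(-z))
    ref = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    loss, dl = models.bce_with_logits(z, y)
    assert abs(loss - ref) < 1e-10
    assert np.allclose(dl, (p - y) / 32)
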
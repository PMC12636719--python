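"""CAREMIL forward pass: oracle equivalence, permutation symmetry,
attention extraction, serialization."""

import numpy as np
import pytest

import caremil as cm
from caremil.aggregators import AggregatorConfig
from caremil.model import extract_cell_attention, save_model, load_model

from oracles import caremil_forward_oracle


def tiny_config(K=1, heads=1, H=2, n_classes=2, seed=0, genmean=False):
    agg = AggregatorConfig(use_mean=True, use_variance=(K >= 2),
                           genmean_powers=(2.0,) if genmean else ())
    return cm.CaremilConfig(D=3, H=H, n_heads=heads, n_classes=n_classes,
                            aggregator_hidden=(4,), parallel_hidden=(4,),
                            mlp_hidden=(4,), aggregator_config=agg,
                            dropout=0.0, seed=seed)


def test_initialize_deterministic_and_validated():
    cfg = tiny_config(seed=5)
    a, b = cm.initialize(cfg), cm.initialize(cfg)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k].data, b.params[k].data)
    with pytest.raises(ValueError):
        cm.CaremilConfig(D=3, H=8, n_heads=3)
    head_w = cm.initialize(tiny_config(n_classes=4)).params["head_W1"]
    assert head_w.data.shape[1] == 4


@pytest.mark.parametrize("K", [1, 2])
@pytest.mark.parametrize("heads", [1, 2])
@pytest.mark.parametrize("H", [2, 4])
def test_forward_matches_straight_line_oracle(K, heads, H, rng):
    """Grid of 8 configurations against the loop-by-loop reference."""
    cfg = tiny_config(K=K, heads=heads, H=H, seed=K * 100 + heads * 10 + H)
    model = cm.initialize(cfg)
    bag = cm.CellBag("toy", rng.normal(size=(6, 3)))
    logits, report = cm.forward(model, bag)
    want_logits, want_probs = caremil_forward_oracle(model, bag.embeddings)
    np.testing.assert_allclose(logits.data, want_logits, atol=1e-5)
    np.testing.assert_allclose(report.per_token_scores,
                               extract_cell_attention(want_probs, model.n_tokens),
                               atol=1e-5)


def test_forward_with_genmean_token_matches_oracle(rng):
    cfg = tiny_config(K=1, heads=2, H=4, genmean=True, seed=9)
    model = cm.initialize(cfg)
    bag = cm.CellBag("toy", rng.normal(size=(5, 3)))
    logits, _ = cm.forward(model, bag)
    want_logits, _ = caremil_forward_oracle(model, bag.embeddings)
    np.testing.assert_allclose(logits.data, want_logits, atol=1e-5)


def test_hand_set_weights_two_cell_bag():
    """Hand-executable configuration: K=1 (mean), one head, identity-ish maps."""
    cfg = cm.CaremilConfig(D=2, H=2, n_heads=1, n_classes=2,
                           aggregator_hidden=(), parallel_hidden=(),
                           mlp_hidden=(), dropout=0.0, seed=0,
                           aggregator_config=AggregatorConfig(True, False, ()))
    model = cm.initialize(cfg)
    I2 = np.eye(2)
    for name in ("agg_W0", "par_W0", "attn_Wq", "attn_Wk", "attn_Wv", "attn_Wo"):
        model.params[name].data = I2.copy()
    model.params["head_W0"].data = np.array([[1.0, 0.0], [0.0, 1.0]])
    for name in ("agg_b0", "par_b0", "attn_bq", "attn_bk", "attn_bv", "attn_bo",
                 "head_b0"):
        model.params[name].data[:] = 0.0
    bag = cm.CellBag("hand", np.array([[1.0, 0.0], [0.0, 1.0]]))
    logits, report = cm.forward(model, bag)
    want_logits, want_probs = caremil_forward_oracle(model, bag.embeddings)
    np.testing.assert_allclose(logits.data, want_logits, atol=1e-10)
    # with every map the identity, the mean token (0.5, 0.5) is equidistant
    # from the two symmetric cells, so cell attention must be uniform
    np.testing.assert_allclose(report.per_token_scores, [[0.5, 0.5]], atol=1e-12)


@pytest.mark.parametrize("n_bags", [20])
def test_permutation_invariance_and_equivariance(n_bags, rng):
    cfg = tiny_config(K=2, heads=2, H=4, seed=3)
    model = cm.initialize(cfg)
    for b in range(n_bags):
        n = int(rng.integers(2, 30))
        X = rng.normal(size=(n, 3))
        bag = cm.CellBag("b", X)
        logits, report = cm.forward(model, bag)
        for _ in range(5):
            perm = rng.permutation(n)
            l2, r2 = cm.forward(model, cm.CellBag("b", X[perm]))
            np.testing.assert_allclose(l2.data, logits.data, atol=1e-6)
            np.testing.assert_allclose(r2.scores, report.scores[perm], atol=1e-6)


@pytest.mark.parametrize("n", [1, 2, 17, 500, 3000])
def test_variable_bag_size(n, rng):
    model = cm.initialize(tiny_config(K=2, heads=2, H=4))
    logits, report = cm.forward(model, cm.CellBag("b", rng.normal(size=(n, 3))))
    assert logits.data.shape == (2,)
    assert report.per_token_scores.shape == (2, n)
    np.testing.assert_allclose(report.per_token_scores.sum(axis=1), [1, 1], atol=1e-6)


def test_single_cell_bag_receives_all_attention(rng):
    model = cm.initialize(tiny_config(K=2, heads=2, H=4))
    _, report = cm.forward(model, cm.CellBag("b", rng.normal(size=(1, 3))))
    np.testing.assert_allclose(report.per_token_scores, [[1.0], [1.0]], atol=1e-9)


def test_dimension_mismatch_rejected(rng):
    model = cm.initialize(tiny_config())
    with pytest.raises(ValueError, match="D="):
        cm.forward(model, cm.CellBag("b", rng.normal(size=(4, 7))))


# --- extract_cell_attention -------------------------------------------------

def test_extract_uniform_attention_gives_uniform_scores():
    T = 6  # K=2 tokens + 4 cells
    att = np.full((T, T, 3), 1.0 / T)
    out = extract_cell_attention(att, K=2)
    np.testing.assert_allclose(out, np.full((2, 4), 0.25))


def test_extract_indicator_row():
    att = np.zeros((5, 5, 1))   # 2 tokens + 3 cells
    att[0, 3, 0] = 1.0          # token 0 puts all mass on cell index 1 (col 3)
    att[1] = 0.2
    out = extract_cell_attention(att, K=2)
    np.testing.assert_allclose(out[0], [0, 1, 0])
    np.testing.assert_allclose(out[1], [1 / 3, 1 / 3, 1 / 3])


def test_extract_two_heads_hand_computation():
    # 3 positions: 1 token, 2 cells; rows softmax-normalized per head
    r1 = np.array([0.2, 0.5, 0.3])
    r2 = np.array([0.6, 0.1, 0.3])
    att = np.zeros((3, 3, 2))
    att[0, :, 0] = r1
    att[0, :, 1] = r2
    att[1:, :, :] = 1.0 / 3
    avg = (r1 + r2) / 2           # (0.4, 0.3, 0.3)
    want = avg[1:] / avg[1:].sum()  # renormalized over cell columns
    out = extract_cell_attention(att, K=1)
    np.testing.assert_allclose(out[0], want, atol=1e-12)
    with pytest.raises(ValueError):
        extract_cell_attention(att, K=3)


# --- probabilities and serialization ----------------------------------------

def test_predict_proba_properties(rng):
    model = cm.initialize(tiny_config(K=2, heads=2, H=4))
    for _ in range(20):
        bag = cm.CellBag("b", rng.normal(size=(int(rng.integers(1, 40)), 3)))
        p = cm.predict_proba(model, bag)
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        logits, _ = cm.forward(model, bag)
        sig = 1.0 / (1.0 + np.exp(-(logits.data[1] - logits.data[0])))
        assert p[1] == pytest.approx(sig, abs=1e-9)


def test_checkpoint_round_trip_bitwise(tmp_path, rng):
    model = cm.initialize(tiny_config(K=2, heads=2, H=4, seed=21))
    bag = cm.CellBag("b", rng.normal(size=(8, 3)))
    logits, _ = cm.forward(model, bag)
    path = tmp_path / "ckpt.npz"
    save_model(model, path)
    reloaded = load_model(path)
    logits2, _ = cm.forward(reloaded, bag)
    np.testing.assert_array_equal(logits.data, logits2.data)
    assert reloaded.config.to_dict() == model.config.to_dict()
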
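import numpy as np
import pytest

from capsicd.capsule import class_scores, conv_ngram, dynamic_routing, primary_capsules
from capsicd.fusion import augment_tokens, fuse_for_classification, sentence_label_similarity, word_label_similarity
from capsicd.lstm import LstmParams, bilstm_encode
from capsicd.network import CapsuleCoder, ModelConfig, build_model, scores_to_codes


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _unpack_lstm(W, U, b):
    u = U.shape[0]
    g = lambda M, j: M[:, j * u : (j + 1) * u].T
    return LstmParams(
        g(W, 0), g(W, 1), g(W, 2), g(W, 3),
        g(U, 0), g(U, 1), g(U, 2), g(U, 3),
        b[:u], b[u : 2 * u], b[2 * u : 3 * u], b[3 * u :],
    )


# -- construction ------------------------------------------------------------


def test_identical_config_and_seed_give_identical_initial_params(tiny_model):
    a = tiny_model().initialize()
    b = tiny_model().initialize()
    assert set(a.params_) == set(b.params_)
    for k in a.params_:
        np.testing.assert_array_equal(a.params_[k], b.params_[k])


def test_ablation_flags_remove_stages(tiny_model):
    m = tiny_model(bilstm=False, label_fusion=False).initialize()
    assert not any(k.startswith(("lstm.", "proj.")) for k in m.params_)
    full = tiny_model().initialize()
    assert any(k.startswith("lstm.") for k in full.params_)
    assert "proj.W" in full.params_


def test_embedding_dimension_mismatch_is_rejected(tiny_embedding, tiny_labels):
    from capsicd.embeddings import LabelEmbeddingMatrix

    bad = LabelEmbeddingMatrix(labels=["001"], vectors=np.zeros((1, 5)))
    with pytest.raises(ValueError, match="share one space"):
        CapsuleCoder(embedding=tiny_embedding, label_embeddings=bad).initialize()


def test_build_model_checks_config_dim(tiny_embedding, tiny_labels):
    cfg = ModelConfig(embedding_dim=6, hidden_units=4, capsule_dim=3, n_filters=4, n_channels=1)
    m = build_model(cfg, tiny_embedding, tiny_labels)
    assert hasattr(m, "params_")
    with pytest.raises(ValueError, match="embedding_dim"):
        build_model(ModelConfig(embedding_dim=7), tiny_embedding, tiny_labels)


def test_forward_scores_are_finite_probabilities(tiny_model):
    m = tiny_model().initialize()
    scores = m.predict_proba([["t0", "t3", "t5", "t1"]])
    assert scores.shape == (1, 3)
    assert np.all(np.isfinite(scores)) and np.all((scores >= 0) & (scores <= 1))


# -- wiring vs the functional primitives -------------------------------------


def test_capsule_only_model_composes_the_functional_path(tiny_model):
    """With Bi-LSTM and fusion disabled, the model forward is exactly the
    conv -> primary capsule -> routing -> head composition."""
    m = tiny_model(bilstm=False, label_fusion=False).initialize()
    tokens = ["t0", "t4", "t9", "t2", "t7"]
    ids, lengths = m._encode_batch([tokens])
    logits = m._forward(ids, lengths)
    V = m.embedding.vectors[ids[0]]
    K1, F = m.kernel_size, m.n_filters
    e = V.shape[1]
    W_a = m.params_["conv.W"].T.reshape(F, K1, e)
    fm = conv_ngram(V, W_a, m.params_["conv.b"])
    P = primary_capsules(fm, m.params_["caps.W"], m.params_["caps.b"], d=m.capsule_dim)
    W_full = np.repeat(m.params_["route.W"][None, :, :, :, :], fm.M.shape[0], axis=0)
    W_full = W_full.transpose(0, 1, 2, 3, 4).reshape(-1, 3, m.capsule_dim, m.capsule_dim)
    scores, state = class_scores(P, W_full, iterations=m.routing_iters)
    ref_logits = state.v.reshape(-1) @ m.params_["head.W"] + m.params_["head.b"]
    np.testing.assert_allclose(logits[0], ref_logits, atol=1e-10)


def test_full_model_composes_fusion_encoder_and_capsules(tiny_model):
    """The fused Bi-LSTM model forward equals the chained functional
    operations (similarity augmentation, bilstm encoding, capsule routing,
    similarity fusion, dense head)."""
    m = tiny_model().initialize()
    tokens = ["t1", "t8", "t3", "t6", "t2", "t5"]
    ids, lengths = m._encode_batch([tokens])
    logits = m._forward(ids, lengths)

    V = m.embedding.vectors[ids[0]]
    C = m.label_embeddings.vectors
    G = word_label_similarity(C, V)
    X_in = augment_tokens(G, V)
    fwd = _unpack_lstm(m.params_["lstm.W_f0"], m.params_["lstm.U_f0"], m.params_["lstm.b_f0"])
    bwd = _unpack_lstm(m.params_["lstm.W_b0"], m.params_["lstm.U_b0"], m.params_["lstm.b_b0"])
    H = bilstm_encode(X_in, fwd, bwd)
    K1, F = m.kernel_size, m.n_filters
    W_a = m.params_["conv.W"].T.reshape(F, K1, H.shape[1])
    fm = conv_ngram(H, W_a, m.params_["conv.b"])
    P = primary_capsules(fm, m.params_["caps.W"], m.params_["caps.b"], d=m.capsule_dim)
    W_full = np.repeat(m.params_["route.W"][None], fm.M.shape[0], axis=0)
    W_full = W_full.reshape(-1, 3, m.capsule_dim, m.capsule_dim)
    _, state = class_scores(P, W_full, iterations=m.routing_iters)
    z = H.mean(axis=0)
    proj = z @ m.params_["proj.W"] + m.params_["proj.b"]
    D = sentence_label_similarity(proj, C)
    head_in = fuse_for_classification(state.v, D)
    ref_logits = head_in @ m.params_["head.W"] + m.params_["head.b"]
    np.testing.assert_allclose(logits[0], ref_logits, atol=1e-9)


def test_batched_routing_inside_model_matches_functional(tiny_model):
    m = tiny_model(bilstm=False, label_fusion=False).initialize()
    ids, lengths = m._encode_batch([["t0", "t1", "t2", "t3"]])
    _, cache = m._forward(ids, lengths, with_cache=True)
    u_hat, _ = cache["route_cache"]
    state = dynamic_routing(u_hat[0], m.routing_iters)
    np.testing.assert_allclose(
        cache["route_cache"][1][-1]["v"][0], state.v, atol=1e-12
    )


# -- gradients and optimisation ---------------------------------------------


def test_head_gradient_matches_finite_differences(tiny_model, tiny_notes):
    """Backprop agrees with a central finite-difference check on a slice of
    the classification head within 1e-4 relative error."""
    m = tiny_model().initialize()
    X, y = tiny_notes
    ids, lengths = m._encode_batch(X[:4])
    Y = m._multi_hot(y[:4])
    _, grads = m._loss_and_grads(ids, lengths, Y)

    def loss():
        l, _ = m._loss_and_dlogits(m._forward(ids, lengths), Y)
        return l

    arr = m.params_["head.W"]
    rng = np.random.default_rng(0)
    eps = 1e-6
    for _ in range(5):
        ix = tuple(rng.integers(0, s) for s in arr.shape)
        old = arr[ix]
        arr[ix] = old + eps
        lp = loss()
        arr[ix] = old - eps
        lm = loss()
        arr[ix] = old
        num = (lp - lm) / (2 * eps)
        assert abs(num - grads["head.W"][ix]) <= 1e-4 * max(1e-8, abs(num))


def test_zero_learning_rate_leaves_parameters_unchanged(tiny_model, tiny_notes):
    X, y = tiny_notes
    m = tiny_model(learning_rate=1e-30, max_epochs=1)
    m.fit(X, y, validation_data=(X[:2], y[:2]))
    ref = tiny_model().initialize()
    for k in ref.params_:
        np.testing.assert_allclose(m.params_[k], ref.params_[k], atol=1e-20)


def test_one_epoch_smoke_records_history(tiny_model, tiny_notes):
    X, y = tiny_notes
    m = tiny_model(max_epochs=1)
    m.fit(X, y, validation_data=(X[:2], y[:2]))
    assert len(m.loss_curve_) == 1
    assert {"epoch", "train_loss", "val_loss"} <= set(m.loss_curve_[0])


def test_fit_is_deterministic_for_fixed_seed(tiny_model, tiny_notes):
    X, y = tiny_notes
    runs = []
    for _ in range(2):
        m = tiny_model(max_epochs=2)
        m.fit(X, y, validation_data=(X[:2], y[:2]))
        runs.append(m.predict_proba(X))
    np.testing.assert_array_equal(runs[0], runs[1])


def test_softmax_loss_mode_scores_sum_to_one(tiny_model, tiny_notes):
    X, y = tiny_notes
    m = tiny_model(loss_mode="softmax-ce", max_epochs=1)
    m.fit(X, y, validation_data=(X[:2], y[:2]))
    scores = m.predict_proba(X[:3])
    np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


def test_empty_inputs_are_rejected(tiny_model):
    with pytest.raises(ValueError):
        tiny_model().fit([], [])
    with pytest.raises(ValueError):
        tiny_model().fit([["a"]], [{"001"}, {"002"}])


# -- inference policies ------------------------------------------------------


def test_threshold_policy_definition():
    sets = scores_to_codes(np.array([[0.9, 0.2, 0.6]]), ["A", "B", "C"], threshold=0.5)
    assert sets == [{"A", "C"}]


def test_top_k_tie_break_prefers_label_order():
    sets = scores_to_codes(np.array([[0.3, 0.3]]), ["A", "B"], threshold=None, top_k=1)
    assert sets == [{"A"}]


def test_policy_selection_is_exclusive():
    with pytest.raises(ValueError):
        scores_to_codes(np.zeros((1, 2)), ["A", "B"], threshold=0.5, top_k=1)
    with pytest.raises(ValueError):
        scores_to_codes(np.zeros((1, 2)), ["A", "B"], threshold=None, top_k=None)


def test_threshold_policy_matches_comparison_loop():
    rng = np.random.default_rng(1)
    scores = rng.random((100, 7))
    labels = [f"{j:03d}" for j in range(7)]
    sets = scores_to_codes(scores, labels, threshold=0.5)
    for i in range(100):
        expected = {labels[j] for j in range(7) if scores[i, j] >= 0.5}
        assert sets[i] == expected


def test_predict_binary_agrees_with_predict_codes(tiny_model, tiny_notes):
    X, y = tiny_notes
    m = tiny_model(max_epochs=1)
    m.fit(X, y, validation_data=(X[:2], y[:2]))
    binary = m.predict(X[:4])
    sets = m.predict_codes(X[:4])
    for i, codes in enumerate(sets):
        assert {m.classes_[j] for j in np.flatnonzero(binary[i])} == codes


def test_empty_note_is_flagged_not_fatal(tiny_model, tiny_notes, caplog):
    X, y = tiny_notes
    m = tiny_model(max_epochs=1)
    m.fit(X, y, validation_data=(X[:2], y[:2]))
    with caplog.at_level("WARNING"):
        scores = m.predict_proba([[]])
    assert scores.shape == (1, 3) and np.all(np.isfinite(scores))
    assert "empty" in caplog.text


# -- persistence -------------------------------------------------------------


def test_checkpoint_round_trip_preserves_scores(tiny_model, tiny_notes, tmp_path):
    X, y = tiny_notes
    m = tiny_model(max_epochs=1)
    m.fit(X, y, validation_data=(X[:2], y[:2]))
    path = tmp_path / "model.npz"
    m.save(path)
    back = CapsuleCoder.load(path)
    assert back.classes_ == m.classes_
    np.testing.assert_array_equal(back.predict_proba(X), m.predict_proba(X))


# -- fusion variants ---------------------------------------------------------


@pytest.mark.parametrize(
    "overrides",
    [
        {"label_sim_reduce": "max"},
        {"label_sim_reduce": "top-m", "label_sim_m": 2},
        {"fusion_mode": "additive"},
        {"pooled_source": "capsule"},
    ],
    ids=["sim-max", "sim-top-m", "additive-D", "capsule-z"],
)
def test_fusion_variant_gradients_match_finite_differences(tiny_model, tiny_notes, overrides):
    """Every fusion configuration keeps backprop exact: random entries of
    every parameter array agree with central finite differences."""
    m = tiny_model(**overrides).initialize()
    if "proj.b" in m.params_:
        # move the projected text vector away from the cosine's |z| = 0
        # point, where finite differences are ill-conditioned
        m.params_["proj.b"] += np.random.default_rng(5).normal(0.3, 0.1, size=6)
    X, y = tiny_notes
    ids, lengths = m._encode_batch(X[:4])
    Y = m._multi_hot(y[:4])
    _, grads = m._loss_and_grads(ids, lengths, Y)

    def loss():
        l, _ = m._loss_and_dlogits(m._forward(ids, lengths), Y)
        return l

    rng = np.random.default_rng(1)
    eps = 1e-6
    for name, arr in m.params_.items():
        for _ in range(2):
            ix = tuple(rng.integers(0, s) for s in arr.shape)
            old = arr[ix]
            arr[ix] = old + eps
            lp = loss()
            arr[ix] = old - eps
            lm = loss()
            arr[ix] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[name][ix]) < 1e-5 * max(1.0, abs(num)), name


def test_sim_reduce_narrows_encoder_input(tiny_model):
    full = tiny_model().initialize()
    narrow = tiny_model(label_sim_reduce="max").initialize()
    # encoder input width: e + L vs e + 1
    assert full.params_["lstm.W_f0"].shape[0] == 6 + 3
    assert narrow.params_["lstm.W_f0"].shape[0] == 6 + 1


def test_additive_fusion_adds_similarity_to_logits(tiny_model):
    m = tiny_model(fusion_mode="additive").initialize()
    assert m.params_["head.W"].shape[0] == 3 * m.capsule_dim  # no D columns
    scores = m.predict_proba([["t0", "t1", "t2"]])
    assert scores.shape == (1, 3) and np.all(np.isfinite(scores))


def test_invalid_fusion_options_are_rejected(tiny_model):
    with pytest.raises(ValueError, match="label_sim_reduce"):
        tiny_model(label_sim_reduce="mean").initialize()
    with pytest.raises(ValueError, match="fusion_mode"):
        tiny_model(fusion_mode="sum").initialize()
    with pytest.raises(ValueError, match="pooled_source"):
        tiny_model(pooled_source="conv").initialize()
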
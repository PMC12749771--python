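import numpy as np
import pytest

import cryomil as cm
from cryomil.errors import (
    DegenerateInputError,
    DimensionMismatchError,
    EmptyBagError,
)
from cryomil.model import MILModel, _backward, _forward, bag_loss


def _ln(v, g, b, eps=1e-5):
    mu = v.mean()
    return g * (v - mu) / np.sqrt(v.var() + eps) + b


def oracle_forward(x, p):
    """Straight-line re-implementation of the block equations, one patch row
    at a time, independent of the package's vectorised code path."""
    n = x.shape[0]
    K = np.array([xi @ p["Wk"] for xi in x])
    Q = np.array([xi @ p["Wq"] for xi in x])
    V = np.array([xi @ p["Wv"] for xi in x])
    A = np.zeros((n, n))
    for i in range(n):
        scores = np.array([K[i] @ Q[j] for j in range(n)])
        e = np.exp(scores - scores.max())
        A[i] = e / e.sum()
    y_sa = np.zeros_like(x, dtype=float)
    for i in range(n):
        av = sum(A[i, j] * V[j] for j in range(n))
        h = np.maximum(av @ p["A1"] + p["b1"], 0)
        y_sa[i] = _ln(x[i] + h @ p["A2"] + p["b2"], p["ln1_g"], p["ln1_b"])
    y_mlp = np.zeros_like(x, dtype=float)
    for i in range(n):
        h = np.maximum(y_sa[i] @ p["B1"] + p["c1"], 0)
        y_mlp[i] = _ln(y_sa[i] + h @ p["B2"] + p["c2"], p["ln2_g"], p["ln2_b"])
    pooled = y_mlp.mean(axis=0)
    logits = pooled @ p["H"] + p["hb"]
    e = np.exp(logits - logits.max())
    return A, y_sa, y_mlp, e / e.sum()


def _tiny_model(seed=42, d=4, a=3, m=5):
    hp = cm.MILHyperparams(
        feature_dim=d, attention_dim=a, mlp_dim=m, epochs=1, seed=seed
    )
    model = MILModel.initialise(hp)
    rng = np.random.default_rng(seed)
    # hand-set weights: overwrite with a fresh random draw incl. nonzero biases
    for k, v in model.params.items():
        model.params[k] = rng.normal(0, 0.5, size=v.shape)
    model.params["ln1_g"] = np.abs(model.params["ln1_g"]) + 0.5
    model.params["ln2_g"] = np.abs(model.params["ln2_g"]) + 0.5
    return model


@pytest.mark.parametrize("n_patches", [1, 2, 3, 5])
def test_block_matches_equation_oracle(n_patches):
    model = _tiny_model()
    rng = np.random.default_rng(n_patches)
    x = rng.normal(size=(n_patches, 4))
    A_o, ysa_o, ymlp_o, probs_o = oracle_forward(x, model.params)
    out = cm.attention_forward(x, model)
    np.testing.assert_allclose(out.A, A_o, atol=1e-6)
    np.testing.assert_allclose(out.y_sa, ysa_o, atol=1e-6)
    np.testing.assert_allclose(cm.transformer_block(x, model), ymlp_o, atol=1e-6)
    bag = cm.FeatureBag("s", x, np.zeros((n_patches, 2)))
    np.testing.assert_allclose(
        cm.slide_logits(bag, model).probabilities, probs_o, atol=1e-6
    )


def test_single_patch_attention_is_one():
    model = _tiny_model()
    out = cm.attention_forward(np.ones((1, 4)), model)
    np.testing.assert_array_equal(out.A, [[1.0]])


def test_attention_rows_are_distributions(rng):
    model = _tiny_model()
    out = cm.attention_forward(rng.normal(size=(7, 4)), model)
    np.testing.assert_allclose(out.A.sum(axis=1), 1.0, atol=1e-6)
    assert (out.A > 0).all() and (out.A <= 1).all()


def test_zero_block_mlp_reduces_to_layernormed_y_sa(rng):
    model = _tiny_model()
    model.params["B2"][:] = 0.0
    model.params["c2"][:] = 0.0
    x = rng.normal(size=(4, 4))
    y_sa = cm.attention_forward(x, model).y_sa
    expected = np.array(
        [_ln(v, model.params["ln2_g"], model.params["ln2_b"]) for v in y_sa]
    )
    np.testing.assert_allclose(cm.transformer_block(x, model), expected, atol=1e-10)


def test_probability_permutation_invariance(rng):
    model = _tiny_model()
    x = rng.normal(size=(9, 4))
    bag = cm.FeatureBag("s", x, np.zeros((9, 2)))
    p0 = cm.slide_logits(bag, model).probabilities
    perm = rng.permutation(9)
    bag2 = cm.FeatureBag("s", x[perm], np.zeros((9, 2)))
    p1 = cm.slide_logits(bag2, model).probabilities
    assert np.abs(p0 - p1).max() < 1e-6
    assert abs(p0.sum() - 1.0) < 1e-6


def test_shape_and_error_contracts(rng):
    model = _tiny_model()
    assert cm.transformer_block(rng.normal(size=(6, 4)), model).shape == (6, 4)
    with pytest.raises(EmptyBagError):
        cm.transformer_block(np.zeros((0, 4)), model)
    with pytest.raises(DimensionMismatchError):
        cm.transformer_block(rng.normal(size=(3, 5)), model)


def test_gradients_match_finite_differences(rng):
    model = _tiny_model(seed=1)
    x = rng.normal(size=(4, 4))
    _, cache = _forward(x, model)
    grads = _backward(model, cache, 1)
    for k, P in model.params.items():
        for _ in range(2):
            idx = tuple(rng.integers(s) for s in P.shape)
            eps, orig = 1e-6, P[idx]
            P[idx] = orig + eps
            lp = bag_loss(model, x, 1)
            P[idx] = orig - eps
            lm = bag_loss(model, x, 1)
            P[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[k][idx]) < 1e-5 * max(1.0, abs(num)), k


def test_training_deterministic_and_loss_decreases(small_cohort, tiny_hp):
    _, records, bags = small_cohort
    labels = np.array(
        [int(r.gene_labels["H3K27M"] == "mutant") for r in records]
    )
    m1 = cm.train_classifier(bags, labels, tiny_hp)
    m2 = cm.train_classifier(bags, labels, tiny_hp)
    assert m1.training_log == m2.training_log
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m2.params[k])
    assert m1.training_log[-1] < m1.training_log[0]


def test_single_class_training_rejected(small_cohort, tiny_hp):
    _, _, bags = small_cohort
    with pytest.raises(DegenerateInputError):
        cm.train_classifier(bags[:4], np.ones(4, dtype=int), tiny_hp)


def test_predict_agrees_with_per_bag_calls(small_cohort, tiny_hp):
    _, records, bags = small_cohort
    labels = np.array([int(r.gene_labels["TP53"] == "mutant") for r in records])
    model = cm.train_classifier(bags[:20], labels[:20], tiny_hp)
    preds = cm.predict(model, bags[:5])
    assert cm.predict(model, []) == []
    for bag, pred in zip(bags[:5], preds):
        single = cm.slide_logits(bag, model)
        assert np.abs(pred.probabilities - single.probabilities).max() < 1e-7


def test_model_round_trip(tmp_path, tiny_hp, small_cohort):
    _, records, bags = small_cohort
    labels = np.array([int(r.gene_labels["ATRX"] == "mutant") for r in records])
    model = cm.train_classifier(bags[:20], labels[:20], tiny_hp)
    model.save(tmp_path / "m.npz")
    loaded = cm.MILModel.load(tmp_path / "m.npz")
    assert loaded.hyperparams == model.hyperparams
    assert loaded.training_log == model.training_log
    for k in model.params:
        np.testing.assert_array_equal(model.params[k], loaded.params[k])
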
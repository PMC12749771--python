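"""Single-block transformer classifier for slide-level bags.

The classifier consumes a bag of patch feature vectors (rows of ``x``),
applies one single-head self-attention block

    K = x W_K,  Q = x W_Q,  V = x W_V
    A = softmax(K Q^T)                       (softmax over the attended index,
                                              each row of A a distribution)
    y_sa  = LN1(x + MLP_a(A V))              (MLP_a: attn_dim -> mlp_dim -> d)
    y_mlp = LN2(y_sa + MLP_b(y_sa))          (MLP_b: d -> mlp_dim -> d)

then mean-pools the rows of ``y_mlp`` into a slide feature and maps it
through a linear head with softmax to a (wild-type, mutant) probability
pair. There is no positional embedding, so the slide probability is
invariant to patch order. Attention scores are not scaled by 1/sqrt(d) by
default (``scale_scores`` turns it on). Both MLPs use ReLU; layer
normalisation is applied after each residual (post-norm).

Training follows the reference protocol: Adam (L2-coupled weight decay),
cross-entropy loss, batch size one bag, a class-balancing weighted sampler
(with replacement, epoch length = training-set size), fixed seeded
initialisation. Everything is plain numpy/float64 — bags are small enough
that a single CPU suffices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionMismatchError,
    EmptyBagError,
    SchemaVersionError,
)
from .synthetic import FeatureBag

MODEL_SCHEMA_VERSION = 1
_LN_EPS = 1e-5


@dataclass(frozen=True)
class MILHyperparams:
    feature_dim: int = 768
    attention_dim: int = 64
    mlp_dim: int = 1024
    n_heads: int = 1
    epochs: int = 80
    learning_rate: float = 1e-4
    batch_size: int = 1
    weight_decay: float = 5e-3
    scale_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("feature_dim", "attention_dim", "mlp_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_heads != 1:
            raise ConfigurationError("only single-head attention is supported")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be >= 0")


@dataclass
class AttentionOutput:
    A: np.ndarray  # (N, N), rows sum to 1
    y_sa: np.ndarray  # (N, d)
    y_mlp: np.ndarray | None = None  # (N, d)


@dataclass
class SlidePrediction:
    slide_id: str
    probabilities: np.ndarray  # (wild-type, mutant)
    predicted_label: int | None = None

    @property
    def p_mutant(self) -> float:
        return float(self.probabilities[1])


_PARAM_NAMES = (
    "Wk", "Wq", "Wv",
    "A1", "b1", "A2", "b2",
    "ln1_g", "ln1_b",
    "B1", "c1", "B2", "c2",
    "ln2_g", "ln2_b",
    "H", "hb",
)


@dataclass
class MILModel:
    params: dict[str, np.ndarray]
    hyperparams: MILHyperparams
    training_log: list[float] = field(default_factory=list)

    @classmethod
    def initialise(cls, hp: MILHyperparams) -> "MILModel":
        """Seeded uniform fan-in initialisation; biases and LN offsets zero."""
        rng = np.random.default_rng(np.random.SeedSequence(hp.seed, spawn_key=(0,)))
        d, a, m = hp.feature_dim, hp.attention_dim, hp.mlp_dim

        def u(fan_in: int, *shape: int) -> np.ndarray:
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        params = {
            "Wk": u(d, d, a), "Wq": u(d, d, a), "Wv": u(d, d, a),
            "A1": u(a, a, m), "b1": np.zeros(m),
            "A2": u(m, m, d), "b2": np.zeros(d),
            "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
            "B1": u(d, d, m), "c1": np.zeros(m),
            "B2": u(m, m, d), "c2": np.zeros(d),
            "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
            "H": u(d, d, 2), "hb": np.zeros(2),
        }
        return cls(params=params, hyperparams=hp)

    def save(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "schema_version": MODEL_SCHEMA_VERSION,
                "hyperparams": asdict(self.hyperparams),
                "training_log": self.training_log,
            }
        )
        np.savez(Path(path), __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "MILModel":
        with np.load(Path(path)) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            if header.get("schema_version") != MODEL_SCHEMA_VERSION:
                raise SchemaVersionError("incompatible model schema version")
            params = {k: z[k] for k in z.files if k != "__header__"}
        return cls(
            params=params,
            hyperparams=MILHyperparams(**header["hyperparams"]),
            training_log=list(header["training_log"]),
        )


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _forward(x: np.ndarray, model: MILModel):
    """Full forward pass; returns (probabilities, cache of intermediates)."""
    p = model.params
    hp = model.hyperparams
    if x.ndim != 2:
        raise DimensionMismatchError("bag features must be 2-D")
    n, d = x.shape
    if n < 1:
        raise EmptyBagError("bag has no patches")
    if d != hp.feature_dim:
        raise DimensionMismatchError(
            f"bag feature dim {d} != model feature_dim {hp.feature_dim}"
        )
    K = x @ p["Wk"]
    Q = x @ p["Wq"]
    V = x @ p["Wv"]
    S = K @ Q.T
    if hp.scale_scores:
        S = S / np.sqrt(hp.attention_dim)
    S = S - S.max(axis=1, keepdims=True)
    expS = np.exp(S)
    A = expS / expS.sum(axis=1, keepdims=True)
    C = A @ V
    pre1 = C @ p["A1"] + p["b1"]
    M1 = np.maximum(pre1, 0.0)
    U1 = M1 @ p["A2"] + p["b2"]
    R1 = x + U1
    Ysa, ln1_cache = _layernorm(R1, p["ln1_g"], p["ln1_b"])
    pre2 = Ysa @ p["B1"] + p["c1"]
    M2 = np.maximum(pre2, 0.0)
    U2 = M2 @ p["B2"] + p["c2"]
    R2 = Ysa + U2
    Y, ln2_cache = _layernorm(R2, p["ln2_g"], p["ln2_b"])
    pooled = Y.mean(axis=0)
    logits = pooled @ p["H"] + p["hb"]
    z = logits - logits.max()
    probs = np.exp(z) / np.exp(z).sum()
    cache = dict(
        x=x, K=K, Q=Q, V=V, A=A, C=C, pre1=pre1, M1=M1, R1=R1,
        ln1=ln1_cache, Ysa=Ysa, pre2=pre2, M2=M2, R2=R2, ln2=ln2_cache,
        Y=Y, pooled=pooled, probs=probs,
    )
    return probs, cache


def attention_forward(x: np.ndarray | FeatureBag, model: MILModel) -> AttentionOutput:
    """Self-attention sub-layer output: the attention matrix A and y_sa."""
    if isinstance(x, FeatureBag):
        x = x.features
    _, cache = _forward(np.asarray(x, dtype=np.float64), model)
    return AttentionOutput(A=cache["A"], y_sa=cache["Ysa"])


def transformer_block(x: np.ndarray | FeatureBag, model: MILModel) -> np.ndarray:
    """Full block output y_mlp (after second residual + layer norm)."""
    if isinstance(x, FeatureBag):
        x = x.features
    _, cache = _forward(np.asarray(x, dtype=np.float64), model)
    return cache["Y"]


def slide_logits(
    bag: FeatureBag, model: MILModel, threshold: float | None = None
) -> SlidePrediction:
    """Mean-pool the block output and classify; probabilities sum to 1."""
    probs, _ = _forward(bag.features, model)
    label = None if threshold is None else int(probs[1] >= threshold)
    return SlidePrediction(bag.slide_id, probabilities=probs, predicted_label=label)


def predict(model: MILModel, bags: list[FeatureBag]) -> list[SlidePrediction]:
    return [slide_logits(bag, model) for bag in bags]


# ---------------------------------------------------------------------------
# backward pass + Adam training loop
# ---------------------------------------------------------------------------


def _layernorm_backward(dy, x_shape_cache, g):
    xhat, inv = x_shape_cache
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
    )
    return dx, dgamma, dbeta


def _backward(model: MILModel, cache: dict, y_true: int) -> dict[str, np.ndarray]:
    """Gradient of the cross-entropy loss for one bag, by reverse-mode rules."""
    p = model.params
    hp = model.hyperparams
    x, A, V = cache["x"], cache["A"], cache["V"]
    n = x.shape[0]
    g: dict[str, np.ndarray] = {}

    dlogits = cache["probs"].copy()
    dlogits[y_true] -= 1.0
    g["H"] = np.outer(cache["pooled"], dlogits)
    g["hb"] = dlogits
    dY = np.tile((p["H"] @ dlogits) / n, (n, 1))

    dR2, g["ln2_g"], g["ln2_b"] = _layernorm_backward(dY, cache["ln2"], p["ln2_g"])
    dU2 = dR2
    g["B2"] = cache["M2"].T @ dU2
    g["c2"] = dU2.sum(axis=0)
    dpre2 = (dU2 @ p["B2"].T) * (cache["pre2"] > 0)
    g["B1"] = cache["Ysa"].T @ dpre2
    g["c1"] = dpre2.sum(axis=0)
    dYsa = dR2 + dpre2 @ p["B1"].T

    dR1, g["ln1_g"], g["ln1_b"] = _layernorm_backward(dYsa, cache["ln1"], p["ln1_g"])
    dU1 = dR1
    g["A2"] = cache["M1"].T @ dU1
    g["b2"] = dU1.sum(axis=0)
    dpre1 = (dU1 @ p["A2"].T) * (cache["pre1"] > 0)
    g["A1"] = cache["C"].T @ dpre1
    g["b1"] = dpre1.sum(axis=0)
    dC = dpre1 @ p["A1"].T

    dA = dC @ V.T
    dV = A.T @ dC
    # softmax rows backward
    dS = A * (dA - (dA * A).sum(axis=1, keepdims=True))
    if hp.scale_scores:
        dS = dS / np.sqrt(hp.attention_dim)
    dK = dS @ cache["Q"]
    dQ = dS.T @ cache["K"]
    g["Wk"] = x.T @ dK
    g["Wq"] = x.T @ dQ
    g["Wv"] = x.T @ dV
    return g


def bag_loss(model: MILModel, bag_features: np.ndarray, y_true: int) -> float:
    probs, _ = _forward(bag_features, model)
    return float(-np.log(max(probs[y_true], 1e-300)))


def train_classifier(
    bags: list[FeatureBag],
    labels: np.ndarray | list[int],
    hyperparams: MILHyperparams,
) -> MILModel:
    """Train on (bag, binary label) pairs; deterministic given the seed.

    The sampler draws ``len(bags)`` bags per epoch with replacement, each bag
    with probability inversely proportional to its class frequency.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(bags) != labels.size:
        raise DimensionMismatchError("bags and labels differ in length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise DegenerateInputError("training set must contain both classes")
    hp = hyperparams
    model = MILModel.initialise(hp)
    sampler = np.random.default_rng(np.random.SeedSequence(hp.seed, spawn_key=(1,)))

    freq = {int(c): float((labels == c).sum()) for c in classes}
    weights = np.array([1.0 / freq[int(y)] for y in labels])
    weights = weights / weights.sum()

    m_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n_train = len(bags)
    feats = [np.asarray(b.features, dtype=np.float64) for b in bags]

    for _epoch in range(hp.epochs):
        order = sampler.choice(n_train, size=n_train, replace=True, p=weights)
        epoch_loss = 0.0
        for idx in order:
            probs, cache = _forward(feats[idx], model)
            y = int(labels[idx])
            epoch_loss += -np.log(max(probs[y], 1e-300))
            grads = _backward(model, cache, y)
            t += 1
            for k, param in model.params.items():
                gk = grads[k] + hp.weight_decay * param
                m_t[k] = beta1 * m_t[k] + (1 - beta1) * gk
                v_t[k] = beta2 * v_t[k] + (1 - beta2) * gk * gk
                mhat = m_t[k] / (1 - beta1**t)
                vhat = v_t[k] / (1 - beta2**t)
                param -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.training_log.append(float(epoch_loss / n_train))
    return model
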
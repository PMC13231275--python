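"""Ordinal sparse neural network: architecture, forward pass and serialization.

The network maps the concatenated input t = (x, r, z) of length m0 = p + p*q + q
through a *sparse layer* (one trainable weight per covariate, unit weights on the
q environmental variables), then L dense layers with ReLU activations and a scalar
output s, and finally an ordinal output function

    [sigma_alpha(s)]_k = sigmoid(alpha_k + s) - sigmoid(alpha_{k-1} + s),

with strictly increasing cutpoints alpha (alpha_0 = -inf, alpha_K = +inf held
implicitly).  Monotonicity of the cutpoints is guaranteed by the reparameterization
alpha_1 = gamma_1, alpha_k = alpha_1 + sum_{j<=k} exp(gamma_j), which lets gamma
vary freely during training.

A nominal (softmax, width-K head) variant of the same architecture is provided for
ablation studies; it discards the ordering information in the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Cutpoints",
    "SparseLayerCoefs",
    "DenseParams",
    "ModelState",
    "gamma_to_alpha",
    "sigmoid",
    "apply_sparse_layer",
    "network_scalar",
    "ordinal_output",
    "predict",
    "predict_proba",
    "init_model",
    "model_to_json",
    "model_from_json",
]


def sigmoid(x: np.ndarray | float) -> np.ndarray:
    """Numerically stable logistic function (no overflow for |x| up to 700+)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gamma_to_alpha(gamma: np.ndarray) -> np.ndarray:
    """Map free cutpoint parameters to strictly increasing cutpoints.

    alpha[0] = gamma[0]; alpha[k] = alpha[0] + sum_{j=1..k} exp(gamma[j]).
    """
    gamma = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(gamma)):
        raise FloatingPointError("gamma must be finite")
    alpha = np.empty_like(gamma)
    alpha[0] = gamma[0]
    if len(gamma) > 1:
        alpha[1:] = gamma[0] + np.cumsum(np.exp(gamma[1:]))
    return alpha


@dataclass
class Cutpoints:
    """Free parameters gamma and the derived increasing cutpoints alpha."""

    gamma: np.ndarray

    @property
    def alpha(self) -> np.ndarray:
        return gamma_to_alpha(self.gamma)


@dataclass
class SparseLayerCoefs:
    """Trainable per-covariate weights of the sparse input layer.

    b (length p) weights the main effects, eta (p x q) the interactions; the q
    environmental variables carry fixed unit weights and are never penalized or
    selected.  The assembled coefficient vector beta = (b, vec(eta), 1_q) has
    length p + p*q + q.
    """

    b: np.ndarray    # (p,)
    eta: np.ndarray  # (p, q)

    @property
    def p(self) -> int:
        return self.b.shape[0]

    @property
    def q(self) -> int:
        return self.eta.shape[1]

    def beta(self) -> np.ndarray:
        return np.concatenate([self.b, self.eta.ravel(), np.ones(self.q)])

    def group_norms(self) -> np.ndarray:
        """||kappa_j||_2 for each group kappa_j = (b_j, eta_j1, ..., eta_jq)."""
        return np.sqrt(self.b**2 + (self.eta**2).sum(axis=1))

    def copy(self) -> "SparseLayerCoefs":
        return SparseLayerCoefs(self.b.copy(), self.eta.copy())


@dataclass
class DenseParams:
    """Weights and biases of the dense part; ReLU between layers, linear output."""

    weights: list[np.ndarray]  # W_l with shape (m_l, m_{l-1})
    biases: list[np.ndarray]   # v_l with shape (m_l,)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must have equal length")
        for l, (W, v) in enumerate(zip(self.weights, self.biases)):
            if W.shape[0] != v.shape[0]:
                raise ValueError(f"layer {l}: W rows {W.shape[0]} != bias size {v.shape[0]}")
            if l > 0 and W.shape[1] != self.weights[l - 1].shape[0]:
                raise ValueError(f"layer {l}: shape chain broken")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def m0(self) -> int:
        return self.weights[0].shape[1]

    def copy(self) -> "DenseParams":
        return DenseParams([W.copy() for W in self.weights], [v.copy() for v in self.biases])


@dataclass
class ModelState:
    """Full parameter state: sparse layer (optional), dense stack, cutpoints.

    ``head='ordinal'`` uses the cumulative-logit output with K-1 cutpoints and a
    scalar dense output; ``head='softmax'`` uses a width-K dense output with a
    softmax (the nominal-classification ablation) and carries no cutpoints.
    ``sparse=None`` models the dense ablation without a sparse layer.
    """

    sparse: SparseLayerCoefs | None
    dense: DenseParams
    gamma: np.ndarray | None
    K: int
    head: str = "ordinal"

    def __post_init__(self) -> None:
        if self.head not in ("ordinal", "softmax"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head == "ordinal":
            if self.gamma is None or len(self.gamma) != self.K - 1:
                raise ValueError("ordinal head requires K-1 gamma parameters")
            if self.dense.weights[-1].shape[0] != 1:
                raise ValueError("ordinal head requires scalar dense output")
        else:
            if self.dense.weights[-1].shape[0] != self.K:
                raise ValueError("softmax head requires width-K dense output")

    @property
    def alpha(self) -> np.ndarray:
        if self.gamma is None:
            raise ValueError("softmax head has no cutpoints")
        return gamma_to_alpha(self.gamma)

    def copy(self) -> "ModelState":
        return ModelState(
            sparse=None if self.sparse is None else self.sparse.copy(),
            dense=self.dense.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
            K=self.K,
            head=self.head,
        )


def apply_sparse_layer(
    x: np.ndarray, r: np.ndarray, z: np.ndarray, sparse: SparseLayerCoefs
) -> np.ndarray:
    """Weight the inputs: (b*x, vec(eta)*r, z), concatenated in that order.

    Accepts single vectors or (n, .) matrices.
    """
    single = np.ndim(x) == 1
    x, r, z = np.atleast_2d(x), np.atleast_2d(r), np.atleast_2d(z)
    p, q = sparse.p, sparse.q
    if x.shape[1] != p or z.shape[1] != q or r.shape[1] != p * q:
        raise ValueError(
            f"shape mismatch: expected p={p}, q={q}, pq={p*q}; "
            f"got {x.shape[1]}, {z.shape[1]}, {r.shape[1]}"
        )
    out = np.hstack([x * sparse.b, r * sparse.eta.ravel(), z])
    return out[0] if single else out


def _dense_forward(dense: DenseParams, T: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward through the dense stack; returns (output, pre-activations).

    ReLU after every layer except the last.
    """
    pres: list[np.ndarray] = []
    a = T
    for l, (W, v) in enumerate(zip(dense.weights, dense.biases)):
        pre = a @ W.T + v
        pres.append(pre)
        a = np.maximum(pre, 0.0) if l < dense.n_layers - 1 else pre
    return a, pres


def network_scalar(t_weighted: np.ndarray, dense: DenseParams) -> np.ndarray | float:
    """Scalar pre-output s = W_L psi(... psi(W_1 t + v_1) ...) + v_L."""
    single = t_weighted.ndim == 1
    T = np.atleast_2d(t_weighted)
    out, _ = _dense_forward(dense, T)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite network output")
    s = out[:, 0]
    return float(s[0]) if single else s


def ordinal_output(s: np.ndarray | float, alpha: np.ndarray) -> np.ndarray:
    """Class probabilities sigmoid(alpha_k + s) - sigmoid(alpha_{k-1} + s).

    The boundary cutpoints alpha_0 = -inf and alpha_K = +inf enter as cumulative
    probabilities 0 and 1 and are never stored.  Rows sum to 1 by construction.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("cutpoints alpha must be strictly increasing")
    single = np.ndim(s) == 0
    s = np.atleast_1d(np.asarray(s, dtype=float))
    cum = sigmoid(alpha[None, :] + s[:, None])          # (n, K-1)
    n = s.shape[0]
    full = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
    probs = np.diff(full, axis=1)
    return probs[0] if single else probs


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(data, model: ModelState) -> np.ndarray:
    """Class-probability matrix (n, K) for a dataset with .features()."""
    T = data.features() if hasattr(data, "features") else np.atleast_2d(data)
    m0 = model.dense.m0
    if T.shape[1] != m0:
        raise ValueError(f"feature width {T.shape[1]} != model input width {m0}")
    if model.sparse is not None:
        T = T * model.sparse.beta()
    out, _ = _dense_forward(model.dense, T)
    if model.head == "ordinal":
        return ordinal_output(out[:, 0], model.alpha)
    return _softmax(out)


def predict(data, model: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and argmax class labels (ties -> smallest class index)."""
    probs = predict_proba(data, model)
    labels = 1 + np.argmax(probs, axis=1)
    return probs, labels


def init_model(
    p: int,
    q: int,
    K: int,
    hidden: tuple[int, ...] = (128, 128),
    head: str = "ordinal",
    use_sparse: bool = True,
    rng: np.random.Generator | None = None,
    sparse_init: float = 0.2,
    gamma_init_sd: float = 2.0,
) -> ModelState:
    """Fresh model with Glorot-uniform dense weights.

    The sparse-layer coefficients start at a nonzero constant (``sparse_init``)
    so penalized groups can move away from the origin; gamma is drawn from
    N(0, gamma_init_sd^2).
    """
    if rng is None:
        rng = np.random.default_rng()
    m0 = p + p * q + q
    out_width = 1 if head == "ordinal" else K
    sizes = (m0, *hidden, out_width)
    weights, biases = [], []
    for m_in, m_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (m_in + m_out))
        weights.append(rng.uniform(-limit, limit, size=(m_out, m_in)))
        biases.append(np.zeros(m_out))
    dense = DenseParams(weights, biases)
    sparse = (
        SparseLayerCoefs(np.full(p, sparse_init), np.full((p, q), sparse_init))
        if use_sparse
        else None
    )
    gamma = rng.normal(0.0, gamma_init_sd, size=K - 1) if head == "ordinal" else None
    return ModelState(sparse=sparse, dense=dense, gamma=gamma, K=K, head=head)


def model_to_json(model: ModelState) -> str:
    """Serialize to a JSON document (decimal round-trip exact via repr floats)."""
    doc = {
        "K": model.K,
        "head": model.head,
        "gamma": None if model.gamma is None else model.gamma.tolist(),
        "sparse": None
        if model.sparse is None
        else {"b": model.sparse.b.tolist(), "eta": model.sparse.eta.tolist()},
        "dense": {
            "weights": [W.tolist() for W in model.dense.weights],
            "biases": [v.tolist() for v in model.dense.biases],
        },
    }
    return json.dumps(doc)


def model_from_json(doc: str) -> ModelState:
    d = json.loads(doc)
    sparse = None
    if d["sparse"] is not None:
        sparse = SparseLayerCoefs(
            np.asarray(d["sparse"]["b"], dtype=float),
            np.asarray(d["sparse"]["eta"], dtype=float),
        )
    dense = DenseParams(
        [np.asarray(W, dtype=float) for W in d["dense"]["weights"]],
        [np.asarray(v, dtype=float) for v in d["dense"]["biases"]],
    )
    gamma = None if d["gamma"] is None else np.asarray(d["gamma"], dtype=float)
    return ModelState(sparse=sparse, dense=dense, gamma=gamma, K=d["K"], head=d["head"])
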
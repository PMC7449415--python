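"""A small feed-forward multilayer perceptron, evaluated exactly.

The classifier used throughout is a three-layer network: 16 input nodes (one
per technology, rescaled to ±1), a tanh hidden layer of 10 nodes, and an
output layer with either a softmax head of 3 nodes (three-way classification,
outputs sum to one and read as class probabilities) or a single sigmoid node
(two-way classification, output read as P(LSA)).

Parameters flatten in a fixed, documented order — W1 row-major, b1, W2
row-major, b2 — so that Jacobian columns, weight penalties and serialized
networks line up reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

SOFTMAX = "softmax"
SIGMOID = "sigmoid"


@dataclass
class NetworkParameters:
    """Weights and biases of one 16→10→K perceptron.

    ``W1`` is hidden×input, ``b1`` hidden, ``W2`` output×hidden, ``b2``
    output; ``output_head`` is ``"softmax"`` (K≥2) or ``"sigmoid"`` (K=1).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    output_head: str = SOFTMAX

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        H, I = self.W1.shape
        K = self.W2.shape[0]
        if self.b1.shape != (H,) or self.W2.shape != (K, H) or self.b2.shape != (K,):
            raise ValueError("inconsistent parameter shapes")
        if self.output_head not in (SOFTMAX, SIGMOID):
            raise ValueError(f"unknown output head: {self.output_head!r}")
        if self.output_head == SIGMOID and K != 1:
            raise ValueError("sigmoid head requires a single output node")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite network parameter")

    # ------------------------------------------------------------------ sizes
    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[0]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    # ------------------------------------------------------------- flattening
    def flatten(self) -> np.ndarray:
        """Parameters as one vector: W1 row-major, b1, W2 row-major, b2."""
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def with_flat(self, theta: np.ndarray) -> "NetworkParameters":
        """A new parameter set with the same shapes, values from ``theta``."""
        H, I = self.W1.shape
        K = self.W2.shape[0]
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError("flat parameter vector has wrong length")
        o = 0
        W1 = theta[o : o + H * I].reshape(H, I); o += H * I
        b1 = theta[o : o + H]; o += H
        W2 = theta[o : o + K * H].reshape(K, H); o += K * H
        b2 = theta[o : o + K]
        return NetworkParameters(W1, b1, W2, b2, self.output_head)

    def bias_mask(self) -> np.ndarray:
        """Boolean mask over the flat vector marking bias entries."""
        H, I = self.W1.shape
        K = self.W2.shape[0]
        mask = np.zeros(self.n_params, dtype=bool)
        mask[H * I : H * I + H] = True
        mask[H * I + H + K * H :] = True
        return mask

    # ---------------------------------------------------------- serialization
    def to_json(self, path: str | Path | None = None, **extra) -> str:
        doc = {
            "shapes": {"n_inputs": self.n_inputs, "n_hidden": self.n_hidden,
                       "n_outputs": self.n_outputs},
            "output_head": self.output_head,
            "theta": self.flatten().tolist(),
        }
        doc.update(extra)
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @staticmethod
    def from_json(source: str | Path) -> "NetworkParameters":
        text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith(".json")
        ) else str(source)
        doc = json.loads(text)
        s = doc["shapes"]
        template = NetworkParameters(
            np.zeros((s["n_hidden"], s["n_inputs"])),
            np.zeros(s["n_hidden"]),
            np.zeros((s["n_outputs"], s["n_hidden"])),
            np.zeros(s["n_outputs"]),
            doc["output_head"],
        )
        return template.with_flat(np.array(doc["theta"], dtype=float))


def rescale_inputs(rows: np.ndarray) -> np.ndarray:
    """Map binary presence/absence {0,1} to the symmetric range {−1,+1}.

    Symmetric inputs keep the tanh hidden layer centred and give presence and
    absence equal leverage on the weighted sums.
    """
    rows = np.asarray(rows)
    if not np.isin(np.unique(rows), [0, 1]).all():
        raise ValueError("rescale_inputs requires binary {0,1} entries")
    return rows.astype(float) * 2.0 - 1.0


def init_network(
    n_in: int,
    n_hidden: int,
    head: str,
    rng: np.random.Generator,
    n_out: int | None = None,
) -> NetworkParameters:
    """Seeded Nguyen–Widrow-style initialization.

    Hidden-layer weight rows are uniform(−1,1) draws renormalized to magnitude
    0.7·H^(1/I), with biases spread uniformly over ±that magnitude — the
    classic scheme for placing tanh units' active regions across the input
    cube, which conditions Levenberg–Marquardt well on small networks. The
    output layer uses plain uniform(−0.5, 0.5) draws.
    """
    if n_in < 1 or n_hidden < 1:
        raise ValueError("layer sizes must be positive")
    if n_out is None:
        n_out = 1 if head == SIGMOID else 3
    beta = 0.7 * n_hidden ** (1.0 / n_in)
    W1 = rng.uniform(-1.0, 1.0, size=(n_hidden, n_in))
    norms = np.linalg.norm(W1, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    W1 = beta * W1 / norms
    b1 = rng.uniform(-beta, beta, size=n_hidden)
    W2 = rng.uniform(-0.5, 0.5, size=(n_out, n_hidden))
    b2 = rng.uniform(-0.5, 0.5, size=n_out)
    return NetworkParameters(W1, b1, W2, b2, head)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def hidden_activations(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.tanh(X @ params.W1.T + params.b1)


def forward(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    """Evaluate the network on rescaled inputs.

    Returns an ``(n, K)`` array of output-node values: softmax probabilities
    (rows sum to one) or the single sigmoid P(LSA). A 1-D input yields a 1-D
    output.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    H = hidden_activations(params, X)
    Z = H @ params.W2.T + params.b2
    if params.output_head == SOFTMAX:
        Y = _softmax(Z)
    else:
        Y = expit(Z)
    return Y[0] if single else Y


def class_probabilities(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    """Per-class probabilities under the network's classification scheme.

    Softmax head: the outputs directly. Sigmoid head: columns (p, 1−p) for
    (LSA, MSA).
    """
    Y = np.atleast_2d(forward(params, X))
    if params.output_head == SIGMOID:
        Y = np.hstack([Y, 1.0 - Y])
    return Y


def predict_classes(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    """Argmax class indices; ties break to the lowest class index."""
    return np.argmax(class_probabilities(params, X), axis=1)


def jacobian(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    """Jacobian of the output values with respect to the flat parameters.

    Rows run over (sample, output node) pairs, sample-major; columns over the
    flat parameter order (W1 row-major, b1, W2 row-major, b2). Because
    residuals are (output − target) with constant targets, this is also the
    residual Jacobian used by Levenberg–Marquardt.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("jacobian requires a nonempty batch")
    H = params.n_hidden
    I = params.n_inputs
    K = params.n_outputs
    h = np.tanh(X @ params.W1.T + params.b1)          # (n, H)
    Z = h @ params.W2.T + params.b2                    # (n, K)
    if params.output_head == SOFTMAX:
        Y = _softmax(Z)
        # dY_k/dZ_a = y_k (δ_ka − y_a)
        S = np.einsum("nk,ka->nka", Y, np.eye(K)) - np.einsum("nk,na->nka", Y, Y)
    else:
        Y = expit(Z)
        S = (Y * (1.0 - Y))[:, :, None]                # (n, 1, 1)
    # output layer
    J_W2 = np.einsum("nka,nh->nkah", S, h).reshape(n, K, K * H)
    J_b2 = S                                           # (n, K, K)
    # back through hidden layer
    back = np.einsum("nka,ah->nkh", S, params.W2)      # (n, K, H)
    B = back * (1.0 - h ** 2)[:, None, :]              # (n, K, H)
    J_W1 = np.einsum("nkh,ni->nkhi", B, X).reshape(n, K, H * I)
    J_b1 = B                                           # (n, K, H)
    J = np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=2)
    return J.reshape(n * K, params.n_params)
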
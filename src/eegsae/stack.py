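"""Stacked sparse autoencoders with a softmax classification head.

Two autoencoders are trained greedily and without labels: the first
compresses the 228 engineered features to 50 hidden units, the second
compresses those 50 codes to 20.  Each minimizes

    J = (1/2n) sum ||x_hat - x||^2  +  (lambda/2) * ||W||^2
        + beta * sum_j KL(rho || rho_hat_j)

where ``rho_hat_j`` is hidden node j's mean activation over the training set
and KL is the Bernoulli Kullback-Leibler divergence — the sparsity penalty
drives each node to fire for few inputs.  Activations are sigmoid throughout,
encoder/decoder weights untied, and inputs min-max scaled to [0, 1] so the
sigmoid decoder can reconstruct them.  A softmax layer maps the 20-dimensional
code to the two class probabilities; optional supervised fine-tuning
backpropagates the cross-entropy through encoder1 -> encoder2 -> softmax.

Optimization is deterministic full-batch L-BFGS (scipy); all initialization
is seeded, so a (data, config) pair reproduces the trained weights bitwise.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.random import default_rng
from scipy.optimize import minimize

from .core import CLASS_CNT, CLASS_PNES, CHANNELS_1020
from .features import FEATURES_PER_CHANNEL, FeatureDataset

CLASS_ORDER = (CLASS_CNT, CLASS_PNES)  # posterior columns: [p_cnt, p_pnes]


class TrainingDivergedError(RuntimeError):
    """Non-finite cost during training; try a smaller learning rate or weaker penalty."""


@dataclass(frozen=True)
class SparseAEConfig:
    """Hyperparameters of one sparse autoencoder."""

    hidden_size: int
    weight_decay: float = 1e-4
    sparsity_weight: float = 1.0
    sparsity_target: float = 0.05
    max_iterations: int = 400
    seed: int = 0
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError(f"hidden_size must be >= 1, got {self.hidden_size}")
        if not 0.0 < self.sparsity_target < 1.0:
            raise ValueError(f"sparsity_target must be in (0, 1), got {self.sparsity_target}")
        if self.weight_decay < 0 or self.sparsity_weight < 0:
            raise ValueError("weight_decay and sparsity_weight must be >= 0")
        if self.activation != "sigmoid":
            raise ValueError(f"only sigmoid activation is supported, got {self.activation!r}")


@dataclass(frozen=True)
class SoftmaxConfig:
    weight_decay: float = 1e-4
    max_iterations: int = 400
    seed: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class FeatureScaler:
    """Per-feature min-max map to [0, 1], fitted on training data only.

    Constant features map to 0.5; out-of-range test values are clipped.
    """

    min_: np.ndarray
    range_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training features must be a non-empty 2-D matrix")
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        return cls(min_=lo, range_=rng)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        const = self.range_ == 0
        safe = np.where(const, 1.0, self.range_)
        out = np.clip((X - self.min_) / safe, 0.0, 1.0)
        out[:, const] = 0.5
        return out


fit_scaler = FeatureScaler.fit


def apply_scaler(scaler: FeatureScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


@dataclass
class SparseAutoencoder:
    """Trained encoder/decoder weights of one autoencoder stage."""

    W_enc: np.ndarray  # (hidden, input)
    b_enc: np.ndarray
    W_dec: np.ndarray  # (input, hidden)
    b_dec: np.ndarray
    config: SparseAEConfig
    history: list[float] = field(default_factory=list)

    @property
    def input_size(self) -> int:
        return self.W_enc.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.W_enc.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_size:
            raise ValueError(f"expected {self.input_size} input features, got {X.shape[1]}")
        return _sigmoid(X @ self.W_enc.T + self.b_enc)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.encode(X) @ self.W_dec.T + self.b_dec)


def encode(ae: SparseAutoencoder, X: np.ndarray) -> np.ndarray:
    return ae.encode(X)


def _ae_pack(We, be, Wd, bd):
    return np.concatenate([We.ravel(), be, Wd.ravel(), bd])


def _ae_unpack(theta, d, h):
    i = 0
    We = theta[i : i + h * d].reshape(h, d); i += h * d
    be = theta[i : i + h]; i += h
    Wd = theta[i : i + d * h].reshape(d, h); i += d * h
    bd = theta[i : i + d]
    return We, be, Wd, bd


def _ae_cost_grad(theta, X, cfg: SparseAEConfig):
    n, d = X.shape
    h = cfg.hidden_size
    We, be, Wd, bd = _ae_unpack(theta, d, h)
    A = _sigmoid(X @ We.T + be)
    Xh = _sigmoid(A @ Wd.T + bd)
    E = Xh - X
    lam, beta, rho = cfg.weight_decay, cfg.sparsity_weight, cfg.sparsity_target

    cost = 0.5 * np.sum(E * E) / n
    cost += 0.5 * lam * (np.sum(We * We) + np.sum(Wd * Wd))
    rho_hat = np.clip(A.mean(axis=0), 1e-8, 1.0 - 1e-8)
    if beta > 0:
        cost += beta * np.sum(
            rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))
        )

    d_out = E * Xh * (1.0 - Xh) / n
    gWd = d_out.T @ A + lam * Wd
    gbd = d_out.sum(axis=0)
    back = d_out @ Wd
    if beta > 0:
        back = back + beta * (-(rho / rho_hat) + (1.0 - rho) / (1.0 - rho_hat)) / n
    d_hid = back * A * (1.0 - A)
    gWe = d_hid.T @ X + lam * We
    gbe = d_hid.sum(axis=0)
    return cost, _ae_pack(gWe, gbe, gWd, gbd)


def _init_uniform(rng, shape):
    r = 1.0 / np.sqrt(shape[1])  # fan-in scaled symmetric uniform
    return rng.uniform(-r, r, size=shape)


def train_sparse_autoencoder(X: np.ndarray, config: SparseAEConfig) -> SparseAutoencoder:
    """Train one sparse autoencoder on (unlabelled) feature rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training features must be a non-empty 2-D matrix")
    n, d = X.shape
    h = config.hidden_size
    rng = default_rng(config.seed)
    theta0 = _ae_pack(
        _init_uniform(rng, (h, d)), np.zeros(h), _init_uniform(rng, (d, h)), np.zeros(d)
    )
    history: list[float] = []
    last_cost = [np.inf]

    def objective(theta):
        c, g = _ae_cost_grad(theta, X, config)
        if not np.isfinite(c):
            raise TrainingDivergedError(
                "autoencoder cost became non-finite; reduce sparsity_weight or "
                "weight_decay, or rescale the inputs"
            )
        last_cost[0] = float(c)
        return c, g

    def cb(theta):
        history.append(last_cost[0])

    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": config.max_iterations, "maxcor": 20}, callback=cb,
    )
    if not np.isfinite(res.fun):
        raise TrainingDivergedError("autoencoder training ended with non-finite cost")
    We, be, Wd, bd = _ae_unpack(res.x, d, h)
    c0, _ = _ae_cost_grad(theta0, X, config)
    history.insert(0, float(c0))
    return SparseAutoencoder(W_enc=We, b_enc=be, W_dec=Wd, b_dec=bd,
                             config=config, history=history)


@dataclass
class SoftmaxHead:
    """Two-way softmax classifier on the deepest code."""

    W: np.ndarray  # (2, hidden)
    b: np.ndarray
    config: SoftmaxConfig

    def proba(self, H: np.ndarray) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[1] != self.W.shape[1]:
            raise ValueError(f"expected {self.W.shape[1]} code dimensions, got {H.shape[1]}")
        return _softmax(H @ self.W.T + self.b)


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _labels_to_onehot(y) -> np.ndarray:
    y = np.asarray(y)
    classes = set(np.unique(y).tolist())
    if not classes <= set(CLASS_ORDER):
        raise ValueError(f"labels must be in {CLASS_ORDER}, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError(f"softmax training needs both classes, got only {sorted(classes)}")
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), (y == CLASS_PNES).astype(int)] = 1.0
    return Y


def _softmax_cost_grad(theta, H, Y, lam):
    n, h = H.shape
    W = theta[: 2 * h].reshape(2, h)
    b = theta[2 * h :]
    P = _softmax(H @ W.T + b)
    cost = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / n + 0.5 * lam * np.sum(W * W)
    G = (P - Y) / n
    gW = G.T @ H + lam * W
    gb = G.sum(axis=0)
    return cost, np.concatenate([gW.ravel(), gb])


def train_softmax(H: np.ndarray, y, config: SoftmaxConfig = SoftmaxConfig()) -> SoftmaxHead:
    H = np.asarray(H, dtype=float)
    Y = _labels_to_onehot(y)
    h = H.shape[1]
    rng = default_rng(config.seed)
    theta0 = np.concatenate([_init_uniform(rng, (2, h)).ravel(), np.zeros(2)])
    res = minimize(
        _softmax_cost_grad, theta0, args=(H, Y, config.weight_decay), jac=True,
        method="L-BFGS-B", options={"maxiter": config.max_iterations},
    )
    if not np.isfinite(res.fun):
        raise TrainingDivergedError("softmax training ended with non-finite cost")
    return SoftmaxHead(W=res.x[: 2 * h].reshape(2, h), b=res.x[2 * h :], config=config)


@dataclass(frozen=True)
class ClassPosterior:
    p_cnt: float
    p_pnes: float

    @property
    def predicted(self) -> str:
        return CLASS_PNES if self.p_pnes > 0.5 else CLASS_CNT


@dataclass
class EncoderStack:
    """Scaler + AE1 + AE2 + softmax head, with training provenance."""

    scaler: FeatureScaler
    ae1: SparseAutoencoder
    ae2: SparseAutoencoder
    softmax: SoftmaxHead
    fine_tuned: bool = False
    provenance: dict = field(default_factory=dict)

    def encode_h1(self, X: np.ndarray) -> np.ndarray:
        return self.ae1.encode(self.scaler.transform(X))

    def encode_h2(self, X: np.ndarray) -> np.ndarray:
        return self.ae2.encode(self.encode_h1(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) posteriors, columns [p_cnt, p_pnes]."""
        return self.softmax.proba(self.encode_h2(X))

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p[:, 1] > 0.5, CLASS_PNES, CLASS_CNT)


def predict(stack: EncoderStack, vector: np.ndarray) -> ClassPosterior:
    """Class posterior for a single feature vector."""
    p = stack.predict_proba(np.atleast_2d(vector))[0]
    return ClassPosterior(p_cnt=float(p[0]), p_pnes=float(p[1]))


def train_stack(
    features,
    y=None,
    cfg1: SparseAEConfig | None = None,
    cfg2: SparseAEConfig | None = None,
    softmax_cfg: SoftmaxConfig = SoftmaxConfig(),
) -> EncoderStack:
    """Greedy layerwise training: scaler -> AE1 -> AE2 -> softmax.

    The autoencoder stages never see ``y``; only the softmax head does.
    ``features`` may be a raw (n, d) matrix (with ``y``) or a
    :class:`~eegsae.features.FeatureDataset`.
    """
    if isinstance(features, FeatureDataset):
        X, y = features.X, features.y
    else:
        X = np.asarray(features, dtype=float)
    if y is None:
        raise ValueError("labels are required (for the softmax stage)")
    if cfg1 is None:
        cfg1 = SparseAEConfig(hidden_size=50)
    if cfg2 is None:
        cfg2 = SparseAEConfig(hidden_size=20, seed=cfg1.seed + 1)
    scaler = FeatureScaler.fit(X)
    Xs = scaler.transform(X)
    ae1 = train_sparse_autoencoder(Xs, cfg1)
    H1 = ae1.encode(Xs)
    ae2 = train_sparse_autoencoder(H1, cfg2)
    H2 = ae2.encode(H1)
    head = train_softmax(H2, y, softmax_cfg)
    provenance = {
        "dims": (X.shape[1], cfg1.hidden_size, cfg2.hidden_size, 2),
        "ae1": asdict(cfg1),
        "ae2": asdict(cfg2),
        "softmax": asdict(softmax_cfg),
    }
    return EncoderStack(scaler=scaler, ae1=ae1, ae2=ae2, softmax=head, provenance=provenance)


def _ft_cost_grad(stack_params, Xs, Y, lam):
    We1, be1, We2, be2, W, b = stack_params
    A1 = _sigmoid(Xs @ We1.T + be1)
    A2 = _sigmoid(A1 @ We2.T + be2)
    P = _softmax(A2 @ W.T + b)
    n = Xs.shape[0]
    cost = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / n + 0.5 * lam * np.sum(W * W)
    G = (P - Y) / n
    gW = G.T @ A2 + lam * W
    gb = G.sum(axis=0)
    d2 = (G @ W) * A2 * (1.0 - A2)
    gWe2 = d2.T @ A1
    gbe2 = d2.sum(axis=0)
    d1 = (d2 @ We2) * A1 * (1.0 - A1)
    gWe1 = d1.T @ Xs
    gbe1 = d1.sum(axis=0)
    return cost, (gWe1, gbe1, gWe2, gbe2, gW, gb)


def fine_tune(
    stack: EncoderStack,
    features,
    y=None,
    epochs: int = 100,
    learning_rate: float = 0.5,
) -> EncoderStack:
    """Supervised end-to-end refinement of encoder1 -> encoder2 -> softmax.

    Full-batch gradient descent with backtracking: a step that increases the
    cross-entropy is undone and the rate halved, so the loss trace is
    non-increasing by construction.  Returns a new stack; the input stack is
    untouched.  ``epochs=0`` returns an unchanged copy.
    """
    if isinstance(features, FeatureDataset):
        X, y = features.X, features.y
    else:
        X = np.asarray(features, dtype=float)
    out = copy.deepcopy(stack)
    if epochs == 0:
        return out
    Y = _labels_to_onehot(y)
    Xs = out.scaler.transform(X)
    lam = out.softmax.config.weight_decay
    params = [out.ae1.W_enc, out.ae1.b_enc, out.ae2.W_enc, out.ae2.b_enc,
              out.softmax.W, out.softmax.b]
    params = [p.copy() for p in params]
    lr = learning_rate
    cost, grads = _ft_cost_grad(params, Xs, Y, lam)
    history = [float(cost)]
    for _ in range(epochs):
        trial = [p - lr * g for p, g in zip(params, grads)]
        new_cost, new_grads = _ft_cost_grad(trial, Xs, Y, lam)
        if not np.isfinite(new_cost):
            raise TrainingDivergedError("fine-tuning cost became non-finite; lower learning_rate")
        if new_cost <= cost:
            params, cost, grads = trial, new_cost, new_grads
            history.append(float(cost))
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
    out.ae1.W_enc, out.ae1.b_enc = params[0], params[1]
    out.ae2.W_enc, out.ae2.b_enc = params[2], params[3]
    out.softmax.W, out.softmax.b = params[4], params[5]
    out.fine_tuned = True
    out.provenance = dict(out.provenance)
    out.provenance["fine_tune"] = {"epochs": epochs, "learning_rate": learning_rate,
                                   "loss_start": history[0], "loss_end": float(cost)}
    return out


def electrode_sensitivity(
    stack: EncoderStack,
    channel_labels: tuple[str, ...] = CHANNELS_1020,
) -> tuple[np.ndarray, list[str]]:
    """Per-channel importance from the trained weight matrices.

    Channel c's score is the absolute-weight path mass
    ``|W_softmax| @ |W_enc2| @ |W_enc1|`` summed over both class outputs and
    over c's 12 input features, normalized to sum to 1.  Returns the scores
    (in ``channel_labels`` order) and the channel ranking, most important
    first.
    """
    mass = np.abs(stack.softmax.W) @ np.abs(stack.ae2.W_enc) @ np.abs(stack.ae1.W_enc)
    per_input = mass.sum(axis=0)
    n_ch = per_input.size // FEATURES_PER_CHANNEL
    if n_ch != len(channel_labels):
        raise ValueError(
            f"stack input dimension implies {n_ch} channels but "
            f"{len(channel_labels)} labels were given"
        )
    scores = per_input.reshape(n_ch, FEATURES_PER_CHANNEL).sum(axis=1)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    ranking = [channel_labels[i] for i in np.argsort(-scores)]
    return scores, ranking


def save_stack(stack: EncoderStack, path: str | Path) -> None:
    """Serialize all weights, the scaler, and provenance into one .npz archive."""
    meta = {"fine_tuned": stack.fine_tuned, "provenance": stack.provenance,
            "format_version": 1}
    np.savez(
        Path(path),
        ae1_W_enc=stack.ae1.W_enc, ae1_b_enc=stack.ae1.b_enc,
        ae1_W_dec=stack.ae1.W_dec, ae1_b_dec=stack.ae1.b_dec,
        ae2_W_enc=stack.ae2.W_enc, ae2_b_enc=stack.ae2.b_enc,
        ae2_W_dec=stack.ae2.W_dec, ae2_b_dec=stack.ae2.b_dec,
        sm_W=stack.softmax.W, sm_b=stack.softmax.b,
        scaler_min=stack.scaler.min_, scaler_range=stack.scaler.range_,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_stack(path: str | Path) -> EncoderStack:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        prov = meta.get("provenance", {})
        cfg1 = SparseAEConfig(**prov["ae1"]) if "ae1" in prov else SparseAEConfig(
            hidden_size=z["ae1_W_enc"].shape[0])
        cfg2 = SparseAEConfig(**prov["ae2"]) if "ae2" in prov else SparseAEConfig(
            hidden_size=z["ae2_W_enc"].shape[0])
        sm_cfg = SoftmaxConfig(**prov["softmax"]) if "softmax" in prov else SoftmaxConfig()
        stack = EncoderStack(
            scaler=FeatureScaler(min_=z["scaler_min"], range_=z["scaler_range"]),
            ae1=SparseAutoencoder(z["ae1_W_enc"], z["ae1_b_enc"], z["ae1_W_dec"],
                                  z["ae1_b_dec"], cfg1),
            ae2=SparseAutoencoder(z["ae2_W_enc"], z["ae2_b_enc"], z["ae2_W_dec"],
                                  z["ae2_b_dec"], cfg2),
            softmax=SoftmaxHead(W=z["sm_W"], b=z["sm_b"], config=sm_cfg),
            fine_tuned=meta.get("fine_tuned", False),
            provenance=prov,
        )
    return stack
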
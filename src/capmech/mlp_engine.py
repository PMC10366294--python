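"""Multilayer perceptron for joint law classification and Ca regression.

The network maps the 1D membrane-node coordinate vector of a capsule's steady
footprint to (a) softmax probabilities over the three constitutive-law
families and (b) the two capillary numbers ``(Ca^Ks, Ca^Gs)``. Architecture:
a shared trunk of three hidden layers of 128 neurons, each Dense ->
batch-norm -> ReLU -> dropout, feeding a 3-way softmax classification head
and a 2-output linear regression head. Training minimises cross-entropy plus
a weighted squared loss on standardised regression targets with Adam,
mini-batches of 128, a 0.001 initial learning rate, dropout 0.3, a 10%
validation hold-out, plateau-driven learning-rate reduction and early
stopping at the best validation loss.

Everything is plain numpy: forward, back-propagation (including through the
batch-norm statistics), Adam, and a pure feed-forward inference path that
uses frozen running statistics, so prediction is a deterministic function of
its input. Parameters serialise to a single JSON file together with the
target standardisation and the feature-vector convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .membrane_laws import LAW_ORDER, FlowCondition, LawKind
from .profile_synthesis import Dataset

__all__ = [
    "TrainingConfig",
    "NetworkParameters",
    "Prediction",
    "forward",
    "losses",
    "train",
    "predict",
    "predict_batch",
    "softmax",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_PROB_FLOOR = 1e-12  # guards log(p) at a true class


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stabilised softmax along the last axis."""
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


@dataclass
class TrainingConfig:
    """Hyperparameters of the training protocol."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    validation_fraction: float = 0.10
    dropout: float = 0.3
    max_epochs: int = 5000
    plateau_patience: int = 100
    stop_patience: int = 300
    lr_factor: float = 0.1
    loss_weight: float = 1.0  # lambda multiplying the regression loss
    hidden: Tuple[int, ...] = (128, 128, 128)
    shared_trunk: bool = True  # False: two independent networks, one per head
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("batch_size", "max_epochs", "plateau_patience", "stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")


class _Net:
    """One trunk-plus-heads network and its Adam state (internal)."""

    def __init__(self, n_in: int, hidden: Sequence[int], n_cls: int, n_reg: int,
                 rng: np.random.Generator):
        self.hidden = list(hidden)
        self.W: List[np.ndarray] = []
        self.gamma: List[np.ndarray] = []
        self.beta: List[np.ndarray] = []
        self.run_mean: List[np.ndarray] = []
        self.run_var: List[np.ndarray] = []
        fan = n_in
        for h in hidden:
            # He initialisation for ReLU layers
            self.W.append(rng.standard_normal((fan, h)) * math.sqrt(2.0 / fan))
            self.gamma.append(np.ones(h))
            self.beta.append(np.zeros(h))
            self.run_mean.append(np.zeros(h))
            self.run_var.append(np.ones(h))
            fan = h
        self.Wc = rng.standard_normal((fan, n_cls)) * math.sqrt(1.0 / fan)
        self.bc = np.zeros(n_cls)
        self.Wr = rng.standard_normal((fan, n_reg)) * math.sqrt(1.0 / fan)
        self.br = np.zeros(n_reg)

    # -- parameter bookkeeping -------------------------------------------
    def params(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for l in range(len(self.W)):
            out += [self.W[l], self.gamma[l], self.beta[l]]
        out += [self.Wc, self.bc, self.Wr, self.br]
        return out

    def state_copy(self) -> List[np.ndarray]:
        return [p.copy() for p in self.params()] + [
            m.copy() for m in self.run_mean
        ] + [v.copy() for v in self.run_var]

    def load_state(self, state: List[np.ndarray]) -> None:
        n = len(self.params())
        for p, s in zip(self.params(), state[:n]):
            p[...] = s
        L = len(self.W)
        for l in range(L):
            self.run_mean[l][...] = state[n + l]
            self.run_var[l][...] = state[n + L + l]

    # -- forward / backward ----------------------------------------------
    def forward(self, X: np.ndarray, training: bool, dropout: float = 0.0,
                rng: Optional[np.random.Generator] = None):
        cache = {"h": [X], "xhat": [], "inv_std": [], "mask": [], "pre_relu": []}
        h = X
        for l in range(len(self.W)):
            a = h @ self.W[l]
            if training:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                self.run_mean[l] = _BN_MOMENTUM * self.run_mean[l] + (1 - _BN_MOMENTUM) * mu
                self.run_var[l] = _BN_MOMENTUM * self.run_var[l] + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean[l], self.run_var[l]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (a - mu) * inv_std
            y = self.gamma[l] * xhat + self.beta[l]
            h = relu(y)
            if training and dropout > 0.0:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
            else:
                mask = None
            cache["xhat"].append(xhat)
            cache["inv_std"].append(inv_std)
            cache["pre_relu"].append(y)
            cache["mask"].append(mask)
            cache["h"].append(h)
        logits = h @ self.Wc + self.bc
        reg = h @ self.Wr + self.br
        return logits, reg, cache

    def backward(self, cache, g_logits: np.ndarray, g_reg: np.ndarray):
        h_top = cache["h"][-1]
        grads: Dict[int, np.ndarray] = {}
        dWc = h_top.T @ g_logits
        dbc = g_logits.sum(axis=0)
        dWr = h_top.T @ g_reg
        dbr = g_reg.sum(axis=0)
        g = g_logits @ self.Wc.T + g_reg @ self.Wr.T
        out = []
        for l in reversed(range(len(self.W))):
            if cache["mask"][l] is not None:
                g = g * cache["mask"][l]
            g = g * (cache["pre_relu"][l] > 0)
            xhat = cache["xhat"][l]
            B = xhat.shape[0]
            dgamma = np.sum(g * xhat, axis=0)
            dbeta = np.sum(g, axis=0)
            # back-prop through the batch statistics
            ga = (self.gamma[l] * cache["inv_std"][l] / B) * (
                B * g - dbeta - xhat * dgamma
            )
            dW = cache["h"][l].T @ ga
            g = ga @ self.W[l].T
            out.append((dW, dgamma, dbeta))
        out.reverse()
        flat: List[np.ndarray] = []
        for dW, dgamma, dbeta in out:
            flat += [dW, dgamma, dbeta]
        flat += [dWc, dbc, dWr, dbr]
        return flat


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class NetworkParameters:
    """Trained network state: weights, normalisation, conventions, history."""

    nets: List[_Net]
    y_mean: np.ndarray
    y_std: np.ndarray
    n_in: int
    hidden: Tuple[int, ...]
    shared_trunk: bool
    dropout: float
    trained: bool = False
    history: List[Dict] = field(default_factory=list)
    manifest: Dict = field(default_factory=dict)

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: Union[str, Path]) -> None:
        def net_dict(net: _Net) -> Dict:
            return {
                "W": [w.tolist() for w in net.W],
                "gamma": [g.tolist() for g in net.gamma],
                "beta": [b.tolist() for b in net.beta],
                "run_mean": [m.tolist() for m in net.run_mean],
                "run_var": [v.tolist() for v in net.run_var],
                "Wc": net.Wc.tolist(), "bc": net.bc.tolist(),
                "Wr": net.Wr.tolist(), "br": net.br.tolist(),
            }

        payload = {
            "format": "capmech-mlp-1",
            "feature_convention": "interleaved (x1,y1,...) tube-radius units, "
                                  "leading-tip start, counter-clockwise",
            "law_order": [k.value for k in LAW_ORDER],
            "n_in": self.n_in,
            "hidden": list(self.hidden),
            "shared_trunk": self.shared_trunk,
            "dropout": self.dropout,
            "trained": self.trained,
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "nets": [net_dict(n) for n in self.nets],
            "manifest": self.manifest,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "NetworkParameters":
        data = json.loads(Path(path).read_text())
        nets = []
        for nd in data["nets"]:
            net = _Net.__new__(_Net)
            net.hidden = data["hidden"]
            net.W = [np.array(w) for w in nd["W"]]
            net.gamma = [np.array(g) for g in nd["gamma"]]
            net.beta = [np.array(b) for b in nd["beta"]]
            net.run_mean = [np.array(m) for m in nd["run_mean"]]
            net.run_var = [np.array(v) for v in nd["run_var"]]
            net.Wc = np.array(nd["Wc"]); net.bc = np.array(nd["bc"])
            net.Wr = np.array(nd["Wr"]); net.br = np.array(nd["br"])
            nets.append(net)
        return cls(
            nets=nets,
            y_mean=np.array(data["y_mean"]),
            y_std=np.array(data["y_std"]),
            n_in=data["n_in"],
            hidden=tuple(data["hidden"]),
            shared_trunk=data["shared_trunk"],
            dropout=data["dropout"],
            trained=data["trained"],
            manifest=data.get("manifest", {}),
        )


@dataclass
class Prediction:
    """Law probabilities, predicted capillary numbers and optional moduli."""

    probs: np.ndarray
    law_kind: LawKind
    ca_ks: float
    ca_gs: float
    Gs: Optional[float] = None
    Ks: Optional[float] = None


def forward(
    params: NetworkParameters,
    vector: np.ndarray,
    training_mode: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Raw head outputs (class probabilities, standardised regression)."""
    X = np.atleast_2d(np.asarray(vector, dtype=float))
    if X.shape[1] != params.n_in:
        raise ValueError(f"feature length {X.shape[1]} != input layer {params.n_in}")
    if training_mode and rng is None:
        rng = np.random.default_rng(0)
    if params.shared_trunk:
        logits, reg, _ = params.nets[0].forward(
            X, training_mode, params.dropout if training_mode else 0.0, rng
        )
    else:
        logits, _, _ = params.nets[0].forward(
            X, training_mode, params.dropout if training_mode else 0.0, rng
        )
        _, reg, _ = params.nets[1].forward(
            X, training_mode, params.dropout if training_mode else 0.0, rng
        )
    return softmax(logits), reg


def losses(
    probs: np.ndarray, reg: np.ndarray, z_onehot: np.ndarray, y_std_targets: np.ndarray
) -> Tuple[float, float]:
    """(cross-entropy, squared) losses, each averaged over the batch.

    The squared loss sums over the two standardised targets; the
    cross-entropy floors probabilities to avoid log(0) at a true class.
    """
    p = np.clip(probs, _PROB_FLOOR, 1.0)
    l_cls = float(-np.mean(np.sum(z_onehot * np.log(p), axis=1)))
    l_reg = float(np.mean(np.sum((y_std_targets - reg) ** 2, axis=1)))
    return l_cls, l_reg


def train(dataset: Dataset, config: Optional[TrainingConfig] = None) -> NetworkParameters:
    """Train the MLP on a labelled dataset; deterministic given the seed.

    Holds out ``validation_fraction`` of the samples, reduces the learning
    rate by ``lr_factor`` after ``plateau_patience`` epochs without
    validation improvement and stops after ``stop_patience`` further stagnant
    epochs (or ``max_epochs``), returning the parameters of the best
    validation epoch with per-epoch loss history attached.
    """
    config = config or TrainingConfig()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    X, z, y = dataset.matrices()
    n, n_in = X.shape
    if n < 2:
        raise ValueError("dataset too small to split")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size < 1:
        raise ValueError("no training samples left after validation split")
    if tr_idx.size < config.batch_size:
        batch_size = int(tr_idx.size)
    else:
        batch_size = config.batch_size

    y_mean = y[tr_idx].mean(axis=0)
    y_std = y[tr_idx].std(axis=0)
    y_std = np.where(y_std < 1e-12, 1.0, y_std)
    Ys = (y - y_mean) / y_std
    Z = np.eye(3)[z]

    n_nets = 1 if config.shared_trunk else 2
    nets = [_Net(n_in, config.hidden, 3, 2, rng) for _ in range(n_nets)]
    params = NetworkParameters(
        nets=nets, y_mean=y_mean, y_std=y_std, n_in=n_in,
        hidden=tuple(config.hidden), shared_trunk=config.shared_trunk,
        dropout=config.dropout, trained=False,
        manifest={"config": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in asdict(config).items()},
                  "n_train": int(tr_idx.size), "n_val": int(n_val)},
    )
    opts = [_Adam(net.params(), config.learning_rate) for net in nets]
    lam = config.loss_weight
    # head weights per net: shared trunk trains both heads jointly; the split
    # variant dedicates net 0 to classification and net 1 to regression.
    head_w = [(1.0, lam)] if config.shared_trunk else [(1.0, 0.0), (0.0, lam)]

    # Per-network plateau state. Each independent network monitors the
    # validation loss of its own head(s): the shared-trunk network uses the
    # combined loss, the split variant its dedicated classification or
    # regression loss — so late regression gains are not masked by the
    # irreducible classification entropy of confounded laws.
    best_val = [math.inf] * n_nets
    best_state = [net.state_copy() for net in nets]
    stagnant = [0] * n_nets  # epochs since each net's best validation loss
    since_reduce = [0] * n_nets  # epochs since each net's last lr reduction
    lr_scale = [1.0] * n_nets
    done = [False] * n_nets

    for epoch in range(config.max_epochs):
        order = rng.permutation(tr_idx)
        train_loss = 0.0
        n_batches = 0
        for s0 in range(0, order.size, batch_size):
            idx = order[s0:s0 + batch_size]
            if idx.size < 2:  # batch-norm needs at least two rows
                continue
            Xb, Zb, Yb = X[idx], Z[idx], Ys[idx]
            B = idx.size
            batch_loss = 0.0
            for i, (net, opt, (wc, wr)) in enumerate(zip(nets, opts, head_w)):
                if done[i]:
                    continue
                logits, reg, cache = net.forward(Xb, True, config.dropout, rng)
                p = softmax(logits)
                l_cls, l_reg = losses(p, reg, Zb, Yb)
                batch_loss += wc * l_cls + wr * l_reg
                g_logits = wc * (p - Zb) / B
                g_reg = wr * 2.0 * (reg - Yb) / B
                grads = net.backward(cache, g_logits, g_reg)
                opt.lr = config.learning_rate * lr_scale[i]
                opt.step(net.params(), grads)
            if not math.isfinite(batch_loss):
                raise FloatingPointError("non-finite training loss")
            train_loss += batch_loss
            n_batches += 1
        train_loss /= max(n_batches, 1)

        record = {"epoch": epoch, "train_loss": train_loss}
        for i, (net, (wc, wr)) in enumerate(zip(nets, head_w)):
            if done[i]:
                continue
            logits_v, reg_v, _ = net.forward(X[val_idx], False)
            lv_cls, lv_reg = losses(softmax(logits_v), reg_v, Z[val_idx], Ys[val_idx])
            val_loss = wc * lv_cls + wr * lv_reg
            if not math.isfinite(val_loss):
                raise FloatingPointError("non-finite validation loss")
            record[f"val_loss_{i}" if n_nets > 1 else "val_loss"] = val_loss
            record[f"lr_{i}" if n_nets > 1 else "lr"] = config.learning_rate * lr_scale[i]

            since_reduce[i] += 1
            if val_loss < best_val[i] - 1e-9:
                best_val[i] = val_loss
                best_state[i] = net.state_copy()
                stagnant[i] = 0
            else:
                stagnant[i] += 1
                if stagnant[i] >= config.stop_patience:
                    done[i] = True  # no progress even after reducing the lr
                elif (stagnant[i] >= config.plateau_patience
                        and since_reduce[i] >= config.plateau_patience):
                    lr_scale[i] *= config.lr_factor
                    since_reduce[i] = 0
        params.history.append(record)
        if all(done):
            break

    for net, state in zip(nets, best_state):
        net.load_state(state)
    params.trained = True
    params.manifest["best_val_loss"] = best_val if n_nets > 1 else best_val[0]
    params.manifest["epochs_run"] = len(params.history)
    return params


def predict_batch(
    params: NetworkParameters, vectors: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """(probabilities, de-standardised (Ca^Ks, Ca^Gs)) for a batch of vectors."""
    if not params.trained:
        raise ValueError("network parameters are untrained")
    probs, reg = forward(params, vectors, training_mode=False)
    ca = reg * params.y_std + params.y_mean
    ca = np.maximum(ca, 1e-9)  # capillary numbers are positive
    return probs, ca


def predict(
    params: NetworkParameters,
    vector: np.ndarray,
    flow: Optional[FlowCondition] = None,
) -> Prediction:
    """Predict the law family and capillary numbers for one feature vector.

    With a flow condition the dimensional moduli are attached via
    ``Gs = mu U / Ca^Gs`` and ``Ks = mu U / Ca^Ks``.
    """
    probs, ca = predict_batch(params, np.atleast_2d(vector))
    p = probs[0]
    ca_ks, ca_gs = float(ca[0, 0]), float(ca[0, 1])
    law = LAW_ORDER[int(np.argmax(p))]
    gs = ks = None
    if flow is not None:
        gs = flow.mu * flow.U / ca_gs
        ks = flow.mu * flow.U / ca_ks
    return Prediction(probs=p, law_kind=law, ca_ks=ca_ks, ca_gs=ca_gs, Gs=gs, Ks=ks)
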
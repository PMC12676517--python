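"""Windowed dense network for 1-D spectra.

The spectrum is cut into overlapping windows; each window feeds its own small
dense block (emulating a sparse convolution), the block outputs are
concatenated into a dense head with Bernoulli dropout, and a single sigmoid
unit emits the disease probability.  Implemented directly in numpy with
manual backpropagation and an Adam optimizer, so training is deterministic
given (config, seed, data ordering).

Dropout is the classic form: during training and stochastic inference a raw
Bernoulli(1-p) mask multiplies the head activations; during deterministic
inference the activations are scaled by (1-p).  The mean over stochastic
passes therefore converges to the deterministic output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NetConfig:
    window_size: int = 50
    stride: int = 25
    block_units: int = 8
    head_units: int = 16
    dropout_rate: float = 0.3
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    balanced_loss: bool = True
    seed: int = 0

    def validate(self, n: int | None = None) -> None:
        if not 1 <= self.stride <= self.window_size:
            raise ValueError("need 1 <= stride <= window_size")
        if n is not None and self.window_size > n:
            raise ValueError(f"window_size {self.window_size} exceeds grid length {n}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def window_slices(n: int, w: int, s: int) -> list[tuple[int, int]]:
    """Overlapping index ranges [i*s, i*s + w); a tail window anchored at n-w
    is appended when the regular windows do not reach n, so every grid point
    is covered."""
    if w > n:
        raise ValueError(f"window size {w} exceeds grid length {n}")
    if not 1 <= s <= w:
        raise ValueError("need 1 <= stride <= window size")
    slices = [(i * s, i * s + w) for i in range((n - w) // s + 1)]
    if slices[-1][1] < n:
        slices.append((n - w, n))
    return slices


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainedNet:
    """Windowed network parameters plus training provenance."""

    config: NetConfig
    n_input: int
    slices: list[tuple[int, int]]
    params: dict[str, np.ndarray]
    training_log: list[float] = field(default_factory=list)
    trained: bool = False

    @property
    def dropout_rate(self) -> float:
        return self.config.dropout_rate

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _windows(self, X: np.ndarray) -> np.ndarray:
        idx = np.array([np.arange(a, b) for a, b in self.slices])  # (n_win, w)
        return X[:, idx]  # (B, n_win, w)

    def _forward(
        self,
        X: np.ndarray,
        mode: str,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """mode: 'train' / 'stochastic' (Bernoulli mask) or 'mean' ((1-p) scaling)."""
        p = self.config.dropout_rate
        Xw = self._windows(X)
        Z1 = np.einsum("bnw,nwu->bnu", Xw, self.params["Wb"]) + self.params["bb"]
        A1 = np.tanh(Z1)
        A1f = A1.reshape(X.shape[0], -1)
        Z2 = A1f @ self.params["Wh"] + self.params["bh"]
        A2 = np.tanh(Z2)
        if mode == "mean" or p == 0.0:
            mask = None
            D = A2 if p == 0.0 else A2 * (1.0 - p)
        else:
            if rng is None:
                raise ValueError("stochastic forward pass requires an rng")
            mask = (rng.random(A2.shape) >= p).astype(float)
            D = A2 * mask
        z3 = D @ self.params["wo"] + self.params["bo"]
        prob = _sigmoid(z3[:, 0])
        cache = {"Xw": Xw, "A1": A1, "A1f": A1f, "A2": A2, "mask": mask, "D": D}
        return prob, cache

    def forward_proba(
        self,
        X: np.ndarray,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("network has not been trained")
        prob, _ = self._forward(
            np.asarray(X, dtype=float), "stochastic" if stochastic else "mean", rng
        )
        return prob


def build_net(config: NetConfig, n: int) -> TrainedNet:
    """Initialize an untrained network (Glorot-uniform weights from config.seed)."""
    config.validate(n)
    slices = window_slices(n, config.window_size, config.stride)
    rng = np.random.default_rng(config.seed)
    n_win, w, ub, uh = len(slices), config.window_size, config.block_units, config.head_units

    def glorot(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    params = {
        "Wb": glorot((n_win, w, ub), w, ub),
        "bb": np.zeros((n_win, ub)),
        "Wh": glorot((n_win * ub, uh), n_win * ub, uh),
        "bh": np.zeros(uh),
        "wo": glorot((uh, 1), uh, 1),
        "bo": np.zeros(1),
    }
    return TrainedNet(config=config, n_input=n, slices=slices, params=params)


def _backward(net: TrainedNet, cache: dict, prob: np.ndarray, y: np.ndarray,
              sample_weight: np.ndarray) -> dict:
    B = y.size
    dz3 = (sample_weight * (prob - y) / B)[:, None]
    grads = {
        "wo": cache["D"].T @ dz3,
        "bo": dz3.sum(axis=0),
    }
    dD = dz3 @ net.params["wo"].T
    p = net.config.dropout_rate
    dA2 = dD if cache["mask"] is None and p == 0.0 else dD * cache["mask"]
    dZ2 = dA2 * (1.0 - cache["A2"] ** 2)
    grads["Wh"] = cache["A1f"].T @ dZ2
    grads["bh"] = dZ2.sum(axis=0)
    dA1f = dZ2 @ net.params["Wh"].T
    dA1 = dA1f.reshape(cache["A1"].shape)
    dZ1 = dA1 * (1.0 - cache["A1"] ** 2)
    grads["Wb"] = np.einsum("bnw,bnu->nwu", cache["Xw"], dZ1)
    grads["bb"] = dZ1.sum(axis=0)
    return grads


def train(net: TrainedNet, X: np.ndarray, y: np.ndarray, config: NetConfig | None = None) -> TrainedNet:
    """Minimize binary cross-entropy with Adam for exactly config.epochs epochs.

    No early stopping; mini-batch order, dropout masks and weights are all
    drawn from a generator seeded by config.seed, so two runs with the same
    seed and data ordering produce identical weights.
    """
    config = config or net.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the training set")

    # inverse-prevalence class weights keep the decision threshold at 0.5 even
    # when the training set is deliberately imbalanced (e.g. after refinement
    # keeps all controls but few disease spectra)
    if config.balanced_loss:
        n1 = float(y.sum())
        n0 = float(y.size - n1)
        weight = np.where(y == 1.0, y.size / (2.0 * n1), y.size / (2.0 * n0))
    else:
        weight = np.ones_like(y)

    rng = np.random.default_rng(config.seed + 1)  # init used config.seed
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    t = 0
    n = X.shape[0]
    eps_p = 1e-12

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            prob, cache = net._forward(X[batch], "train", rng)
            yb = y[batch]
            wb = weight[batch]
            loss = -np.mean(
                wb * (yb * np.log(prob + eps_p) + (1.0 - yb) * np.log(1.0 - prob + eps_p))
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * batch.size
            grads = _backward(net, cache, prob, yb, wb)
            t += 1
            for k in net.params:
                g = grads[k].reshape(net.params[k].shape)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                net.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        net.training_log.append(epoch_loss / n)
    net.trained = True
    return net


def predict(net: TrainedNet, X: np.ndarray, stochastic: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-spectrum disease probability.

    stochastic=False disables dropout (weight scaling by 1-p): deterministic.
    stochastic=True applies one Bernoulli mask, as used by Monte Carlo Dropout.
    """
    return net.forward_proba(X, stochastic=stochastic, rng=rng)
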
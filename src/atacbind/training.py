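"""Training loop: Adam on binary cross-entropy, minibatch 35, iterations of
10 shuffled epochs each, keeping the 3 snapshots with the lowest
iteration-end validation losses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BindingCNN, ModelConfig, ModelEnsemble, bce_loss

__all__ = ["TrainConfig", "AdamState", "train"]


@dataclass(frozen=True)
class TrainConfig:
    minibatch: int = 35
    epoch_size: int = 10  # epochs per iteration
    max_iterations: int = 100
    # 1e-3 reliably collapses the all-positive concat features into dead
    # ReLUs on weak-signal data; 1e-4 trains stably
    learning_rate: float = 1e-4
    seed: int = 0
    n_best: int = 3

    def __post_init__(self):
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class AdamState:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[ModelEnsemble, list[dict]]:
    """Train and return (3-best ensemble, per-iteration loss trace).

    Each iteration runs ``epoch_size`` passes over the shuffled training set
    in minibatches (final partial batch kept); validation BCE is evaluated at
    the end of each iteration and the ``n_best`` lowest-loss snapshots are
    retained.  Fully deterministic under ``train_config.seed``.
    """
    train_config = train_config or TrainConfig()
    if len(X_train) == 0:
        raise ValueError("empty training set")
    if len(X_val) < 2:
        raise ValueError("validation set must have at least 2 examples")
    if model_config is None:
        model_config = ModelConfig(in_channels=X_train.shape[1],
                                   window_len=X_train.shape[2])
    rng = np.random.default_rng(train_config.seed)
    model = BindingCNN(model_config, seed=train_config.seed)
    opt = AdamState(model.params, train_config.learning_rate)
    n = len(X_train)
    bs = train_config.minibatch
    trace: list[dict] = []
    best: list[tuple[float, int, BindingCNN]] = []  # (val_loss, iteration, snapshot)
    Xtr = np.asarray(X_train, dtype=np.float64)
    ytr = np.asarray(y_train, dtype=np.float64)
    Xva = np.asarray(X_val, dtype=np.float64)
    yva = np.asarray(y_val, dtype=np.float64)
    for it in range(train_config.max_iterations):
        epoch_losses = []
        for _ in range(train_config.epoch_size):
            order = rng.permutation(n)
            for lo in range(0, n, bs):
                idx = order[lo : lo + bs]
                prob, cache = model.forward(Xtr[idx], return_cache=True)
                grads = model.backward(cache, ytr[idx])
                opt.step(model.params, grads)
                epoch_losses.append(bce_loss(prob, ytr[idx]))
        val_loss = bce_loss(model.forward(Xva), yva)
        trace.append(
            {"iteration": it, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss}
        )
        best.append((val_loss, it, model.copy()))
        best.sort(key=lambda t: (t[0], t[1]))
        best = best[: train_config.n_best]
    members = [snap for _, _, snap in best]
    while len(members) < train_config.n_best:  # fewer iterations than n_best
        members.append(members[-1].copy())
    meta = {
        "seed": train_config.seed,
        "iterations_run": train_config.max_iterations,
        "best_val_losses": [round(vl, 10) for vl, _, _ in best],
        "best_iterations": [it for _, it, _ in best],
    }
    return ModelEnsemble(members, model_config, meta), trace
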
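"""Multi-kernel 1D-CNN binding classifier (pure numpy).

Per kernel size k in {3, 5, 7}: a same-padded stride-1 convolution with 3
learnable filters and ReLU, then a max over the 3 feature maps at each
position, giving one 1 x W vector per kernel size.  The three vectors are
concatenated (3W) and passed through two fully connected layers
(3W -> hidden -> 1) with a final sigmoid.

Implemented directly in numpy with hand-derived gradients (validated by a
finite-difference check in the test suite) so the package has no deep
learning framework dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelConfig",
    "BindingCNN",
    "ModelEnsemble",
    "predict",
    "threshold_calls",
    "bce_loss",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 9
    window_len: int = 1000
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    filters_per_kernel: int = 3
    hidden_units: int = 32

    def __post_init__(self):
        for k in self.kernel_sizes:
            if k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd, got {k}")
        if self.filters_per_kernel < 1:
            raise ValueError("filters_per_kernel must be >= 1")


def _uniform_fan_in(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class BindingCNN:
    """Forward/backward passes and parameter management for the classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        C, W, H = config.in_channels, config.window_len, config.hidden_units
        F = config.filters_per_kernel
        self.params: dict[str, np.ndarray] = {}
        for k in config.kernel_sizes:
            fan = C * k
            self.params[f"conv{k}_w"] = _uniform_fan_in(rng, (F, C, k), fan)
            # small positive bias keeps ReLU maps alive under weak signal
            self.params[f"conv{k}_b"] = np.abs(_uniform_fan_in(rng, (F,), fan))
        concat_len = len(config.kernel_sizes) * W
        self.params["fc1_w"] = _uniform_fan_in(rng, (concat_len, H), concat_len)
        # concat features are non-negative with a large common-mode component,
        # so zero-mean biases leave half the hidden units dead from the start
        self.params["fc1_b"] = np.abs(_uniform_fan_in(rng, (H,), concat_len)) + 0.01
        self.params["fc2_w"] = _uniform_fan_in(rng, (H, 1), H)
        self.params["fc2_b"] = _uniform_fan_in(rng, (1,), H)

    # ---------------------------------------------------------------- forward
    def forward(
        self, X: np.ndarray, return_cache: bool = False
    ):
        """Binding probabilities for a batch of (C, W) windows.

        ``X`` has shape (B, C, W); output shape (B,), strictly inside (0, 1).
        """
        cfg = self.config
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        B, C, W = X.shape
        if (C, W) != (cfg.in_channels, cfg.window_len):
            raise ValueError(
                f"window shape {(C, W)} does not match config "
                f"{(cfg.in_channels, cfg.window_len)}"
            )
        cache: dict = {"X": X, "branches": {}}
        pooled = []
        for k in cfg.kernel_sizes:
            pad = k // 2
            xp = np.pad(X, ((0, 0), (0, 0), (pad, pad)))
            view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
            # view: (B, C, W, k); weights: (F, C, k)
            z = np.einsum("bcwk,fck->bfw", view, self.params[f"conv{k}_w"],
                          optimize=True) + self.params[f"conv{k}_b"][None, :, None]
            a = np.maximum(z, 0.0)
            arg = a.argmax(axis=1)  # (B, W): winning filter per position
            m = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
            cache["branches"][k] = {"view": view, "z": z, "arg": arg}
            pooled.append(m)
        concat = np.concatenate(pooled, axis=1)  # (B, 3W)
        h_pre = concat @ self.params["fc1_w"] + self.params["fc1_b"]
        h = np.maximum(h_pre, 0.0)
        logit = (h @ self.params["fc2_w"] + self.params["fc2_b"])[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        eps = np.finfo(np.float64).tiny
        prob = np.clip(prob, eps, 1.0 - eps)
        cache.update(concat=concat, h_pre=h_pre, h=h, prob=prob)
        if return_cache:
            return prob, cache
        return prob

    # --------------------------------------------------------------- backward
    def backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean BCE loss w.r.t. every parameter."""
        cfg = self.config
        B = cache["X"].shape[0]
        W = cfg.window_len
        prob = cache["prob"]
        dlogit = (prob - np.asarray(y, dtype=np.float64)) / B  # (B,)
        grads: dict[str, np.ndarray] = {}
        h = cache["h"]
        grads["fc2_w"] = h.T @ dlogit[:, None]
        grads["fc2_b"] = np.array([dlogit.sum()])
        dh = dlogit[:, None] @ self.params["fc2_w"].T  # (B, H)
        dh_pre = dh * (cache["h_pre"] > 0)
        grads["fc1_w"] = cache["concat"].T @ dh_pre
        grads["fc1_b"] = dh_pre.sum(axis=0)
        dconcat = dh_pre @ self.params["fc1_w"].T  # (B, 3W)
        for i, k in enumerate(cfg.kernel_sizes):
            br = cache["branches"][k]
            dm = dconcat[:, i * W : (i + 1) * W]  # (B, W)
            F = cfg.filters_per_kernel
            da = np.zeros((B, F, W))
            np.put_along_axis(da, br["arg"][:, None, :], dm[:, None, :], axis=1)
            dz = da * (br["z"] > 0)
            grads[f"conv{k}_w"] = np.einsum(
                "bfw,bcwk->fck", dz, br["view"], optimize=True
            )
            grads[f"conv{k}_b"] = dz.sum(axis=(0, 2))
        return grads

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "BindingCNN":
        cfg_dict = dict(state["config"])
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        model = cls(ModelConfig(**cfg_dict))
        model.params = {k: np.asarray(v, dtype=np.float64) for k, v in state["params"].items()}
        return model

    def copy(self) -> "BindingCNN":
        clone = BindingCNN(self.config)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone


def bce_loss(prob: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy."""
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=np.float64)
    return float(-(y * np.log(prob) + (1 - y) * np.log(1 - prob)).mean())


@dataclass
class ModelEnsemble:
    """The 3 lowest-validation-loss snapshots plus training metadata."""

    members: list[BindingCNN]
    config: ModelConfig
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for m in self.members:
            if m.config != self.config:
                raise ValueError("ensemble members must share one config")

    def save(self, path: str) -> None:
        payload = {
            "config": asdict(self.config),
            "members": [m.state_dict()["params"] for m in self.members],
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "ModelEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_dict = dict(payload["config"])
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        config = ModelConfig(**cfg_dict)
        members = []
        for params in payload["members"]:
            members.append(
                BindingCNN.from_state_dict({"config": cfg_dict, "params": params})
            )
        return cls(members, config, payload.get("training_meta", {}))


def predict(windows: np.ndarray, ensemble: ModelEnsemble) -> np.ndarray:
    """Ensemble binding probability: arithmetic mean of member outputs."""
    outputs = np.stack([m.forward(windows) for m in ensemble.members])
    return outputs.mean(axis=0)


UNBOUND_CALL = "unbound"
BOUND_CALL = "bound"
CONSTITUTIVE_CALL = "constitutive"


def threshold_calls(
    probs: np.ndarray, bound_t: float = 0.5, constitutive_t: float = 0.95
) -> list[str]:
    """p > constitutive_t -> constitutive; p > bound_t -> bound; else unbound.

    Inequalities are strict: p exactly at a threshold stays in the lower tier.
    """
    if not (0 < bound_t < constitutive_t < 1):
        raise ValueError("need 0 < bound_t < constitutive_t < 1")
    calls = []
    for p in np.atleast_1d(probs):
        if p > constitutive_t:
            calls.append(CONSTITUTIVE_CALL)
        elif p > bound_t:
            calls.append(BOUND_CALL)
        else:
            calls.append(UNBOUND_CALL)
    return calls
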
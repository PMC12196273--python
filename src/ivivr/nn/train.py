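"""Seeded mean-squared-error training with Adam.

Input stacks are min-max normalised to [0, 1] using statistics of the
*training* set only (a single global min/max, not per-stack, so the
absolute absorbance scale — which carries the dissolution signal —
survives normalisation).  Two runs with identical seeds, inputs and
config produce bit-identical loss histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ivivr.nn.architectures import ArchitectureSpec, build_architecture
from ivivr.nn.net import Network


@dataclass(frozen=True)
class TrainConfig:
    """Training settings; ``iterations`` counts epochs (full passes)."""

    iterations: int
    lr: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    loss: str = "mse"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if self.loss != "mse" or self.optimizer != "adam":
            raise ValueError("only mse loss with adam is implemented")

    def to_dict(self) -> dict:
        return {"iterations": self.iterations, "lr": self.lr,
                "batch_size": self.batch_size, "seed": self.seed,
                "loss": self.loss, "optimizer": self.optimizer}


@dataclass
class RegressionModel:
    """A fitted network plus everything needed to reproduce and apply it."""

    network: Network
    config: TrainConfig
    history: list[float]  # mean training loss per iteration (epoch)
    norm_min: float
    norm_max: float
    scale_constant: float | None = None  # ng/mL per unit target, if scaled
    trained_on: frozenset = frozenset()  # formulation ids seen in training

    @property
    def architecture(self) -> ArchitectureSpec:
        return self.network.spec

    def metadata(self) -> dict:
        return {"architecture": self.architecture.to_dict(),
                "config": self.config.to_dict(),
                "norm": [self.norm_min, self.norm_max],
                "scale_constant": self.scale_constant,
                "trained_on": sorted(self.trained_on)}


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(architecture: str, x: np.ndarray, y: Sequence[float],
          config: TrainConfig, scale_constant: float | None = None,
          trained_on: Sequence[str] = ()) -> RegressionModel:
    """Fit an architecture on stacks ``x`` (N, planes, H, W) and targets
    ``y`` by minimising MSE for ``config.iterations`` epochs."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.ndim != 4 or len(x) != len(y):
        raise ValueError("x must be (N, planes, H, W) matching targets")
    if len(x) < 2:
        raise ValueError("need at least 2 training stacks")
    net = build_architecture(architecture, x.shape[1:], seed=config.seed)
    lo, hi = float(x.min()), float(x.max())
    xn = _normalise(x, lo, hi)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    net.set_rng(np.random.default_rng(np.random.SeedSequence([config.seed, 13])))
    opt = Adam(net.parameters(), lr=config.lr)
    n = len(xn)
    bs = min(config.batch_size, n)
    history: list[float] = []
    for epoch in range(config.iterations):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            xb, yb = xn[idx], y[idx]
            net.zero_grad()
            pred = net.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(architecture={architecture}, lr={config.lr}); "
                    f"last finite epoch losses: {history[-3:]}")
            net.backward(2.0 * err / len(idx))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return RegressionModel(network=net, config=config, history=history,
                           norm_min=lo, norm_max=hi,
                           scale_constant=scale_constant,
                           trained_on=frozenset(trained_on))


def predict(model: RegressionModel, x: np.ndarray) -> np.ndarray:
    """Predict concentrations for stacks; un-scales back to ng/mL when the
    model was trained on scaled targets.  Negative outputs are passed
    through unchanged."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or tuple(x.shape[1:]) != model.architecture.input_layout:
        raise ValueError(
            f"stack layout {x.shape[1:]} does not match the model's "
            f"{model.architecture.input_layout}")
    out = model.network.predict(_normalise(x, model.norm_min, model.norm_max))
    if model.scale_constant is not None:
        out = out * model.scale_constant
    return out.astype(float)


def _normalise(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.zeros_like(x)
    return (x - lo) / span
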
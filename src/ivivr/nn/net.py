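"""Network container: forward/backward, parameter bookkeeping, checkpoints."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from ivivr.nn.layers import Layer, Param, Sequential


class Network:
    """A rooted layer graph with a single scalar regression output."""

    def __init__(self, root: Sequential, spec: "ArchitectureSpec"):
        self.root = root
        self.spec = spec

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.root.forward(np.asarray(x, dtype=np.float32), train=train)
        return out[:, 0]

    def backward(self, g_out: np.ndarray) -> None:
        self.root.backward(np.asarray(g_out, dtype=np.float32)[:, None])

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Deterministic eval-mode forward pass, batched."""
        x = np.asarray(x, dtype=np.float32)
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty(0, dtype=np.float32)

    def parameters(self) -> list[Param]:
        return self.root.parameters()

    def set_rng(self, rng: np.random.Generator) -> None:
        self.root.set_rng(rng)

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpoints: npz weights + JSON architecture description ----------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p.value for i, p in enumerate(self.parameters())})
        path.with_suffix(".json").write_text(json.dumps(self.spec.to_dict(), indent=1))

    def load_weights(self, path: str | Path) -> None:
        data = np.load(Path(path).with_suffix(".npz"))
        params = self.parameters()
        if len(data.files) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]


def plan_hash(plan: dict) -> str:
    """Stable hash of a layer plan; guards against silent drift."""
    return hashlib.sha256(
        json.dumps(plan, sort_keys=True).encode()).hexdigest()[:16]
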
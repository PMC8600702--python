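"""A small directed-acyclic-graph container over :mod:`fus2net.nn.layers`.

Nodes are added in topological order; each names the nodes it consumes, so
multi-branch fusion (concat) and residual shortcuts (add) are expressed
directly. Backpropagation walks the nodes in reverse, summing gradients at
fan-out points.
"""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Dropout, Layer, softmax

INPUT = "input"


class Node:
    def __init__(self, name: str, layer: Layer, inputs: list[str]):
        self.name = name
        self.layer = layer
        self.inputs = inputs


class Network:
    def __init__(self) -> None:
        self.nodes: list[Node] = []
        self._by_name: dict[str, Node] = {}

    def add(self, name: str, layer: Layer, inputs: str | list[str]) -> str:
        if name in self._by_name or name == INPUT:
            raise ValueError(f"duplicate node name {name!r}")
        if isinstance(inputs, str):
            inputs = [inputs]
        for src in inputs:
            if src != INPUT and src not in self._by_name:
                raise ValueError(f"node {name!r} consumes unknown node {src!r}")
        node = Node(name, layer, list(inputs))
        self.nodes.append(node)
        self._by_name[name] = node
        return name

    @property
    def output_name(self) -> str:
        return self.nodes[-1].name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cache: dict[str, np.ndarray] = {INPUT: np.asarray(x, dtype=DTYPE)}
        for node in self.nodes:
            ins = [cache[s] for s in node.inputs]
            cache[node.name] = node.layer.forward(ins, training)
        self._cache_keys = list(cache)
        return cache[self.output_name]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Propagate a gradient at the sink back to the input tensor."""
        grads: dict[str, np.ndarray] = {self.output_name: np.asarray(dout, dtype=DTYPE)}
        for node in reversed(self.nodes):
            if node.name not in grads:
                continue  # dead branch (possible in truncated builds)
            dins = node.layer.backward(grads.pop(node.name))
            for src, d in zip(node.inputs, dins):
                if src in grads:
                    grads[src] = grads[src] + d
                else:
                    grads[src] = d
        return grads.get(INPUT)

    # -------------------------------------------------------------- params

    def parameters(self):
        """Yield (node_name, param_key, value, grad) in a stable order."""
        for node in self.nodes:
            for key, val in node.layer.params.items():
                yield node.name, key, val, node.layer.grads.get(key)

    def trainable_arrays(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for _, _, val, grad in self.parameters():
            if grad is None:
                raise RuntimeError("backward() must run before collecting grads")
            out.append((val, grad))
        return out

    def l2_penalty(self) -> float:
        return sum(node.layer.l2_penalty() for node in self.nodes)

    def param_count(self) -> int:
        return sum(node.layer.param_count() for node in self.nodes)

    def seed_dropout(self, seed: int) -> None:
        for i, node in enumerate(self.nodes):
            if isinstance(node.layer, Dropout):
                node.layer.reseed(seed + i)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    # ------------------------------------------------------------ weights IO

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for node in self.nodes:
            for key, val in node.layer.params.items():
                state[f"{node.name}/{key}"] = val
            for key in ("running_mean", "running_var"):
                if hasattr(node.layer, key):
                    state[f"{node.name}/{key}"] = getattr(node.layer, key)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for node in self.nodes:
            for key in node.layer.params:
                node.layer.params[key][...] = state[f"{node.name}/{key}"]
            for key in ("running_mean", "running_var"):
                if hasattr(node.layer, key):
                    getattr(node.layer, key)[...] = state[f"{node.name}/{key}"]

    def save_weights(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))
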
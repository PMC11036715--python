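"""NumPy building blocks for the graph encoder.

Implements a Graph Isomorphism Network (GIN) with edge features, reverse-mode
gradients written out by hand, and an Adam optimizer.  Message passing follows

    h_i^(t) = MLP_t( h_i^(t-1) + aggregate_j  ReLU( h_j^(t-1) + W_e e_ij ) )

with a two-layer perceptron per GIN layer and fixed epsilon 0.  The encoder is
deterministic given its initialization seed; all arithmetic is float64.

Graphs are pre-packed into :class:`GraphData`: dense scatter matrices turn the
sparse neighbourhood sums into small matrix products, which is the fastest
layout at molecule scale (tens of atoms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import MoleculeGraph

__all__ = ["GraphData", "init_params", "encoder_forward", "encoder_backward",
           "Adam", "embedding_width"]


@dataclass
class GraphData:
    """A molecule graph packed for the encoder."""

    n: int
    X: np.ndarray          # (n, F) atom features
    E: np.ndarray          # (2m, 6) directed-edge bond features
    src: np.ndarray        # (2m,) message source atom per directed edge
    scatter_dst: np.ndarray  # (n, 2m) one-hot: accumulate messages at target
    scatter_src: np.ndarray  # (n, 2m) one-hot: route gradients back to source
    degree: np.ndarray     # (n,) in-degree, min-clamped to 1 for mean aggregation

    @classmethod
    def from_graph(cls, graph: MoleculeGraph) -> "GraphData":
        n = graph.atom_count
        src, dst = graph.edge_index
        m2 = src.size
        Zd = np.zeros((n, m2))
        Zs = np.zeros((n, m2))
        Zd[dst, np.arange(m2)] = 1.0
        Zs[src, np.arange(m2)] = 1.0
        deg = np.maximum(Zd.sum(axis=1), 1.0)
        return cls(n=n, X=graph.atom_features, E=graph.bond_features,
                   src=src, scatter_dst=Zd, scatter_src=Zs, degree=deg)


def embedding_width(embed_dim: int, mp_layers: int, jumping_knowledge: bool) -> int:
    """Output width: (L + 1) * d with Jumping Knowledge (layer 0 included)."""
    return (mp_layers + 1) * embed_dim if jumping_knowledge else embed_dim


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_params(feature_len: int, bond_feature_len: int, embed_dim: int,
                mp_layers: int, seed: int) -> dict[str, np.ndarray]:
    """Glorot-uniform initialization of all encoder weights, seeded."""
    rng = np.random.default_rng(seed)
    d = embed_dim
    params = {
        "W_in": _glorot(rng, feature_len, d),
        "b_in": np.zeros(d),
    }
    for l in range(mp_layers):
        params[f"We_{l}"] = _glorot(rng, bond_feature_len, d)
        params[f"be_{l}"] = np.zeros(d)
        params[f"W1_{l}"] = _glorot(rng, d, d)
        params[f"b1_{l}"] = np.zeros(d)
        params[f"W2_{l}"] = _glorot(rng, d, d)
        params[f"b2_{l}"] = np.zeros(d)
    return params


def encoder_forward(data: GraphData, params: dict, mp_layers: int,
                    jumping_knowledge: bool = True, aggregate: str = "sum"):
    """Forward pass; returns (H, cache) with one embedding row per atom."""
    if aggregate not in ("sum", "mean", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    h = data.X @ params["W_in"] + params["b_in"]
    hs = [h]
    layer_caches = []
    for l in range(mp_layers):
        Et = data.E @ params[f"We_{l}"] + params[f"be_{l}"]
        m_pre = h[data.src] + Et
        msg = np.maximum(m_pre, 0.0)
        if aggregate == "sum":
            agg = data.scatter_dst @ msg
            arg = None
        elif aggregate == "mean":
            agg = (data.scatter_dst @ msg) / data.degree[:, None]
            arg = None
        else:  # max over incident messages, gradient routed to the argmax
            d = msg.shape[1] if msg.size else 0
            agg = np.zeros((data.n, d))
            arg = np.full((data.n, d), -1, dtype=np.int64)
            for i in range(data.n):
                rows = np.flatnonzero(data.scatter_dst[i])
                if rows.size:
                    block = msg[rows]
                    idx = block.argmax(axis=0)
                    agg[i] = block[idx, np.arange(d)]
                    arg[i] = rows[idx]
        z = h + agg
        a1 = z @ params[f"W1_{l}"] + params[f"b1_{l}"]
        r1 = np.maximum(a1, 0.0)
        h_next = r1 @ params[f"W2_{l}"] + params[f"b2_{l}"]
        layer_caches.append({"h": h, "m_pre": m_pre, "msg": msg, "z": z,
                             "a1": a1, "r1": r1, "arg": arg})
        h = h_next
        hs.append(h)
    H = np.concatenate(hs, axis=1) if jumping_knowledge else hs[-1]
    cache = {"hs": hs, "layers": layer_caches, "jk": jumping_knowledge,
             "aggregate": aggregate}
    return H, cache


def encoder_backward(dH: np.ndarray, data: GraphData, params: dict,
                     cache: dict, grads: dict) -> None:
    """Accumulate parameter gradients for one graph into ``grads`` in place."""
    L = len(cache["layers"])
    d = cache["hs"][0].shape[1]
    if cache["jk"]:
        d_blocks = [dH[:, l * d:(l + 1) * d] for l in range(L + 1)]
        dh = d_blocks[-1].copy()
    else:
        d_blocks = None
        dh = dH.copy()
    for l in range(L - 1, -1, -1):
        c = cache["layers"][l]
        # h_next = relu(z @ W1 + b1) @ W2 + b2
        grads[f"W2_{l}"] += c["r1"].T @ dh
        grads[f"b2_{l}"] += dh.sum(axis=0)
        dr1 = dh @ params[f"W2_{l}"].T
        da1 = dr1 * (c["a1"] > 0)
        grads[f"W1_{l}"] += c["z"].T @ da1
        grads[f"b1_{l}"] += da1.sum(axis=0)
        dz = da1 @ params[f"W1_{l}"].T
        # z = h + aggregate(messages)
        dh_prev = dz.copy()
        agg = cache["aggregate"]
        if agg == "sum":
            dmsg = data.scatter_dst.T @ dz
        elif agg == "mean":
            dmsg = data.scatter_dst.T @ (dz / data.degree[:, None])
        else:
            dmsg = np.zeros_like(c["msg"])
            arg = c["arg"]
            for i in range(data.n):
                cols = np.flatnonzero(arg[i] >= 0)
                if cols.size:
                    np.add.at(dmsg, (arg[i, cols], cols), dz[i, cols])
        dm_pre = dmsg * (c["m_pre"] > 0)
        grads[f"We_{l}"] += data.E.T @ dm_pre
        grads[f"be_{l}"] += dm_pre.sum(axis=0)
        dh_prev += data.scatter_src @ dm_pre
        if d_blocks is not None:
            dh_prev += d_blocks[l]
        dh = dh_prev
    grads["W_in"] += data.X.T @ dh
    grads["b_in"] += dh.sum(axis=0)


class Adam:
    """Plain Adam over a dict of parameter arrays (deterministic)."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2)
                                                  + self.eps)
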
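"""Graph Isomorphism Network layers, duality operators, and the trainable model.

The GIN layer aggregates, for each node v, (1+ε)·p_v + Σ_{u∈N(v)} p_u and maps
the result through an MLP.  In matrix form the layer is σ((cI + A) X W) with
c = 1+ε, which is a two-tab convolutional layer in which the adjacency matrix
plays the role of the cyclic shift operator — the duality that justifies
applying CNN-style saliency mapping to the trained network.  Graph-level
readout sums node features per layer and concatenates across layers.

Module contents:
  * pure-numpy reference forms of the layers (node-wise and matrix GIN, the
    GCN baseline, the shift matrix and the CNN duality check), used directly
    and as oracles;
  * ``GINNetwork``: the trainable classifier (batched autodiff forward with
    batch normalization, ReLU, sum-readout/concat, dropout + linear head).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "GinConfig",
    "GraphEmbedding",
    "gin_layer_nodewise",
    "gin_layer_matrix",
    "gcn_layer",
    "shift_matrix",
    "verify_cnn_duality",
    "readout",
    "GINNetwork",
    "forward_classify",
]


# ---------------------------------------------------------------------------
# reference layer forms


def gin_layer_nodewise(node_features, adjacency, epsilon: float = 0.0, mlp=None):
    """Node-wise GIN aggregation: MLP((1+ε)·p_v + Σ_{u∈N(v)} p_u) per node.

    ``mlp`` is any callable on a single feature vector (identity if None).
    Implemented as an explicit loop over nodes — the reference form.
    """
    x = np.asarray(node_features, dtype=np.float64)
    a = np.asarray(adjacency, dtype=np.float64)
    if a.shape[0] != a.shape[1] or a.shape[0] != x.shape[0]:
        raise ValueError("adjacency/node-feature shape mismatch")
    out = []
    for v in range(x.shape[0]):
        agg = (1.0 + epsilon) * x[v].copy()
        for u in np.flatnonzero(a[v]):
            agg = agg + x[u]
        out.append(agg if mlp is None else mlp(agg))
    return np.asarray(out)


def gin_layer_matrix(X, adjacency, c: float, W, activation: str | None = "relu"):
    """Dual matrix form of the GIN layer: σ((c·I + A) X W)."""
    x = np.asarray(X, dtype=np.float64)
    a = np.asarray(adjacency, dtype=np.float64)
    w = np.asarray(W, dtype=np.float64)
    if a.shape[1] != x.shape[0] or x.shape[1] != w.shape[0]:
        raise ValueError("shape mismatch in gin_layer_matrix")
    out = (c * x + a @ x) @ w
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation is not None:
        raise ValueError(f"unknown activation {activation!r}")
    return out


def gcn_layer(X, adjacency, W, activation: str | None = None):
    """GCN baseline layer: σ(D̃^{−1/2} Ã D̃^{−1/2} X W) with Ã = A + I."""
    x = np.asarray(X, dtype=np.float64)
    a = np.asarray(adjacency, dtype=np.float64) + np.eye(X.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    norm = d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    out = norm @ x @ np.asarray(W, dtype=np.float64)
    if activation == "relu":
        out = np.maximum(out, 0.0)
    return out


def shift_matrix(n: int) -> np.ndarray:
    """Cyclic shift operator: S[i, j] = 1 iff i = j+1 (mod n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return np.roll(np.eye(n), 1, axis=0)


def verify_cnn_duality(signal, W, c: float, tolerance: float = 1e-8):
    """Check the GIN layer on the cyclic shift graph against direct convolution.

    Left side: the GIN matrix layer with A = shift_matrix(n) (no nonlinearity).
    Right side: multi-channel circular convolution with the two-tab filters
    h_{ij} = [c·w_{ij}, w_{ij}], computed by explicit convolution sums.
    Returns (agrees: bool, max_abs_deviation: float).
    """
    x = np.asarray(signal, dtype=np.float64)
    w = np.asarray(W, dtype=np.float64)
    n, c_in = x.shape
    c_out = w.shape[1]
    s = shift_matrix(n)
    gin_side = gin_layer_matrix(x, s, c, w, activation=None)

    conv_side = np.zeros((n, c_out))
    for i in range(c_out):  # output channel
        for j in range(c_in):  # input channel
            for t in range(n):  # circular two-tab convolution sum
                conv_side[t, i] += c * w[j, i] * x[t, j] + w[j, i] * x[(t - 1) % n, j]
    dev = float(np.max(np.abs(gin_side - conv_side))) if x.size else 0.0
    return dev <= tolerance, dev


# ---------------------------------------------------------------------------
# readout


@dataclass
class GraphEmbedding:
    """Per-layer node features, per-layer graph features, and their concatenation."""

    per_layer_node_features: list
    per_layer_graph_features: list
    graph_feature: np.ndarray


def readout(per_layer_node_features, include_layer0: bool = False) -> GraphEmbedding:
    """Sum-pool node features per layer and concatenate across layers.

    Layer 0 (the raw encoding, identical across subjects in one-hot mode) is
    excluded from the concatenation by default.
    """
    layers = [np.asarray(x, dtype=np.float64) for x in per_layer_node_features]
    if not layers:
        raise ValueError("need at least one layer of node features")
    pooled = [x.sum(axis=0) for x in layers]
    start = 0 if include_layer0 or len(layers) == 1 else 1
    return GraphEmbedding(
        per_layer_node_features=layers,
        per_layer_graph_features=pooled,
        graph_feature=np.concatenate(pooled[start:]),
    )


# ---------------------------------------------------------------------------
# trainable network


@dataclass
class GinConfig:
    """Architecture of the GIN classifier.

    Defaults follow the best-performing configuration on the source task:
    5 layers of 64 hidden units, 2-layer MLPs with batch normalization and
    ReLU, dropout 0.5 at the final linear head, two classes.
    """

    n_layers: int = 5
    hidden_units: int = 64
    dropout_rate: float = 0.5
    epsilon_init: float = 0.0
    mlp_depth: int = 2
    n_classes: int = 2
    include_layer0_readout: bool = False
    readout_mode: str = "sum_concat"  # "mean_last" gives the CAM-compatible variant

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_units < 1 or self.mlp_depth < 1:
            raise ValueError("n_layers, hidden_units and mlp_depth must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.readout_mode not in ("sum_concat", "mean_last"):
            raise ValueError("readout_mode must be 'sum_concat' or 'mean_last'")


class _BatchNorm:
    """Per-channel batch normalization over the (graph, node) axes."""

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            n = x.data.shape[0] * x.data.shape[1]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {
            "gamma": self.gamma.data,
            "beta": self.beta.data,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, st):
        self.gamma.data = np.asarray(st["gamma"], dtype=np.float64)
        self.beta.data = np.asarray(st["beta"], dtype=np.float64)
        self.running_mean = np.asarray(st["running_mean"], dtype=np.float64)
        self.running_var = np.asarray(st["running_var"], dtype=np.float64)


class GINNetwork:
    """Batched GIN graph classifier.

    Forward pass (all graphs in a batch share the node count N):
      X^(k) = ReLU(BN(... linear ...((1+ε_k)·X^(k−1) + A X^(k−1)) ...)),
    sum-readout per layer, concatenation over layers 1..K, dropout, and a
    linear head to class logits.  An optional input projection (linear map
    from the raw feature width to N) supports dimension-matched coordinate
    embeddings.
    """

    def __init__(
        self,
        config: GinConfig,
        in_features: int,
        n_nodes: int,
        seed: int = 0,
        input_projection: bool = False,
    ):
        self.config = config
        self.in_features = in_features
        self.n_nodes = n_nodes
        self.input_projection = input_projection
        rng = np.random.default_rng(seed)

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)

        self.proj_w = None
        self.proj_b = None
        width_in = in_features
        if input_projection:
            self.proj_w = glorot(in_features, n_nodes)
            self.proj_b = Tensor(np.zeros(n_nodes), requires_grad=True)
            width_in = n_nodes

        c = config.hidden_units
        self.epsilons: list[Tensor] = []
        self.mlps: list[list[dict]] = []  # per layer: list of {"w","b","bn"}
        prev = width_in
        for _ in range(config.n_layers):
            self.epsilons.append(Tensor(np.array(config.epsilon_init), requires_grad=True))
            stages = []
            w_in = prev
            for _d in range(config.mlp_depth):
                stages.append(
                    {"w": glorot(w_in, c), "b": Tensor(np.zeros(c), requires_grad=True),
                     "bn": _BatchNorm(c)}
                )
                w_in = c
            self.mlps.append(stages)
            prev = c

        if config.readout_mode == "sum_concat":
            start = 0 if config.include_layer0_readout else 1
            feat_dim = c * config.n_layers
            if config.include_layer0_readout:
                feat_dim += width_in
            self._readout_start = start
        else:  # mean_last: CAM-compatible global-average-pool head
            feat_dim = c
            self._readout_start = config.n_layers
        self.feat_dim = feat_dim
        self.head_w = glorot(feat_dim, config.n_classes)
        self.head_b = Tensor(np.zeros(config.n_classes), requires_grad=True)

    # -- parameter access ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = []
        if self.proj_w is not None:
            params += [self.proj_w, self.proj_b]
        for eps, stages in zip(self.epsilons, self.mlps):
            params.append(eps)
            for st in stages:
                params += [st["w"], st["b"]] + st["bn"].parameters()
        params += [self.head_w, self.head_b]
        return params

    # -- forward -------------------------------------------------------------
    def forward(
        self,
        adjacency: np.ndarray,
        node_features,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Run the network on a batch.

        ``adjacency``: (B, N, N); ``node_features``: (B, N, C0) array or Tensor.
        Returns (logits Tensor (B, c), per-layer node-feature Tensors
        [X^(0)..X^(K)], graph_feature Tensor (B, feat_dim)).
        """
        a = np.asarray(adjacency, dtype=np.float64)
        x = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
        if x.ndim != 3 or a.ndim != 3 or a.shape[:2] != x.shape[:2]:
            raise ValueError("expected batched (B,N,N) adjacency and (B,N,C0) features")
        if self.proj_w is not None:
            x = x @ self.proj_w + self.proj_b
        elif x.shape[2] != self.in_features:
            raise ValueError(
                f"feature width {x.shape[2]} != configured width {self.in_features}"
            )
        a_t = Tensor(a)

        layer_feats = [x]
        for eps, stages in zip(self.epsilons, self.mlps):
            h = x * (eps + 1.0) + a_t @ x
            for st in stages:
                h = h @ st["w"] + st["b"]
                h = st["bn"](h, training=training)
                h = h.relu()
            x = h
            layer_feats.append(x)

        if self.config.readout_mode == "sum_concat":
            pooled = [t.sum(axis=1) for t in layer_feats[self._readout_start:]]
            graph_feat = concat(pooled, axis=-1) if len(pooled) > 1 else pooled[0]
        else:
            graph_feat = layer_feats[-1].mean(axis=1)

        h = graph_feat
        if training and self.config.dropout_rate > 0:
            if dropout_rng is None:
                raise ValueError("training forward with dropout needs a random generator")
            keep = 1.0 - self.config.dropout_rate
            mask = (dropout_rng.random(h.shape) < keep) / keep
            h = h * Tensor(mask)
        logits = h @ self.head_w + self.head_b
        return logits, layer_feats, graph_feat

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict:
        arrays = {}
        if self.proj_w is not None:
            arrays["proj_w"] = self.proj_w.data
            arrays["proj_b"] = self.proj_b.data
        for k, (eps, stages) in enumerate(zip(self.epsilons, self.mlps)):
            arrays[f"eps_{k}"] = eps.data
            for d, st in enumerate(stages):
                arrays[f"w_{k}_{d}"] = st["w"].data
                arrays[f"b_{k}_{d}"] = st["b"].data
                for name, val in st["bn"].state().items():
                    arrays[f"bn_{k}_{d}_{name}"] = val
        arrays["head_w"] = self.head_w.data
        arrays["head_b"] = self.head_b.data
        return arrays

    def save(self, path):
        meta = {
            "config": asdict(self.config),
            "in_features": self.in_features,
            "n_nodes": self.n_nodes,
            "input_projection": self.input_projection,
        }
        arrays = {k: np.asarray(v) for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GINNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            net = cls(
                GinConfig(**meta["config"]),
                in_features=meta["in_features"],
                n_nodes=meta["n_nodes"],
                input_projection=meta["input_projection"],
            )
            if net.proj_w is not None:
                net.proj_w.data = data["proj_w"]
                net.proj_b.data = data["proj_b"]
            for k, (eps, stages) in enumerate(zip(net.epsilons, net.mlps)):
                eps.data = data[f"eps_{k}"]
                for d, st in enumerate(stages):
                    st["w"].data = data[f"w_{k}_{d}"]
                    st["b"].data = data[f"b_{k}_{d}"]
                    st["bn"].load_state(
                        {name: data[f"bn_{k}_{d}_{name}"]
                         for name in ("gamma", "beta", "running_mean", "running_var")}
                    )
            net.head_w.data = data["head_w"]
            net.head_b.data = data["head_b"]
        return net


def forward_classify(graph, network: GINNetwork):
    """Evaluation-mode forward pass for one graph.

    Returns (logits as length-c array, GraphEmbedding).
    """
    logits, layer_feats, graph_feat = network.forward(
        graph.adjacency[None], graph.node_features[None], training=False
    )
    per_layer = [t.data[0] for t in layer_feats]
    pooled = [x.sum(axis=0) for x in per_layer]
    return logits.data[0], GraphEmbedding(per_layer, pooled, graph_feat.data[0])
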
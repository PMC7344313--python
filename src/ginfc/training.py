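"""Training of the GIN classifier: losses, optimizer, cross-validation, metrics.

The objective is cross-entropy plus an optional Infomax regularizer: a
bilinear discriminator is trained jointly to tell matched (node embedding,
graph embedding) pairs from pairs whose node embedding was taken from another
graph in the minibatch, which pushes the readout to retain mutual information
with the node features.  Optimization is Adam with a step-decay learning-rate
schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor, log_softmax, softplus
from .gin import GinConfig, GINNetwork

__all__ = [
    "TrainConfig",
    "FoldResult",
    "cross_entropy_loss",
    "infomax_loss",
    "total_loss",
    "BilinearDiscriminator",
    "train_model",
    "predict",
    "cross_validate",
    "compute_metrics",
    "silhouette_evaluation",
]


@dataclass
class TrainConfig:
    """Optimization schedule and cross-validation settings.

    The learning rate decays by ``lr_decay_factor`` after every
    ``lr_decay_every`` epochs.  ``lambda_infomax`` = 0 disables the
    regularizer entirely.
    """

    epochs: int = 150
    learning_rate: float = 0.005
    lr_decay_factor: float = 0.8
    lr_decay_every: int = 5
    lambda_infomax: float = 0.05
    batch_size: int = 32
    n_folds: int = 10
    seed: int = 0
    positive_class: int = 1

    def __post_init__(self):
        if min(self.epochs, self.lr_decay_every, self.batch_size, self.n_folds) < 1:
            raise ValueError("epochs, lr_decay_every, batch_size, n_folds must be >= 1")
        if self.learning_rate <= 0 or not (0 < self.lr_decay_factor <= 1):
            raise ValueError("bad learning-rate schedule")
        if self.lambda_infomax < 0:
            raise ValueError("lambda_infomax must be >= 0")


@dataclass
class FoldResult:
    fold_index: int
    accuracy: float
    precision: float
    recall: float
    test_indices: np.ndarray
    predicted_labels: np.ndarray
    true_labels: np.ndarray
    graph_features: np.ndarray
    network: "GINNetwork" = None
    precision_undefined: bool = False


# ---------------------------------------------------------------------------
# losses


def cross_entropy_loss(logits: Tensor, labels) -> Tensor:
    """Mean cross-entropy of softmax class probabilities against integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a length-B integer vector")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    ls = log_softmax(logits, axis=-1)
    return -(ls * Tensor(onehot)).sum() * (1.0 / n)


class BilinearDiscriminator:
    """D(p_v, p_G) = sigmoid(p_v^T B p_G), with B learnable."""

    def __init__(self, node_width: int, graph_width: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        lim = np.sqrt(6.0 / (node_width + graph_width))
        self.weight = Tensor(
            rng.uniform(-lim, lim, size=(node_width, graph_width)), requires_grad=True
        )

    def parameters(self):
        return [self.weight]

    def scores(self, node_feats: Tensor, graph_feats: Tensor) -> Tensor:
        """Pre-sigmoid scores, shape (B, N)."""
        b, _n, _c = node_feats.shape
        t = node_feats @ self.weight  # (B, N, F)
        return (t * graph_feats.reshape(b, 1, -1)).sum(axis=2)


def infomax_loss(
    node_feats: Tensor,
    graph_feats: Tensor,
    discriminator: BilinearDiscriminator,
    rng: np.random.Generator,
) -> Tensor:
    """Negative Infomax log-likelihood, normalized by the number of terms.

    Positive pairs take each node embedding with its own graph's readout;
    corrupted pairs substitute node embeddings from another graph in the batch
    (a seeded derangement of batch indices).  Minimizing this binary log-loss
    maximizes the discriminator's ability to tell them apart, i.e. the mutual
    information between node and graph embeddings.
    """
    b, n, _ = node_feats.shape
    if b < 2:
        raise ValueError(
            "Infomax corruption needs a batch of >= 2 graphs; "
            "use lambda_infomax=0 or a larger batch"
        )
    shift = int(rng.integers(1, b))  # cyclic shift: a derangement for any b >= 2
    perm = (np.arange(b) + shift) % b
    pos = discriminator.scores(node_feats, graph_feats)
    neg = discriminator.scores(node_feats.take_batch(perm), graph_feats)
    # -log sigmoid(pos) = softplus(-pos); -log(1 - sigmoid(neg)) = softplus(neg)
    n_terms = 2 * b * n
    return (softplus(-pos).sum() + softplus(neg).sum()) * (1.0 / n_terms)


def total_loss(xent: Tensor, infomax: Tensor | None, lam: float) -> Tensor:
    """L = L_xent + λ·L_Infomax."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0 or infomax is None:
        return xent
    return xent + lam * infomax


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# training loop


def _stack(graphs):
    a = np.stack([g.adjacency for g in graphs]).astype(np.float64)
    x = np.stack([g.node_features for g in graphs]).astype(np.float64)
    y = np.asarray([g.label for g in graphs], dtype=np.intp)
    return a, x, y


def train_model(
    graphs,
    gin_config: GinConfig,
    train_config: TrainConfig,
    seed: int | None = None,
):
    """Train a GIN classifier on a list of BrainGraphs.

    Deterministic given the seed.  Returns (network, per-epoch mean loss trace).
    """
    if not graphs:
        raise ValueError("empty training set")
    seed = train_config.seed if seed is None else seed
    a_all, x_all, y_all = _stack(graphs)
    n_graphs, n_nodes, c0 = x_all.shape
    needs_proj = bool(getattr(graphs[0], "needs_input_projection", False))

    net = GINNetwork(gin_config, in_features=c0, n_nodes=n_nodes, seed=seed,
                     input_projection=needs_proj)
    lam = train_config.lambda_infomax
    disc = None
    params = net.parameters()
    if lam > 0:
        disc = BilinearDiscriminator(gin_config.hidden_units, net.feat_dim, seed=seed + 1)
        params = params + disc.parameters()
    opt = Adam(params)
    rng = np.random.default_rng(seed + 2)

    trace = []
    for epoch in range(train_config.epochs):
        lr = train_config.learning_rate * train_config.lr_decay_factor ** (
            epoch // train_config.lr_decay_every
        )
        order = rng.permutation(n_graphs)
        batches = [
            order[i : i + train_config.batch_size]
            for i in range(0, n_graphs, train_config.batch_size)
        ]
        # Infomax corruption needs >= 2 graphs per batch: fold a trailing
        # singleton into the previous batch.
        if lam > 0 and len(batches) > 1 and len(batches[-1]) == 1:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches = batches[:-1]
        epoch_losses = []
        for idx in batches:
            opt.zero_grad()
            logits, layer_feats, graph_feat = net.forward(
                a_all[idx], x_all[idx], training=True, dropout_rng=rng
            )
            loss = cross_entropy_loss(logits, y_all[idx])
            if lam > 0 and len(idx) >= 2:
                loss = total_loss(loss, infomax_loss(layer_feats[-1], graph_feat, disc, rng), lam)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step(lr)
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    return net, trace


def predict(network: GINNetwork, graphs):
    """Evaluation-mode predictions: (predicted labels, logits, graph features)."""
    a, x, _ = _stack(graphs)
    logits, _feats, graph_feat = network.forward(a, x, training=False)
    return np.argmax(logits.data, axis=1), logits.data, graph_feat.data


# ---------------------------------------------------------------------------
# metrics and cross-validation


def compute_metrics(y_true, y_pred, positive_class: int = 1) -> dict:
    """Binary accuracy/precision/recall as percentages w.r.t. the positive class.

    When nothing is predicted positive, precision is reported as 0 with the
    ``precision_undefined`` flag set (and a warning emitted).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((y_pred == positive_class) & (y_true == positive_class)))
    fp = int(np.sum((y_pred == positive_class) & (y_true != positive_class)))
    fn = int(np.sum((y_pred != positive_class) & (y_true == positive_class)))
    acc = 100.0 * float(np.mean(y_pred == y_true))
    undefined = (tp + fp) == 0
    if undefined:
        warnings.warn("no predicted positives: precision undefined, reported as 0")
        prec = 0.0
    else:
        prec = 100.0 * tp / (tp + fp)
    rec = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "precision_undefined": undefined,
    }


def cross_validate(
    graphs,
    gin_config: GinConfig,
    train_config: TrainConfig,
):
    """Stratified k-fold cross-validation.

    Returns (list of FoldResult, summary dict of mean ± sd accuracy,
    precision and recall in percent over folds).
    """
    y = np.asarray([g.label for g in graphs])
    if train_config.n_folds > len(graphs):
        raise ValueError("more folds than subjects")
    skf = StratifiedKFold(
        n_splits=train_config.n_folds, shuffle=True, random_state=train_config.seed
    )
    folds = []
    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"fold {fold_idx} training split is missing a class; use fewer folds"
            )
        net, _ = train_model(
            [graphs[i] for i in train_idx], gin_config, train_config,
            seed=train_config.seed + 1000 * fold_idx,
        )
        preds, _logits, feats = predict(net, [graphs[i] for i in test_idx])
        m = compute_metrics(y[test_idx], preds, train_config.positive_class)
        folds.append(
            FoldResult(
                fold_index=fold_idx,
                accuracy=m["accuracy"],
                precision=m["precision"],
                recall=m["recall"],
                test_indices=np.asarray(test_idx),
                predicted_labels=preds,
                true_labels=y[test_idx],
                graph_features=feats,
                network=net,
                precision_undefined=m["precision_undefined"],
            )
        )
    summary = {}
    for key in ("accuracy", "precision", "recall"):
        vals = np.array([getattr(f, key) for f in folds])
        summary[f"{key}_mean"] = float(vals.mean())
        summary[f"{key}_sd"] = float(vals.std())
    return folds, summary


def silhouette_evaluation(graph_features, labels) -> float:
    """Mean silhouette score of the graph-feature embedding under the labels."""
    labels = np.asarray(labels)
    feats = np.asarray(graph_features, dtype=np.float64)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("silhouette needs at least 2 subjects in each of 2 classes")
    return float(silhouette_score(feats, labels, metric="euclidean"))
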
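"""Grad-CAM saliency mapping for the GIN classifier.

At layer k the channel weights are the node-summed gradients of the target
class logit with respect to the layer's feature matrix,
α_j = Σ_i ∂y/∂X_ij, and the per-node saliency is S = Σ_j α_j x_j.  With
one-hot node features the input layer (k = 0) collapses to column sums of the
input-feature gradient, giving each region's direct contribution to the
decision.  Gradients are not rectified; negative saliency survives until
min–max normalization of the group map.

Group-level analysis: per-subject maps are averaged (per class), min–max
normalized to [0, 1], the top-percentile regions extracted, and robustness
quantified as the percentage of top regions from subject subsets that match
those from the full group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .gin import GINNetwork

__all__ = [
    "SaliencyMap",
    "SalientRegionSet",
    "RobustnessReport",
    "grad_cam_layer",
    "grad_cam_input",
    "cam_baseline",
    "group_saliency",
    "top_percentile_regions",
    "robustness_match_ratio",
    "network_hemisphere_summary",
    "write_saliency_tsv",
]


@dataclass
class SaliencyMap:
    values: np.ndarray  # length N
    layer_index: int
    target_class: int
    subject_id: str = "group"
    normalized: bool = False


@dataclass
class SalientRegionSet:
    region_indices: np.ndarray  # ranked, best first
    values: np.ndarray
    percentile: float
    table: pd.DataFrame = None

    @property
    def indices(self) -> set:
        return set(int(i) for i in self.region_indices)


@dataclass
class RobustnessReport:
    match_ratios: np.ndarray  # per subset, percent
    mean: float
    sd: float
    subset_sizes: list = field(default_factory=list)


def _forward_with_grad(network: GINNetwork, graph, target_class: int):
    """Single-graph eval-mode forward with input gradient tracking."""
    x0 = Tensor(graph.node_features[None], requires_grad=True)
    logits, layer_feats, _ = network.forward(graph.adjacency[None], x0, training=False)
    c = logits.shape[1]
    if not (0 <= target_class < c):
        raise ValueError(f"target_class {target_class} out of range for {c} classes")
    sel = np.zeros((1, c))
    sel[0, target_class] = 1.0
    y = (logits * Tensor(sel)).sum()
    y.backward()
    return logits, layer_feats


def grad_cam_layer(network: GINNetwork, graph, k: int, target_class: int) -> SaliencyMap:
    """Grad-CAM map at layer k: S = Σ_j (Σ_i ∂y/∂X_ij) · x_j."""
    n_layers = network.config.n_layers
    if not (0 <= k <= n_layers):
        raise ValueError(f"layer index {k} out of range 0..{n_layers}")
    _, layer_feats = _forward_with_grad(network, graph, target_class)
    feat = layer_feats[k]
    if feat.grad is None:
        raise RuntimeError("no gradient reached the requested layer")
    grad = feat.grad[0]  # N × C
    alpha = grad.sum(axis=0)  # channel weights
    values = feat.data[0] @ alpha  # per-node map
    return SaliencyMap(values=values, layer_index=k, target_class=target_class,
                       subject_id=graph.subject_id or "subject")


def grad_cam_input(network: GINNetwork, graph, target_class: int) -> SaliencyMap:
    """Input-layer Grad-CAM for one-hot node features: column sums of ∂y/∂X^(0)."""
    n = graph.node_features.shape[0]
    if graph.node_features.shape != (n, n) or not np.array_equal(
        graph.node_features, np.eye(n)
    ):
        raise ValueError(
            "input-layer saliency requires one-hot node features; "
            "use grad_cam_layer for other encodings"
        )
    _, layer_feats = _forward_with_grad(network, graph, target_class)
    grad = layer_feats[0].grad[0]  # N × N input gradient
    values = grad.sum(axis=0)
    return SaliencyMap(values=values, layer_index=0, target_class=target_class,
                       subject_id=graph.subject_id or "subject")


def cam_baseline(network: GINNetwork, graph, target_class: int) -> SaliencyMap:
    """Class-activation map: last-layer node features scored by the head weights.

    Requires the mean-pooling ("mean_last") readout variant, whose single
    linear head makes the per-node logit contribution well-defined.
    """
    if network.config.readout_mode != "mean_last":
        raise ValueError("CAM needs a network trained with readout_mode='mean_last'")
    logits, layer_feats, _ = network.forward(
        graph.adjacency[None], graph.node_features[None], training=False
    )
    c = logits.shape[1]
    if not (0 <= target_class < c):
        raise ValueError(f"target_class {target_class} out of range for {c} classes")
    last = layer_feats[-1].data[0]  # N × C
    w = network.head_w.data[:, target_class]  # C
    return SaliencyMap(values=last @ w, layer_index=network.config.n_layers,
                       target_class=target_class,
                       subject_id=graph.subject_id or "subject")


def group_saliency(maps, class_filter: int | None = None) -> SaliencyMap:
    """Average subject maps (optionally one class only) and min–max normalize.

    A constant mean map (degenerate min = max) normalizes to all zeros with a
    warning.
    """
    selected = [
        m for m in maps if class_filter is None or m.target_class == class_filter
    ]
    if not selected:
        raise ValueError("no saliency maps selected for group aggregation")
    stack = np.stack([np.asarray(m.values, dtype=np.float64) for m in selected])
    mean = stack.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi > lo:
        norm = (mean - lo) / (hi - lo)
    else:
        warnings.warn("constant group saliency map; normalizing to zeros")
        norm = np.zeros_like(mean)
    target = selected[0].target_class if class_filter is None else class_filter
    return SaliencyMap(values=norm, layer_index=selected[0].layer_index,
                       target_class=target, subject_id="group", normalized=True)


def top_percentile_regions(
    group_map: SaliencyMap,
    parc: pd.DataFrame | None = None,
    percentile: float = 5.0,
) -> SalientRegionSet:
    """The floor(percentile/100 · N) highest-saliency regions, ties by index."""
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    values = np.asarray(group_map.values, dtype=np.float64)
    n = values.size
    count = int(np.floor(percentile / 100.0 * n))
    order = np.lexsort((np.arange(n), -values))
    chosen = order[:count]
    table = None
    if parc is not None and count:
        table = parc.iloc[chosen].copy()
        table["saliency"] = values[chosen]
        table["rank"] = np.arange(1, count + 1)
    return SalientRegionSet(
        region_indices=chosen, values=values[chosen], percentile=percentile, table=table
    )


def robustness_match_ratio(full_set: SalientRegionSet, subset_sets) -> RobustnessReport:
    """Percent of the full-group top regions recovered by each subset's top set."""
    full = full_set.indices
    if not full:
        raise ValueError("empty full-group region set")
    ratios = []
    sizes = []
    for s in subset_sets:
        if len(s.region_indices) != len(full_set.region_indices):
            raise ValueError("subset region sets must match the full set's size")
        ratios.append(100.0 * len(s.indices & full) / len(full))
        sizes.append(len(s.region_indices))
    ratios = np.asarray(ratios)
    return RobustnessReport(
        match_ratios=ratios, mean=float(ratios.mean()), sd=float(ratios.std()),
        subset_sizes=sizes,
    )


def network_hemisphere_summary(region_set: SalientRegionSet, parc: pd.DataFrame):
    """Fractions of the selected regions per functional network and hemisphere."""
    idx = region_set.region_indices
    missing = [int(i) for i in idx if i not in parc.index]
    if missing:
        raise ValueError(f"regions missing from parcellation: {missing}")
    sub = parc.loc[idx]
    n = len(sub)
    network_frac = (sub["network"].value_counts() / n).to_dict()
    hemi_frac = (sub["hemisphere"].value_counts() / n).to_dict()
    return {"network": network_frac, "hemisphere": hemi_frac}


def write_saliency_tsv(
    group_map: SaliencyMap,
    region_set: SalientRegionSet,
    parc: pd.DataFrame,
    path,
    raw_values: np.ndarray | None = None,
):
    """Region-by-region saliency table: value, rank, selected flag, metadata."""
    values = np.asarray(group_map.values, dtype=np.float64)
    n = values.size
    order = np.lexsort((np.arange(n), -values))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    selected = np.zeros(n, dtype=int)
    selected[region_set.region_indices] = 1
    df = parc.copy()
    df["raw_value"] = values if raw_values is None else np.asarray(raw_values)
    df["normalized_value"] = values
    df["rank"] = rank
    df["selected"] = selected
    df.to_csv(path, sep="\t")
    return path


def plot_composition(summary: dict, path=None, title: str = ""):
    """Bar chart of network and hemisphere fractions of the salient regions.

    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, key in zip(axes, ("network", "hemisphere")):
        items = sorted(summary[key].items(), key=lambda kv: -kv[1])
        ax.bar([k for k, _ in items], [v for _, v in items])
        ax.set_ylabel("fraction of salient regions")
        ax.set_title(key)
        ax.set_ylim(0, 1)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
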
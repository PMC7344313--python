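"""Model/Results interface to connectome classification.

``ConnectomeGIN`` is built from a cohort of brain graphs (or directly from
ROI time-series via :meth:`ConnectomeGIN.from_timeseries`).  ``fit`` trains a
single network and returns a :class:`GINResults`; ``cross_validate`` runs
stratified k-fold evaluation and returns a :class:`CrossValidationResults`
carrying per-fold metrics, pooled summary statistics, silhouette score of the
learned embedding, and group-level saliency mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import saliency as _sal
from .gin import GinConfig, GINNetwork, forward_classify
from .graphs import BrainGraph, RoiTimeSeries, build_graph, filter_by_fd
from .training import (
    TrainConfig,
    compute_metrics,
    cross_validate,
    predict,
    silhouette_evaluation,
    train_model,
)


class ConnectomeGIN:
    """GIN classifier over a cohort of functional-connectome graphs."""

    def __init__(
        self,
        graphs: list,
        gin_config: GinConfig | None = None,
        train_config: TrainConfig | None = None,
        parcellation: pd.DataFrame | None = None,
    ):
        if not graphs:
            raise ValueError("empty cohort")
        n = graphs[0].n_nodes
        if any(g.n_nodes != n for g in graphs):
            raise ValueError("all graphs must share the node count")
        self.graphs = list(graphs)
        self.labels = np.asarray([g.label for g in graphs])
        self.gin_config = gin_config or GinConfig()
        self.train_config = train_config or TrainConfig()
        self.parcellation = parcellation

    @classmethod
    def from_timeseries(
        cls,
        series: list,
        labels,
        fd_series: list | None = None,
        sparsity_percent: float = 30.0,
        feature_mode: str = "one_hot",
        parcellation: pd.DataFrame | None = None,
        gin_config: GinConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "ConnectomeGIN":
        """Build graphs from per-subject T×N time-series (applying the FD filter).

        ``series`` may contain RoiTimeSeries or raw T×N arrays.
        """
        graphs = []
        for i, (ts, label) in enumerate(zip(series, labels)):
            if fd_series is not None and not filter_by_fd(fd_series[i]):
                continue
            if not isinstance(ts, RoiTimeSeries):
                ts = RoiTimeSeries(
                    values=ts,
                    region_ids=list(range(np.asarray(ts).shape[1])),
                    subject_id=f"sub-{i:04d}",
                )
            graphs.append(
                build_graph(ts, sparsity_percent, label=label,
                            feature_mode=feature_mode, parc=parcellation)
            )
        return cls(graphs, gin_config, train_config, parcellation)

    def fit(self, seed: int | None = None) -> "GINResults":
        net, trace = train_model(self.graphs, self.gin_config, self.train_config, seed=seed)
        return GINResults(self, net, trace)

    def cross_validate(self) -> "CrossValidationResults":
        folds, summary = cross_validate(self.graphs, self.gin_config, self.train_config)
        return CrossValidationResults(self, folds, summary)


@dataclass
class GINResults:
    """A single trained network plus its loss trace."""

    model: ConnectomeGIN
    network: GINNetwork
    loss_trace: list

    def predict(self, graphs=None):
        preds, _logits, _f = predict(self.network, graphs or self.model.graphs)
        return preds

    def classify(self, graph: BrainGraph):
        return forward_classify(graph, self.network)

    def metrics(self, graphs=None) -> dict:
        graphs = graphs or self.model.graphs
        preds = self.predict(graphs)
        true = [g.label for g in graphs]
        return compute_metrics(true, preds, self.model.train_config.positive_class)

    def saliency(self, graph: BrainGraph, target_class: int | None = None):
        target = graph.label if target_class is None else target_class
        return _sal.grad_cam_input(self.network, graph, target)


class CrossValidationResults:
    """Per-fold metrics, pooled summary, embeddings, and saliency mapping."""

    def __init__(self, model: ConnectomeGIN, folds, summary: dict):
        self.model = model
        self.folds = folds
        self._summary = summary

    @property
    def accuracy(self) -> float:
        return self._summary["accuracy_mean"]

    @property
    def summary_stats(self) -> dict:
        return dict(self._summary)

    def test_embeddings(self):
        """Held-out graph features and labels, pooled over folds."""
        feats = np.concatenate([f.graph_features for f in self.folds])
        labels = np.concatenate([f.true_labels for f in self.folds])
        return feats, labels

    def silhouette(self) -> float:
        feats, labels = self.test_embeddings()
        return silhouette_evaluation(feats, labels)

    def subject_saliency_maps(self, target: str = "true"):
        """Input-layer Grad-CAM for every held-out subject, per fold.

        ``target``: "true" uses each subject's true class logit, "predicted"
        the predicted one.  Returns a list of (fold_index, SaliencyMap, label).
        """
        out = []
        for fold in self.folds:
            for j, gi in enumerate(fold.test_indices):
                g = self.model.graphs[gi]
                cls = int(fold.true_labels[j] if target == "true"
                          else fold.predicted_labels[j])
                m = _sal.grad_cam_input(fold.network, g, cls)
                out.append((fold.fold_index, m, g.label))
        return out

    def group_saliency(self, class_filter: int, subject_maps=None):
        maps = subject_maps if subject_maps is not None else self.subject_saliency_maps()
        selected = [m for _fold, m, _lbl in maps if m.target_class == class_filter]
        return _sal.group_saliency(selected)

    def saliency_analysis(self, class_filter: int, percentile: float = 5.0):
        """Group map, top-percentile region set, and fold-wise robustness.

        Robustness compares the top regions from single-fold and half-cohort
        aggregates against the full-group top regions.
        """
        maps = self.subject_saliency_maps()
        selected = [(f, m) for f, m, _lbl in maps if m.target_class == class_filter]
        full_map = _sal.group_saliency([m for _f, m in selected])
        full_set = _sal.top_percentile_regions(full_map, self.model.parcellation, percentile)

        def subset_set(fold_ids):
            ms = [m for f, m in selected if f in fold_ids]
            gm = _sal.group_saliency(ms)
            return _sal.top_percentile_regions(gm, self.model.parcellation, percentile)

        n_folds = self.model.train_config.n_folds
        one_fold = [subset_set({f}) for f in range(n_folds)]
        half = n_folds // 2
        multi = [subset_set(set(range(0, half))), subset_set(set(range(half, n_folds)))]
        return {
            "group_map": full_map,
            "top_regions": full_set,
            "robustness_one_fold": _sal.robustness_match_ratio(full_set, one_fold),
            "robustness_half_cohort": _sal.robustness_match_ratio(full_set, multi),
        }

    def summary(self) -> str:
        s = self._summary
        lines = [
            "Connectome GIN cross-validation",
            "=" * 45,
            f"subjects: {len(self.model.graphs)}   folds: {len(self.folds)}",
            f"layers: {self.model.gin_config.n_layers}   "
            f"hidden units: {self.model.gin_config.hidden_units}   "
            f"lambda_infomax: {self.model.train_config.lambda_infomax}",
            "-" * 45,
            f"accuracy : {s['accuracy_mean']:6.2f} ± {s['accuracy_sd']:.2f} %",
            f"precision: {s['precision_mean']:6.2f} ± {s['precision_sd']:.2f} %",
            f"recall   : {s['recall_mean']:6.2f} ± {s['recall_sd']:.2f} %",
        ]
        for f in self.folds:
            lines.append(
                f"  fold {f.fold_index}: acc {f.accuracy:6.2f}%  "
                f"prec {f.precision:6.2f}%  rec {f.recall:6.2f}%"
            )
        return "\n".join(lines)
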
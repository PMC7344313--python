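"""Brain-graph construction from ROI time-series.

Pipeline: Pearson functional connectivity -> top-M-percentile sparsity
thresholding -> unweighted undirected adjacency, plus node-feature encodings
(one-hot region identity by default) and degree/Laplacian utilities.  Subjects
failing the head-motion rule (any framewise displacement over 0.3 mm) are
excluded before graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FD_THRESHOLD_MM = 0.3

FEATURE_MODES = ("one_hot", "bold_mean", "coordinate", "coordinate_dim_matched")


@dataclass
class RoiTimeSeries:
    """Per-subject T×N matrix of mean BOLD signal per region."""

    values: np.ndarray
    region_ids: list
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time-series must be a T×N matrix")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints for Pearson correlation")
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region_ids length must equal number of columns")


@dataclass
class ConnectivityMatrix:
    r: np.ndarray
    region_ids: list


@dataclass
class BrainGraph:
    """Unweighted undirected graph plus node features and a class label."""

    adjacency: np.ndarray  # N×N binary, symmetric, zero diagonal
    node_features: np.ndarray  # N×C0
    label: int = 0
    sparsity_percent: float = 100.0
    subject_id: str = ""
    feature_mode: str = "one_hot"
    needs_input_projection: bool = False
    region_ids: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def filter_by_fd(fd: np.ndarray, threshold: float = FD_THRESHOLD_MM) -> bool:
    """Keep a subject iff no frame's displacement exceeds ``threshold`` mm."""
    fd = np.asarray(fd, dtype=np.float64)
    if fd.size == 0:
        raise ValueError("empty framewise-displacement vector")
    if np.any(fd < 0):
        raise ValueError("framewise displacement must be non-negative")
    return bool(np.max(fd) <= threshold)


def pearson_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time-series."""
    x = ts.values
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [str(ts.region_ids[i]) for i in zero]
        raise ValueError(f"zero-variance region(s): {', '.join(names)}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, region_ids=list(ts.region_ids))


def _edge_budget(n: int, sparsity_percent: float) -> int:
    """round-half-away-from-zero of sparsity% of the N(N-1)/2 pair count."""
    n_pairs = n * (n - 1) // 2
    x = sparsity_percent / 100.0 * n_pairs
    return int(np.floor(x + 0.5))


def threshold_sparsity(
    c: ConnectivityMatrix, sparsity_percent: float, use_absolute: bool = False
) -> np.ndarray:
    """Keep the top-M-percentile connectivity values as unweighted edges.

    Upper-triangle entries are ranked by signed value descending (or by
    magnitude when ``use_absolute``); ties break by (row, column) index.  The
    number of edges is exactly round(M/100 · N(N−1)/2).
    """
    if not (0.0 <= sparsity_percent <= 100.0):
        raise ValueError("sparsity_percent must lie in [0, 100]")
    r = c.r
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(r[iu, ju]) if use_absolute else r[iu, ju]
    budget = _edge_budget(n, sparsity_percent)
    # np.lexsort is stable: sort by -value, ties resolved by (row, col) order
    order = np.lexsort((ju, iu, -vals))
    keep = order[:budget]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return adj.astype(np.float64)


def one_hot_features(n: int) -> np.ndarray:
    """One-hot region-identity node features: the N×N identity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.eye(n)


def alt_features(
    ts: RoiTimeSeries | None,
    parc: pd.DataFrame | None,
    mode: str,
) -> tuple[np.ndarray, bool]:
    """Alternative node embeddings: mean BOLD activation or centroid coordinates.

    Returns (features, needs_input_projection).  ``coordinate_dim_matched``
    returns the raw N×3 coordinates with the projection flag set: the model
    then learns a linear map from width 3 to the one-hot width N at train time.
    """
    if mode == "bold_mean":
        if ts is None:
            raise ValueError("bold_mean mode needs a time-series")
        return ts.values.mean(axis=0)[:, None], False
    if mode in ("coordinate", "coordinate_dim_matched"):
        if parc is None:
            raise ValueError("coordinate modes need a parcellation table")
        coords = parc[["R", "A", "S"]].to_numpy(dtype=np.float64)
        return coords, mode == "coordinate_dim_matched"
    raise ValueError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")


def degree_and_laplacian(adjacency: np.ndarray):
    """Degree matrix D, combinatorial Laplacian L = D − A, and normalized L_n.

    Rows of isolated nodes in L_n follow the identity-row convention (the
    normalized term is taken as 0 where the degree is 0).
    """
    a = np.asarray(adjacency, dtype=np.float64)
    deg = a.sum(axis=1)
    d = np.diag(deg)
    lap = d - a
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    ln = np.eye(a.shape[0]) - (inv_sqrt[:, None] * a * inv_sqrt[None, :])
    return d, lap, ln


def build_graph(
    ts: RoiTimeSeries,
    sparsity_percent: float,
    label: int = 0,
    feature_mode: str = "one_hot",
    parc: pd.DataFrame | None = None,
    use_absolute: bool = False,
) -> BrainGraph:
    """End-to-end: time-series -> connectivity -> thresholded graph + features."""
    conn = pearson_connectivity(ts)
    adj = threshold_sparsity(conn, sparsity_percent, use_absolute=use_absolute)
    if feature_mode == "one_hot":
        feats, needs_proj = one_hot_features(len(ts.region_ids)), False
    else:
        feats, needs_proj = alt_features(ts, parc, feature_mode)
    return BrainGraph(
        adjacency=adj,
        node_features=feats,
        label=int(label),
        sparsity_percent=sparsity_percent,
        subject_id=ts.subject_id,
        feature_mode=feature_mode,
        needs_input_projection=needs_proj,
        region_ids=list(ts.region_ids),
    )
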
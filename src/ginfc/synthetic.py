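"""Synthetic multi-subject ROI time-series cohorts with a planted group effect.

Two groups of subjects are sampled from multivariate normal BOLD-like signals.
Group 0 uses a compound-symmetric correlation matrix (a single baseline
inter-regional correlation); group 1 additionally raises the pairwise
correlation inside a planted subset of regions.  Pearson functional
connectivity computed downstream then differs between groups exactly on the
planted edges, which is the property every later stage (graph construction,
classification, saliency mapping) is tested against.

A scalar framewise-displacement (FD) series per subject is generated
independently, solely to exercise the motion-exclusion rule (subjects with any
frame over 0.3 mm are discarded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

YEO7_NETWORKS = ("DMN", "SVN", "CCN", "DAN", "LN", "SMN", "VN")

FD_THRESHOLD_MM = 0.3


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-class synthetic cohort.

    ``effect_size`` is the correlation added, in class 1, between every pair of
    regions in ``planted_regions`` on top of ``base_correlation``.  Region
    indices are 0-based.
    """

    n_subjects_per_class: int
    n_regions: int
    n_timepoints: int
    planted_regions: frozenset = frozenset()
    effect_size: float = 0.0
    base_correlation: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0
    fd_spike_prob: float = 0.001

    def __post_init__(self):
        object.__setattr__(self, "planted_regions", frozenset(self.planted_regions))
        if self.n_subjects_per_class < 1 or self.n_regions < 2 or self.n_timepoints < 3:
            raise ValueError("cohort dimensions too small")
        if self.planted_regions and (
            min(self.planted_regions) < 0 or max(self.planted_regions) >= self.n_regions
        ):
            raise ValueError("planted_regions outside 0..n_regions-1")
        if self.effect_size > 0 and len(self.planted_regions) < 2:
            raise ValueError("a planted effect needs at least 2 planted regions")
        if not (0.0 <= self.base_correlation < 1.0):
            raise ValueError("base_correlation must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.fd_spike_prob <= 1.0):
            raise ValueError("fd_spike_prob must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated cohort: one T×N time-series matrix and one FD series per subject."""

    time_series: list  # of np.ndarray, each T×N
    labels: list  # of int in {0, 1}
    fd_series: list  # of np.ndarray, per-frame FD in mm
    spec: CohortSpec
    subject_ids: list = field(default_factory=list)


def _nearest_correlation(sigma: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result rescaled to unit
    diagonal; for matrices that are already positive definite this is the
    identity map up to the rescaling.
    """
    sym = (sigma + sigma.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        sym = (v * w) @ v.T
    d = np.sqrt(np.diag(sym))
    sym = sym / np.outer(d, d)
    np.fill_diagonal(sym, 1.0)
    return sym


def class_covariances(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return the two class correlation matrices (Σ0, Σ1)."""
    n, rho = spec.n_regions, spec.base_correlation
    sigma0 = (1.0 - rho) * np.eye(n) + rho * np.ones((n, n))
    sigma1 = sigma0.copy()
    planted = sorted(spec.planted_regions)
    for a in planted:
        for b in planted:
            if a != b:
                sigma1[a, b] += spec.effect_size
    sigma1 = _nearest_correlation(sigma1)
    w = np.linalg.eigvalsh((sigma1 + sigma1.T) / 2.0)
    if w.min() <= 0:
        raise ValueError(
            "class-1 covariance not positive definite after repair; "
            f"check effect_size={spec.effect_size}, "
            f"base_correlation={spec.base_correlation}, "
            f"planted_regions={planted}"
        )
    return sigma0, sigma1


def generate_fd(n_timepoints: int, spike_prob: float, seed: int) -> np.ndarray:
    """Framewise displacement (mm): low baseline with occasional >0.3 mm spikes."""
    if not (0.0 <= spike_prob <= 1.0):
        raise ValueError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fd = rng.uniform(0.02, 0.25, size=n_timepoints)
    spikes = rng.random(n_timepoints) < spike_prob
    fd[spikes] = rng.uniform(0.31, 1.0, size=int(spikes.sum()))
    return fd


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Sample a balanced two-class cohort of ROI time-series.

    Deterministic for a given spec (including its seed).  Class means are zero;
    ``noise_sd`` sets the marginal signal amplitude and leaves correlations
    untouched.
    """
    sigma0, sigma1 = class_covariances(spec)
    chol = {0: np.linalg.cholesky(sigma0), 1: np.linalg.cholesky(sigma1)}
    rng = np.random.default_rng(spec.seed)
    fd_rng_seed = np.random.default_rng(spec.seed + 1)

    time_series, labels, fd_series, subject_ids = [], [], [], []
    for label in (0, 1):
        for i in range(spec.n_subjects_per_class):
            z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            ts = spec.noise_sd * (z @ chol[label].T)
            time_series.append(ts)
            labels.append(label)
            fd_series.append(
                generate_fd(
                    spec.n_timepoints,
                    spec.fd_spike_prob,
                    seed=int(fd_rng_seed.integers(0, 2**31 - 1)),
                )
            )
            subject_ids.append(f"sub-{label}{i:04d}")
    return SyntheticCohort(time_series, labels, fd_series, spec, subject_ids)


def generate_parcellation(n_regions: int, seed: int) -> pd.DataFrame:
    """A synthetic parcellation table: label, hemisphere, network, centroid.

    First half of the regions is assigned to the left hemisphere, second half
    to the right; the seven canonical functional-network names are cycled so
    all appear whenever n_regions >= 7.  Centroids are drawn uniformly in a
    cortical bounding box (mm), with the R coordinate signed by hemisphere.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    rows = []
    for i in range(n_regions):
        hemi = "L" if i < half else "R"
        network = YEO7_NETWORKS[i % len(YEO7_NETWORKS)]
        r = rng.uniform(5.0, 70.0) * (-1.0 if hemi == "L" else 1.0)
        a = rng.uniform(-100.0, 70.0)
        s = rng.uniform(-50.0, 80.0)
        rows.append(
            {
                "region_id": i,
                "label": f"{hemi}_{network}_{i:03d}",
                "hemisphere": hemi,
                "network": network,
                "R": round(r, 1),
                "A": round(a, 1),
                "S": round(s, 1),
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


# ---------------------------------------------------------------------------
# on-disk layout: per-subject TSV time-series, JSON-lines manifest, TSV parcellation


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write time-series TSVs and a JSON-lines manifest; return manifest path."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.jsonl"
    region_cols = [f"region{j:03d}" for j in range(cohort.spec.n_regions)]
    with open(manifest_path, "w") as fh:
        for sid, ts, label, fd in zip(
            cohort.subject_ids, cohort.time_series, cohort.labels, cohort.fd_series
        ):
            path = ts_dir / f"{sid}.tsv"
            pd.DataFrame(ts, columns=region_cols).to_csv(
                path, sep="\t", index=False, float_format="%.10g"
            )
            rec = {
                "subject_id": sid,
                "label": int(label),
                "path": str(path.relative_to(out_dir)),
                "max_fd_mm": float(np.max(fd)),
            }
            fh.write(json.dumps(rec) + "\n")
    return manifest_path


def read_cohort(manifest_path: str | Path):
    """Yield (subject_id, label, T×N array, max_fd_mm) per manifest record."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        for line in fh:
            rec = json.loads(line)
            ts = pd.read_csv(root / rec["path"], sep="\t").to_numpy(dtype=np.float64)
            yield rec["subject_id"], int(rec["label"]), ts, float(rec["max_fd_mm"])


def write_parcellation(parc: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parc.to_csv(path, sep="\t")
    return path


def read_parcellation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("region_id")
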
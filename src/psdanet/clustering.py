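"""Temporal clustering of gene-specific regulation profiles into meta-genes.

Genes sharing a temporal regulation pattern are grouped by k-means on their
unit-amplitude log2 R(t) traces; each cluster becomes a "meta-gene" whose
averaged activity (normalized to +/-1) and 50% activation/inhibition time
feed the Boolean discretization downstream. Clusters are relabeled by
ascending half-time so labels are stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .data import TimeGrid, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]          # gene -> cluster index, 1-based
    centroids: np.ndarray           # k x n_times mean normalized traces
    signs: list[str]                # per-cluster "activated" | "inhibited"
    seed: int
    degenerate: bool = False


@dataclass
class MetaGeneActivity:
    """Averaged, peak-normalized activity of one cluster."""

    cluster: int
    grid: TimeGrid
    activity: np.ndarray            # in [-1, 1]; peak magnitude 1 if any event
    half_time: float | None         # minutes; None when no event detected

    @property
    def sign(self) -> str:
        peak = self.activity[np.argmax(np.abs(self.activity))]
        return "inhibited" if peak < 0 else "activated"


def normalize_profiles(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each trace to unit peak magnitude.

    Returns (normalized traces, boolean flags marking all-zero traces that
    were passed through unchanged -- genes with no detected event).
    """
    profiles = np.asarray(profiles, dtype=float)
    if not np.all(np.isfinite(profiles)):
        raise ValidationError("regulation traces must be finite")
    peak = np.max(np.abs(profiles), axis=1)
    flat = peak == 0
    scale = np.where(flat, 1.0, peak)
    return profiles / scale[:, None], flat


def _first_crossing(activity: np.ndarray, times: np.ndarray,
                    level: float) -> float | None:
    """First time |activity| reaches ``level`` on the way to its peak.

    Linear interpolation between samples; None when the peak never reaches
    the level.
    """
    a = np.abs(activity)
    peak_idx = int(np.argmax(a))
    if a[peak_idx] < level:
        return None
    if a[0] >= level:
        return float(times[0])
    for k in range(peak_idx):
        if a[k] < level <= a[k + 1]:
            frac = (level - a[k]) / (a[k + 1] - a[k])
            return float(times[k] + frac * (times[k + 1] - times[k]))
    return float(times[peak_idx])


def half_activation_time(activity: np.ndarray, grid: TimeGrid) -> float | None:
    """50% activation/inhibition time of a peak-normalized activity trace."""
    peak = np.max(np.abs(activity))
    if peak == 0:
        return None
    return _first_crossing(activity / peak, grid.times, 0.5)


def kmeans_cluster(traces: dict[str, np.ndarray], grid: TimeGrid, k: int = 6,
                   n_restarts: int = 50, seed: int = 0) -> ClusterAssignment:
    """k-means (Euclidean) on unit-amplitude regulation traces.

    Best of ``n_restarts`` initialisations by within-cluster sum of squares;
    clusters relabeled 1..k by ascending half-time (ties by descending size)
    so the labels are reproducible. Duplicate centroids mark the result
    degenerate.
    """
    genes = list(traces)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(genes) < k:
        raise ValidationError(f"need >= k={k} traces, got {len(genes)}")
    X = np.vstack([traces[g] for g in genes])
    Xn, _ = normalize_profiles(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2 ** 31))
    raw = km.fit_predict(Xn)
    centroids = km.cluster_centers_
    degenerate = False
    for i in range(k):
        if not np.any(raw == i):
            degenerate = True
        for j in range(i + 1, k):
            if np.allclose(centroids[i], centroids[j]):
                degenerate = True
    if degenerate:
        logger.warning("degenerate k-means result: empty or duplicate cluster(s)")
    # order clusters by half-time of their centroid for stable labels
    sizes = np.bincount(raw, minlength=k)
    half = []
    for i in range(k):
        ht = half_activation_time(centroids[i], grid)
        half.append(np.inf if ht is None else ht)
    order = sorted(range(k), key=lambda i: (half[i], -sizes[i]))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = {g: relabel[int(c)] for g, c in zip(genes, raw)}
    centroids = centroids[order]
    signs = []
    for c in centroids:
        peak = c[np.argmax(np.abs(c))]
        signs.append("inhibited" if peak < 0 else "activated")
        if np.any(c > 0) and np.any(c < 0) and min(abs(c.max()), abs(c.min())) > 0.5 * abs(peak):
            logger.warning("mixed-sign centroid labeled by dominant direction")
    return ClusterAssignment(k, labels, centroids, signs, seed, degenerate)


def meta_gene_activity(assignment: ClusterAssignment,
                       traces: dict[str, np.ndarray],
                       grid: TimeGrid) -> list[MetaGeneActivity]:
    """Average member traces per cluster, renormalize to peak +/-1.

    The half-time is the first (interpolated) time the activity magnitude
    crosses 0.5 toward its peak; clusters whose centroid never leaves zero
    get half_time None.
    """
    missing = [g for g in traces if g not in assignment.labels]
    if missing:
        raise ValidationError(f"assignment does not cover genes: {missing[:5]}")
    out = []
    for c in range(1, assignment.k + 1):
        members = [traces[g] for g, lab in assignment.labels.items() if lab == c]
        if not members:
            out.append(MetaGeneActivity(c, grid, np.zeros(len(grid)), None))
            continue
        centroid = np.mean(np.vstack(members), axis=0)
        peak = np.max(np.abs(centroid))
        if peak == 0:
            out.append(MetaGeneActivity(c, grid, centroid, None))
            continue
        activity = centroid / peak
        out.append(MetaGeneActivity(c, grid, activity,
                                    _first_crossing(activity, grid.times, 0.5)))
    return out
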
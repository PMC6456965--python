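"""k-means clustering of the delta matrix with stability resampling.

The landscape analysis clusters genes by their joint GH-SH response
across seven signals (six histone marks + mRNA). Because k-means is a
stochastic algorithm, cluster robustness is quantified by re-running the
clustering N times with different seeds and, for every unordered pair of
assignments and every cluster of the lower-indexed assignment, recording
the maximum percent overlap of that cluster with any cluster of the
other assignment. With N runs and k clusters this yields exactly
N(N-1)/2 pairs and k * N(N-1)/2 overlap records (1035 pairs and 8280
records at N=46, k=8).

`StabilityKMeans` is a scikit-learn style estimator (fit / predict /
labels_) wrapping the standard Lloyd's algorithm with k-means++ seeding;
module functions are thin wrappers returning the domain result types.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .signal_io import DeltaMatrix, ExpressionTable, pooled_mean_expression


def _as_matrix(delta) -> np.ndarray:
    if isinstance(delta, DeltaMatrix):
        return delta.values()
    return check_array(np.asarray(delta, dtype=float))


class StabilityKMeans(ClusterMixin, BaseEstimator):
    """k-means with restarts plus the max-overlap stability procedure.

    Parameters
    ----------
    n_clusters:
        Number of clusters k.
    n_init:
        Number of k-means++ initializations; the best by inertia wins.
    random_state:
        Seed; the same seed reproduces labels bit-for-bit.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster index per sample, 0-based (scikit-learn convention; the
        domain-level `ClusterAssignment` uses 1-based labels).
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    inertia_ : float
        Total within-cluster sum of squares.
    """

    def __init__(self, n_clusters: int = 8, n_init: int = 10, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n = X.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(
                f"n_clusters must be in [1, n_samples]; got {self.n_clusters} for n={n}"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(X)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = _as_matrix(X)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(-1)
        return d.argmin(axis=1)

    def stability(self, X, n_runs: int, base_seed: int = 0) -> "StabilityReport":
        """Run the clustering ``n_runs`` times (seeds base_seed + i) and
        aggregate per-cluster maximum percent overlaps over all pairs."""
        if n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        X = _as_matrix(X)
        seeds = [int(base_seed) + i for i in range(n_runs)]
        labels = [
            StabilityKMeans(self.n_clusters, self.n_init, s).fit(X).labels_
            for s in seeds
        ]
        records = max_overlap_records(labels, self.n_clusters)
        return StabilityReport(
            n_runs=n_runs, k=self.n_clusters, seeds=seeds, overlap_records=records
        )


@dataclass
class ClusterAssignment:
    """Labels per gene (1..k) with the seed and inertia of the winning run."""

    genes: list[str]
    labels: np.ndarray  # 1-based
    k: int
    seed: int | None
    inertia: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.genes):
            raise ValueError("labels and genes length mismatch")
        present = set(np.unique(self.labels))
        if not present <= set(range(1, self.k + 1)):
            raise ValueError(f"labels outside [1..{self.k}]")
        if len(present) != self.k:
            raise ValueError("every cluster label must be used at least once")

    def members(self, cluster: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "cluster": self.labels})


def kmeans_fit(
    delta: DeltaMatrix, k: int, seed: int | None = 0, restarts: int = 10
) -> ClusterAssignment:
    """Lloyd's k-means (k-means++ seeding, best of ``restarts`` inits).

    Deterministic given ``seed``. Empty clusters cannot survive: the
    underlying solver relocates an empty centroid to the point farthest
    from its center, so k is always preserved.
    """
    est = StabilityKMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(delta)
    return ClusterAssignment(
        genes=delta.genes, labels=est.labels_ + 1, k=k, seed=seed,
        inertia=est.inertia_,
    )


def _spherical_bic(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC for a hard-assignment spherical Gaussian mixture with shared
    variance: -2 * max-loglik + (k*d + 1) * ln(n)."""
    n, d = X.shape
    rss = 0.0
    loglik = 0.0
    sizes = np.bincount(labels, minlength=k).astype(float)
    for c in range(k):
        pts = X[labels == c]
        if len(pts):
            rss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    sigma2 = max(rss / (n * d), 1e-12)
    for c in range(k):
        if sizes[c] > 0:
            loglik += sizes[c] * (np.log(sizes[c]) - np.log(n))
    loglik += -0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0)
    return float(-2.0 * loglik + (k * d + 1) * np.log(n))


@dataclass
class KSelection:
    """Chosen k plus the full diagnostics curve for inspection."""

    k: int
    criterion: str
    curve: pd.DataFrame  # columns: k, inertia, bic, second_diff
    low_confidence: bool


def choose_k(
    delta: DeltaMatrix | np.ndarray,
    k_min: int = 1,
    k_max: int = 12,
    criterion: str = "bic",
    seed: int | None = 0,
    restarts: int = 10,
) -> KSelection:
    """Select the cluster count over [k_min, k_max].

    ``bic``: minimize the spherical-Gaussian BIC. ``elbow``: maximize the
    second difference of the inertia curve (interior k only). The full
    curve is always returned; a shallow optimum is flagged low-confidence.
    """
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if criterion not in ("bic", "elbow"):
        raise ValueError("criterion must be 'bic' or 'elbow'")
    X = _as_matrix(delta)
    ks = list(range(k_min, k_max + 1))
    inertia, bic = [], []
    for k in ks:
        est = StabilityKMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        inertia.append(est.inertia_)
        bic.append(_spherical_bic(X, est.labels_, k))
    second = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        second[i] = inertia[i - 1] - 2 * inertia[i] + inertia[i + 1]
    curve = pd.DataFrame({"k": ks, "inertia": inertia, "bic": bic, "second_diff": second})

    if criterion == "bic":
        best_i = int(np.argmin(bic))
        # shallow curve or optimum pinned at the search boundary
        rng_ = max(bic) - min(bic)
        low_conf = best_i in (0, len(ks) - 1) and len(ks) > 1 or rng_ == 0
        if len(ks) > 2 and best_i not in (0, len(ks) - 1):
            neighbors = min(bic[best_i - 1], bic[best_i + 1])
            low_conf = (neighbors - bic[best_i]) < 0.01 * max(rng_, 1e-12)
    else:
        if len(ks) < 3:
            best_i = 0
            low_conf = True
        else:
            interior = second[1:-1]
            best_i = 1 + int(np.nanargmax(interior))
            scale = np.nanmedian(np.abs(interior))
            peak = second[best_i]
            low_conf = not (scale > 0 and peak / scale >= 5.0)
    return KSelection(k=ks[best_i], criterion=criterion, curve=curve,
                      low_confidence=bool(low_conf))


def max_overlap_records(labels: Sequence[np.ndarray], k: int) -> np.ndarray:
    """Per-cluster maximum percent overlaps over all unordered pairs.

    For each pair (i, j) with i < j and each cluster c of assignment i,
    the record is 100 * max_c' |c intersect c'| / |c| over clusters c' of
    assignment j. Sources come from the lower-indexed assignment only, so
    the record count is exactly k * N(N-1)/2.
    """
    labels = [np.asarray(l, dtype=int) for l in labels]
    lab0 = [l - l.min() for l in labels]  # accept 0- or 1-based
    records = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        li, lj = lab0[i], lab0[j]
        cont = np.zeros((k, k), dtype=np.int64)
        np.add.at(cont, (li, lj), 1)
        sizes = cont.sum(axis=1)
        if (sizes == 0).any():
            raise ValueError("assignment with an empty cluster")
        records.extend(100.0 * cont.max(axis=1) / sizes)
    return np.asarray(records, dtype=float)


@dataclass
class StabilityReport:
    """Distribution of per-cluster maximum overlaps across repeated runs."""

    n_runs: int
    k: int
    seeds: list[int]
    overlap_records: np.ndarray

    def __post_init__(self) -> None:
        self.overlap_records = np.asarray(self.overlap_records, dtype=float)
        if len(self.overlap_records) != self.k * self.pair_count:
            raise ValueError(
                f"expected {self.k * self.pair_count} overlap records, "
                f"got {len(self.overlap_records)}"
            )
        if ((self.overlap_records < 0) | (self.overlap_records > 100)).any():
            raise ValueError("overlap records must lie in [0, 100]")

    @property
    def pair_count(self) -> int:
        return self.n_runs * (self.n_runs - 1) // 2

    @property
    def median_overlap(self) -> float:
        return float(np.median(self.overlap_records))

    @property
    def frac_above_99(self) -> float:
        return float(np.mean(self.overlap_records > 99.0))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_runs": self.n_runs,
            "k": self.k,
            "seeds": self.seeds,
            "pair_count": self.pair_count,
            "n_records": int(len(self.overlap_records)),
            "median_overlap": self.median_overlap,
            "frac_above_99": self.frac_above_99,
            "overlap_records": [round(float(x), 6) for x in self.overlap_records],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def cluster_stability(
    delta: DeltaMatrix, k: int, n_runs: int, base_seed: int = 0, restarts: int = 10
) -> StabilityReport:
    """The resampling stability procedure (N assignments, distinct seeds)."""
    est = StabilityKMeans(n_clusters=k, n_init=restarts)
    return est.stability(delta, n_runs=n_runs, base_seed=base_seed)


@dataclass
class ClusterProfile:
    """Per-cluster mean z per signal, ordered by mean mRNA expression.

    ``means`` rows are clusters re-labelled 1..k in increasing order of
    mean mRNA expression; ``counts`` is genes per cluster (sums to the
    total gene count); ``relabel`` maps original label -> ordered label.
    """

    means: pd.DataFrame
    counts: pd.Series
    relabel: dict[int, int]

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != int(self.counts.sum()):  # pragma: no cover
            raise ValueError


def profile_clusters(
    delta: DeltaMatrix,
    assignment: ClusterAssignment,
    expr: ExpressionTable | None = None,
) -> ClusterProfile:
    """Per-cluster signal means with clusters sorted by mRNA expression.

    If an expression table is given, ordering uses mean pooled TPM per
    cluster; otherwise the mRNA z column of the delta matrix is used.
    """
    if assignment.genes != delta.genes:
        raise ValueError("assignment and delta cover different genes")
    z = delta.z
    lab = pd.Series(assignment.labels, index=z.index, name="cluster")
    means = z.groupby(lab).mean()
    counts = lab.value_counts().sort_index()
    if expr is not None:
        level = pooled_mean_expression(expr).reindex(z.index)
        order_stat = level.groupby(lab).mean()
    elif "mRNA" in z.columns:
        order_stat = means["mRNA"]
    else:
        order_stat = means.iloc[:, 0]
    order = list(order_stat.sort_values(kind="mergesort").index)
    relabel = {old: new + 1 for new, old in enumerate(order)}
    means = means.loc[order]
    means.index = pd.Index(range(1, len(order) + 1), name="cluster")
    counts = counts.loc[order]
    counts.index = means.index
    assert int(counts.sum()) == len(assignment.genes)
    return ClusterProfile(means=means, counts=counts, relabel=relabel)
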
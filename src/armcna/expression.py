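"""Expression workflow: normalization, probe filtering, consensus subtyping.

The workflow mirrors classic microarray subtyping practice:

1. **Global normalization** — each array (sample column) is scaled so its
   mean signal equals a target value (default 100), preserving relative
   values within the column.
2. **Probe filtering** — keep probes with maximum normalized signal >= 100,
   mean >= 10 and coefficient of variation (sd/mean, linear scale) >= 0.3;
   informative, expressed, variable probes.
3. **Hierarchical clustering** — Euclidean distance, complete linkage on
   log2(signal + 1) of the filtered matrix (log transform configurable).
4. **Consensus k-means** — for each candidate k, many k-means runs each on a
   random gene subset (and a shuffled sample order); the consensus matrix
   records how often two samples co-cluster; final labels cut an
   average-linkage tree of (1 - consensus) at k.
5. **k selection by NMF** — the candidate k whose consensus matrix has the
   lowest relative Frobenius reconstruction error under rank-k non-negative
   factorization wins (smallest k on ties).  A stable, near-binary block
   consensus factorizes almost exactly at its true rank, while off-rank
   consensus matrices are blurred by unstable co-clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "FilterConfig",
    "ConsensusResult",
    "global_normalize",
    "filter_probes",
    "hierarchical_clusters",
    "consensus_kmeans",
    "select_k_nmf",
    "rank_marker_genes",
]


@dataclass
class FilterConfig:
    """Normalization target and probe-filter thresholds (linear scale)."""

    max_signal: float = 100.0
    mean_signal: float = 10.0
    cv: float = 0.3
    target_mean: float = 100.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if min(self.max_signal, self.mean_signal, self.cv) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.target_mean <= 0:
            raise ValueError("normalization target must be positive")


def global_normalize(matrix: pd.DataFrame,
                     config: FilterConfig | None = None) -> pd.DataFrame:
    """Scale each sample column so its mean equals the target (default 100).

    Idempotent and scale-invariant; an all-zero column has no scale and is
    an error.
    """
    config = config or FilterConfig()
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression signals must be non-negative")
    means = matrix.mean(axis=0)
    if (means <= 0).any():
        bad = means.index[means <= 0][0]
        raise ValueError(f"sample {bad!r} has zero mean signal")
    return matrix / means * config.target_mean


def filter_probes(matrix: pd.DataFrame,
                  config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep probes passing max / mean / CV thresholds, order preserved.

    Operates on the normalized linear-scale matrix.  An empty result is a
    warning, not an error.
    """
    config = config or FilterConfig()
    vals = matrix.to_numpy(float)
    mean = vals.mean(axis=1)
    mx = vals.max(axis=1)
    sd = vals.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = (mx >= config.max_signal) & (mean >= config.mean_signal) & (cv >= config.cv)
    if not keep.any():
        warnings.warn("probe filter removed every probe", stacklevel=2)
    return matrix.loc[keep]


def _sample_features(matrix: pd.DataFrame, log_transform: bool) -> np.ndarray:
    """Samples-as-rows feature array, log2(signal + 1) by default."""
    x = matrix.to_numpy(float).T
    return np.log2(x + 1.0) if log_transform else x


def hierarchical_clusters(matrix: pd.DataFrame, k: int,
                          config: FilterConfig | None = None):
    """Agglomerative clustering of samples: Euclidean, complete linkage.

    Cuts the tree at *k* clusters.  Deterministic given input order; scipy
    breaks distance ties by merge order.  Returns ``(labels, linkage)``.
    """
    config = config or FilterConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.shape[1]:
        raise ValueError("k exceeds the number of samples")
    feats = _sample_features(matrix, config.log_transform)
    z = hierarchy.linkage(pdist(feats, metric="euclidean"), method="complete")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster"), z


@dataclass
class ConsensusResult:
    """Consensus matrices, per-k labels and NMF errors across candidate k."""

    consensus: dict          # k -> samples x samples DataFrame in [0, 1]
    labels: dict             # k -> Series of final labels (1..k)
    nmf_error: dict          # k -> relative Frobenius reconstruction error
    chosen_k: int | None = None


def _random_partition_init(feats: np.ndarray, k: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Centroids from a uniformly random partition of the samples."""
    n = feats.shape[0]
    while True:
        assign = rng.integers(0, k, size=n)
        if len(np.unique(assign)) == k:
            break
    return np.stack([feats[assign == j].mean(axis=0) for j in range(k)])


def consensus_kmeans(matrix: pd.DataFrame, k_range=range(2, 11),
                     n_iter: int = 1000, n_genes: int = 3000,
                     seed: int = 0,
                     config: FilterConfig | None = None) -> ConsensusResult:
    """Subsampled consensus k-means over a range of cluster counts.

    For each k, ``n_iter`` k-means runs are performed, each on ``n_genes``
    probes drawn without replacement and a shuffled sample order
    (random-partition initialization, <= 100 Lloyd iterations).  The
    consensus entry (i, j) is the fraction of runs placing samples i and j
    in the same cluster; final labels cut an average-linkage tree of
    (1 - consensus) at k.  If fewer than ``n_genes`` probes are available,
    every run uses all of them.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    config = config or FilterConfig()
    rng = np.random.default_rng(seed)
    feats_full = _sample_features(matrix, config.log_transform)
    n_samples, n_avail = feats_full.shape
    n_use = min(n_genes, n_avail)
    consensus, labels = {}, {}
    for k in k_range:
        if k > n_samples:
            raise ValueError(f"k={k} exceeds {n_samples} samples")
        counts = np.zeros((n_samples, n_samples))
        for _ in range(n_iter):
            gene_idx = rng.choice(n_avail, size=n_use, replace=False)
            order = rng.permutation(n_samples)
            feats = feats_full[np.ix_(order, gene_idx)]
            init = _random_partition_init(feats, k, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100,
                            random_state=int(rng.integers(2**31)))
                run = km.fit_predict(feats)
            lab = np.empty(n_samples, dtype=int)
            lab[order] = run
            counts += lab[:, None] == lab[None, :]
        cons = counts / n_iter
        np.fill_diagonal(cons, 1.0)
        cons_df = pd.DataFrame(cons, index=matrix.columns, columns=matrix.columns)
        z = hierarchy.linkage(squareform(1.0 - cons, checks=False), method="average")
        labels[k] = pd.Series(hierarchy.fcluster(z, t=k, criterion="maxclust"),
                              index=matrix.columns, name="cluster")
        consensus[k] = cons_df
    return ConsensusResult(consensus=consensus, labels=labels, nmf_error={})


def select_k_nmf(result: ConsensusResult, k_range=None, n_restarts: int = 10,
                 seed: int = 0) -> ConsensusResult:
    """Choose the cluster count whose consensus matrix best factorizes.

    For each candidate k, the consensus matrix is factorized at rank k with
    multiplicative-update NMF over ``n_restarts`` random restarts; the score
    is the lowest relative Frobenius reconstruction error.  The chosen k is
    the argmin (smallest k on ties, to within 1e-9).
    """
    ks = sorted(result.consensus) if k_range is None else list(k_range)
    rng = np.random.default_rng(seed)
    errors = {}
    for k in ks:
        c = result.consensus[k].to_numpy(float)
        norm = np.linalg.norm(c)
        best = np.inf
        for _ in range(n_restarts):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                nmf = NMF(n_components=k, init="random", solver="mu",
                          beta_loss="frobenius", max_iter=1000, tol=1e-6,
                          random_state=int(rng.integers(2**31)))
                w = nmf.fit_transform(c)
            err = np.linalg.norm(c - w @ nmf.components_) / norm
            best = min(best, err)
        errors[k] = float(best)
    chosen = min(ks, key=lambda k: (round(errors[k] / 1e-9), k))
    result.nmf_error = errors
    result.chosen_k = chosen
    return result


def rank_marker_genes(matrix: pd.DataFrame, labels: pd.Series,
                      cluster_a, cluster_b, pseudocount: float = 1.0,
                      ) -> pd.DataFrame:
    """Per-gene mean log2 ratio between two clusters, ranked.

    The ratio is formed from mean linear signals plus a pseudocount, so
    zero-variance or silent genes stay defined.  Rank 1 is the gene most
    upregulated in *cluster_a*.
    """
    in_a = labels[labels == cluster_a].index
    in_b = labels[labels == cluster_b].index
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValueError("both clusters must be non-empty")
    mean_a = matrix[in_a].mean(axis=1)
    mean_b = matrix[in_b].mean(axis=1)
    log2_ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    out = pd.DataFrame({
        "gene": matrix.index,
        "log2_ratio": log2_ratio.to_numpy(),
    }).sort_values("log2_ratio", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
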
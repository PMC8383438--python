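"""Sample-level quality control: ENCODE-style library-complexity metrics,
threshold/replicate filtering, and PCA + Ward-clustering outlier detection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator


@dataclass
class ComplexityMetrics:
    """Library-complexity summary of a read-position multiset.

    nrf  = distinct positions / total reads (non-redundant fraction)
    pbc1 = single-read positions / distinct positions
    pbc2 = single-read positions / two-read positions (inf when no two-read
           positions exist but single-read positions do)
    """

    total_reads: int
    distinct_reads: int
    nrf: float
    pbc1: float
    pbc2: float


def complexity_metrics(positions) -> ComplexityMetrics:
    """NRF/PBC1/PBC2 from a multiset of genomic positions (one per read)."""
    pos = np.asarray(positions)
    if pos.size == 0:
        raise ValueError("no reads: cannot compute complexity metrics")
    _, counts = np.unique(pos, return_counts=True)
    total = int(pos.size)
    distinct = int(counts.size)
    m1 = int(np.sum(counts == 1))
    m2 = int(np.sum(counts == 2))
    if m2 > 0:
        pbc2 = m1 / m2
    else:
        pbc2 = float("inf") if m1 > 0 else 0.0
    return ComplexityMetrics(
        total_reads=total,
        distinct_reads=distinct,
        nrf=distinct / total,
        pbc1=m1 / distinct,
        pbc2=pbc2,
    )


def filter_samples(
    qc: pd.DataFrame, min_normalized_peak_calls: float = 100.0
) -> tuple[list, pd.DataFrame]:
    """Drop low-signal samples and redundant replicates.

    Samples with ``normalized_peak_calls`` (peak calls per million mapped
    reads at FDR q<0.01) below the threshold are removed.  When a
    (donor, cell_fraction) pair has several surviving replicates, only the
    one with the highest normalized_peak_calls (the signal-to-noise proxy) is
    kept; ties keep the lexicographically smallest sample id.

    Returns (kept sample ids, dropped table with a ``reason`` column).
    """
    if qc.empty:
        raise ValueError("QC table is empty")
    qc = qc.copy()
    if "sample_id" in qc.columns:
        qc = qc.set_index("sample_id")
    dropped = []

    low = qc.index[qc["normalized_peak_calls"] < min_normalized_peak_calls]
    for sid in low:
        dropped.append((sid, f"normalized_peak_calls<{min_normalized_peak_calls:g}"))
    qc = qc.drop(index=low)

    if {"donor_id", "cell_fraction"} <= set(qc.columns):
        for (donor, frac), grp in qc.groupby(["donor_id", "cell_fraction"]):
            if len(grp) <= 1:
                continue
            top_val = grp["normalized_peak_calls"].max()
            winners = sorted(grp.index[grp["normalized_peak_calls"] == top_val])
            keep = winners[0]
            for sid in grp.index:
                if sid != keep:
                    dropped.append((sid, "lower-signal replicate"))
    drop_ids = {sid for sid, _ in dropped}
    kept = [sid for sid in qc.index if sid not in drop_ids]
    if not kept:
        warnings.warn("all samples were filtered out", stacklevel=2)
    dropped_df = pd.DataFrame(dropped, columns=["sample_id", "reason"])
    return kept, dropped_df


class WardOutlierDetector(BaseEstimator):
    """Flag stray samples via PCA scores + Ward hierarchical clustering.

    Samples are projected onto the top ``n_pcs`` principal components of the
    (log-scale) matrix, clustered with Ward linkage into ``k`` clusters, and
    every member of a cluster smaller than ``min_cluster_frac`` of the cohort
    (at least one sample) is flagged.

    Parameters
    ----------
    k : number of clusters to cut the dendrogram into.
    n_pcs : PCs retained for the distance computation.
    min_cluster_frac : clusters at or below ``max(1, floor(frac * n))``
        members are treated as outlier clusters.
    """

    def __init__(self, k: int = 2, n_pcs: int = 10, min_cluster_frac: float = 0.05):
        self.k = k
        self.n_pcs = n_pcs
        self.min_cluster_frac = min_cluster_frac

    def fit(self, X, y=None):
        """X: (n_samples, n_features) log-normalized values, or a DataFrame."""
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        centered = arr - arr.mean(axis=0, keepdims=True)
        if not np.any(centered):
            raise ValueError("no variance: constant matrix")
        n_pcs = min(self.n_pcs, arr.shape[0] - 1, arr.shape[1])
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        scores = u[:, :n_pcs] * s[:n_pcs]
        Z = linkage(scores, method="ward")
        labels = fcluster(Z, t=self.k, criterion="maxclust")
        self.labels_ = pd.Series(labels, index=index, name="cluster")
        thresh = max(1, int(np.floor(self.min_cluster_frac * arr.shape[0])))
        sizes = self.labels_.value_counts()
        small = sizes.index[sizes <= thresh]
        self.outliers_ = sorted(self.labels_.index[self.labels_.isin(small)])
        return self

    def fit_predict(self, X, y=None):
        """Return -1 for flagged samples, cluster label otherwise."""
        self.fit(X)
        out = self.labels_.copy()
        out[out.index.isin(self.outliers_)] = -1
        return out


def detect_outlier_samples(log_counts: pd.DataFrame, k: int = 2, n_pcs: int = 10) -> list:
    """Functional wrapper: ``log_counts`` is peaks x samples (column = sample)."""
    det = WardOutlierDetector(k=k, n_pcs=n_pcs)
    det.fit(log_counts.T)
    return det.outliers_
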
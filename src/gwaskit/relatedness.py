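"""Genomic relatedness: kinship (GRM), principal components, and the
hierarchical sample ordering used by kinship heatmaps.

Two GRM estimators are provided.  The default ``standardized`` form
scales each centered dosage column to unit empirical variance before
forming ``W W^T / m`` — the unit-variance-SNP convention used by
spectral LMM implementations, whose diagonal averages about 1 (the
binomial scaling ``sqrt(2 f (1-f))`` agrees in expectation under
Hardy-Weinberg).  The ``centered`` form only subtracts
column means.  Allele frequencies come from the analyzed (imputed)
cohort; zero-variance columns are excluded from both W and m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class KinshipMatrix:
    """n x n symmetric relatedness matrix with its sample order."""

    values: np.ndarray
    sample_ids: list[tuple[str, str]]
    method_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if len(self.sample_ids) != K.shape[0]:
            raise ValueError("sample_ids length must match kinship dimension")
        if np.abs(K - K.T).max(initial=0.0) > 1e-10:
            raise ValueError("kinship must be symmetric to 1e-10")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        ids = ["_".join(s) for s in self.sample_ids]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(Path(path), sep="\t")

    @classmethod
    def from_tsv(cls, path, method_tag: str = "standardized") -> "KinshipMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        ids = [tuple(str(c).split("_", 1)) if "_" in str(c) else (str(c), str(c)) for c in df.columns]
        return cls(df.to_numpy(), ids, method_tag)


@dataclass
class PCAResult:
    """Sample scores on the top principal components of the centered
    dosage matrix, with the fraction of total variance each explains."""

    scores: np.ndarray
    variance_explained: np.ndarray


def compute_kinship(
    g_imputed: np.ndarray, sample_ids=None, method: str = "standardized"
) -> KinshipMatrix:
    """Genomic relationship matrix from a complete (imputed) dosage array.

    ``standardized``: each column is centered and scaled to unit empirical
    variance (the FaST-LMM "Unit" convention; equals the binomial scaling
    sqrt(2 f (1-f)) in expectation under Hardy-Weinberg), then
    K = W W^T / m.  ``centered``: W = g - colmean, K = W W^T / m.  m counts
    only non-zero-variance columns.
    """
    X = np.asarray(g_imputed, dtype=float)
    if np.isnan(X).any():
        raise ValueError("imputed dosages must contain no missing values")
    if method not in ("standardized", "centered"):
        raise ValueError(f"unknown kinship method {method!r}")
    colmean = X.mean(axis=0)
    var = X.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError("all variants have zero variance; kinship undefined")
    X = X[:, keep]
    colmean = colmean[keep]
    m = X.shape[1]
    if method == "standardized":
        W = (X - colmean) / np.sqrt(var[keep])
    else:
        W = X - colmean
    K = (W @ W.T) / m
    K = (K + K.T) / 2.0  # enforce exact symmetry
    if sample_ids is None:
        sample_ids = [(str(i), str(i)) for i in range(X.shape[0])]
    return KinshipMatrix(K, list(sample_ids), method)


def compute_pca(g_imputed: np.ndarray, k: int) -> PCAResult:
    """Top-k PCA of the column-centered dosage matrix.

    Deterministic up to sign; each component's sign is fixed so its
    largest-magnitude sample score direction has a positive largest
    loading.
    """
    X = np.asarray(g_imputed, dtype=float)
    n, m = X.shape
    if not 1 <= k <= min(n - 1, m):
        raise ValueError(f"k must be in [1, min(n-1, m)] = [1, {min(n - 1, m)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    scores = U[:, :k] * s[:k]
    ve = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(scores=scores, variance_explained=ve)


def cluster_order(K: KinshipMatrix) -> np.ndarray:
    """Leaf permutation from average-linkage hierarchical clustering on
    the distance ``d(i, j) = max(K) - K[i, j]`` (tolerates entries > 1)."""
    n = K.n
    if n == 1:
        return np.array([0])
    D = K.values.max() - K.values
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return np.asarray(leaves_list(Z))
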
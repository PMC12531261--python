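"""Bray-Curtis dissimilarity, PCoA/NMDS embeddings, and ANOSIM.

The beta-diversity layer of the pipeline: community-level differences among
disease groups are summarized as pairwise Bray-Curtis dissimilarities on
relative abundances, embedded for visualization by principal-coordinates
analysis (metric) or nonmetric multidimensional scaling, and tested for group
separation with the rank-based ANOSIM permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

from .tables_io import AsvTable, relative_abundance


@dataclass
class DistanceMatrix:
    sample_ids: list
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("negative distances")
        self.data = d

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int


@dataclass
class OrdinationResult:
    sample_ids: list
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray | None = None  # PCoA: all eigenvalues, negatives included
    proportion_explained: np.ndarray | None = None
    stress: float | None = None  # NMDS: Kruskal stress-1
    converged: bool = True


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities on per-sample relative abundances.

    d(a, b) = sum |p_a - p_b| / sum (p_a + p_b); invariant to per-sample count
    scaling because proportions are formed first.
    """
    if isinstance(table, AsvTable):
        props = relative_abundance(table)
        ids = table.sample_ids
        mat = props.to_numpy()
    else:
        mat = np.asarray(table, dtype=float)
        totals = mat.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("zero-total sample")
        mat = mat / totals
        ids = [f"sample_{k}" for k in range(mat.shape[0])]
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(ids, d)


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of the Gower-centered matrix -0.5 * J D^2 J. All
    eigenvalues are reported, negatives included (they flag non-Euclidean
    structure); coordinates use the top k positive eigenvalues, and
    proportion explained is relative to the positive-eigenvalue total.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    dist = d.data
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10 * max(abs(eigvals[0]), 1.0), 0.0)
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} positive eigenvalues")
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_total = eigvals[eigvals > tol].sum()
    return OrdinationResult(
        sample_ids=list(d.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=np.where(eigvals > tol, eigvals / pos_total, 0.0),
    )


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20, seed: int = 0,
         max_iter: int = 300) -> OrdinationResult:
    """Nonmetric MDS: best (lowest Kruskal stress-1) of n_starts seeded runs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(
            n_components=k, metric=False, dissimilarity="precomputed",
            n_init=n_starts, random_state=seed, max_iter=max_iter,
            normalized_stress=True, eps=1e-9,
        )
        coords = model.fit_transform(d.data)
    stress = float(model.stress_)
    return OrdinationResult(
        sample_ids=list(d.sample_ids), coordinates=coords,
        stress=stress, converged=bool(np.isfinite(stress)),
    )


def anosim(d: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities on ranked dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances; R near 0 means no separation, 1 complete
    separation. p uses the add-one rule over seeded label permutations, so it
    can never fall below 1/(n_permutations + 1).
    """
    labels = np.asarray(list(groups))
    n = len(labels)
    if n != len(d.sample_ids):
        raise ValueError("group labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        raise ValueError(f"singleton groups: {uniq[counts < 2].tolist()}")
    ranks = rankdata(d.condensed())
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return AnosimResult(R=float(observed), p=float(p), n_permutations=n_permutations)
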
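"""SparCC: basis (absolute-abundance) correlations from compositional counts.

Sequencing counts are compositional: per-sample totals are arbitrary, so
Pearson correlations on proportions are distorted by the closure. SparCC
works instead from the log-ratio variances

    t_ij = Var_samples[ log(x_i / x_j) ],

which are invariant to per-sample totals. Writing t_ij in terms of the
unobserved basis variances w_i and basis correlations rho_ij,

    t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

and assuming the correlation structure is sparse (sum_j rho_ij sqrt(w_i w_j)
is negligible), the row sums of t become a linear system in w that is solved
directly; rho then follows from the display above. Strongly correlated pairs
violate the sparsity assumption, so the pair with the largest |rho| is
iteratively excluded from the system and the basis variances re-solved.

Significance is assessed by a permutation bootstrap: each taxon's counts are
shuffled independently across samples, destroying all correlation while
preserving marginals, and a two-sided pseudo p-value is computed with the
add-one rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import AsvTable

NOMINAL_DEPTH = 10_000.0


@dataclass
class CorrelationResult:
    asv_ids: list
    rho: np.ndarray  # symmetric, unit diagonal, clipped to [-1, 1]; NaN = flagged
    pvalues: np.ndarray | None
    n_bootstrap: int
    pseudocount: float

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.asv_ids, columns=self.asv_ids)

    def pvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.asv_ids, columns=self.asv_ids)

    def to_long(self) -> pd.DataFrame:
        """Long-format (asv_i, asv_j, rho, p) over the upper triangle."""
        rows = []
        p = len(self.asv_ids)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append((
                    self.asv_ids[i], self.asv_ids[j], self.rho[i, j],
                    self.pvalues[i, j] if self.pvalues is not None else np.nan,
                ))
        return pd.DataFrame(rows, columns=["asv_i", "asv_j", "rho", "p"])


def _smoothed_log(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    # close to proportions, rescale to a fixed nominal depth, then smooth:
    # the estimate is exactly invariant to per-sample total rescaling
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("zero-total sample in count matrix")
    return np.log(counts / totals * NOMINAL_DEPTH + pseudocount)


def log_ratio_variances(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Matrix of log-ratio variances t_ij (zero diagonal).

    Accepts an :class:`AsvTable` or a samples x taxa array. Requires >= 4 taxa
    (the basis-variance system is underdetermined below that) and >= 3 samples.
    """
    if isinstance(counts, AsvTable):
        counts = counts.counts.to_numpy()
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    if p < 4:
        raise ValueError(
            f"SparCC needs >= 4 taxa for identifiability of basis variances, got {p}"
        )
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    logx = _smoothed_log(counts, pseudocount)
    # t_ij = var(L_i) + var(L_j) - 2 cov(L_i, L_j)
    cov = np.cov(logx, rowvar=False, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlations(
    t: np.ndarray, exclusion_threshold: float = 0.1, max_exclusions: int = 10
) -> np.ndarray:
    """Solve for basis variances under the sparsity approximation and return rho.

    Iteratively excludes the most-correlated pair from the linear system while
    max |rho| exceeds ``exclusion_threshold``, up to ``max_exclusions`` rounds;
    excluded pairs still receive a final rho from the converged variances.
    Taxa whose estimated basis variance is non-positive are flagged: their
    correlations are set to NaN rather than fabricated.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    if t.shape != (p, p) or not np.allclose(t, t.T):
        raise ValueError("t must be a symmetric square matrix")
    M = np.ones((p, p)) + np.eye(p) * (p - 2.0)
    t_work = t.copy()
    excluded: set = set()

    def solve():
        w = np.linalg.solve(M, t_work.sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 2.0 * np.sqrt(np.outer(w, w))
            rho = (w[:, None] + w[None, :] - t) / denom
        bad = w <= 0
        rho = np.clip(rho, -1.0, 1.0)
        rho[bad, :] = np.nan
        rho[:, bad] = np.nan
        np.fill_diagonal(rho, 1.0)
        return w, rho

    w, rho = solve()
    for _ in range(max_exclusions):
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        cand[np.isnan(cand)] = 0.0
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold or i == j:
            break
        excluded.add((i, j))
        M[i, j] = M[j, i] = 0.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        t_work[i, j] = t_work[j, i] = 0.0
        w, rho = solve()
    return rho


def bootstrap_pvalues(
    counts,
    observed_rho: np.ndarray,
    n_bootstrap: int = 99,
    seed: int = 0,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> np.ndarray:
    """Two-sided permutation pseudo p-values for every pair, add-one rule.

    Each bootstrap permutes every taxon's counts independently across samples
    and re-runs the full estimator; p = (1 + #{|rho*| >= |rho|}) / (1 + B).
    """
    if n_bootstrap < 19:
        raise ValueError("n_bootstrap must be >= 19")
    if isinstance(counts, AsvTable):
        counts = counts.counts.to_numpy()
    counts = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(seed)
    n, p = counts.shape
    obs = np.abs(observed_rho)
    exceed = np.zeros((p, p))
    for _ in range(n_bootstrap):
        perm = np.empty_like(counts)
        for j in range(p):
            perm[:, j] = counts[rng.permutation(n), j]
        t = log_ratio_variances(perm, pseudocount)
        rho_b = basis_correlations(t, exclusion_threshold, max_exclusions)
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(rho_b) >= obs).astype(float)
    pvals = (1.0 + exceed) / (1.0 + n_bootstrap)
    pvals = np.minimum(pvals, 1.0)
    np.fill_diagonal(pvals, 1.0)
    return pvals


def sparcc(
    table,
    pseudocount: float = 1.0,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    n_bootstrap: int = 99,
    seed: int = 0,
    n_resamples: int = 1,
) -> CorrelationResult:
    """Full SparCC run: correlations plus bootstrap p-values.

    ``n_resamples > 1`` averages the estimate over seeded Dirichlet resamples
    of each sample's composition (the reference algorithm's inner averaging);
    the default is a single deterministic pass.
    """
    if isinstance(table, AsvTable):
        asv_ids = table.asv_ids
        counts = table.counts.to_numpy().astype(float)
    else:
        counts = np.asarray(table, dtype=float)
        asv_ids = [f"taxon_{k}" for k in range(counts.shape[1])]
    rng = np.random.default_rng(seed)
    if n_resamples <= 1:
        t = log_ratio_variances(counts, pseudocount)
        rho = basis_correlations(t, exclusion_threshold, max_exclusions)
    else:
        acc = np.zeros((counts.shape[1], counts.shape[1]))
        for _ in range(n_resamples):
            frac = np.vstack([rng.dirichlet(row + 1.0) for row in counts])
            resampled = frac * counts.sum(axis=1, keepdims=True)
            t = log_ratio_variances(resampled, pseudocount)
            acc += basis_correlations(t, exclusion_threshold, max_exclusions)
        rho = np.clip(acc / n_resamples, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
    pvals = bootstrap_pvalues(
        counts, rho, n_bootstrap=n_bootstrap,
        seed=int(rng.integers(2**31 - 1)), pseudocount=pseudocount,
        exclusion_threshold=exclusion_threshold, max_exclusions=max_exclusions,
    )
    return CorrelationResult(
        asv_ids=asv_ids, rho=rho, pvalues=pvals,
        n_bootstrap=n_bootstrap, pseudocount=pseudocount,
    )
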
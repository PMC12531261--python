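"""Nonparametric differential abundance with BH-FDR and volcano classification.

Per-taxon group comparisons use rank tests on relative abundances: Wilcoxon
rank-sum (Mann-Whitney) for pairwise group contrasts and Kruskal-Wallis for
the three-group screen, with Benjamini-Hochberg control within each
comparison family. Fold changes are log2 ratios of group mean proportions
(with a small eps guard); a taxon is "enriched" in the front group when
log2FC > 1 with p < 0.05, "depleted" when log2FC < -1 with p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_MAX = 0.05
LFC_MIN = 1.0
EPS = 1e-6


def pairwise_wilcoxon(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Two-sided rank-sum p per taxon (columns aligned across the two groups).

    Exact enumeration for small untied samples (both n <= 20), tie-corrected
    normal approximation otherwise — scipy's method='auto' policy. Taxa that
    are all-zero in both groups carry no evidence: p = 1, flagged.
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("group tables must share the same taxa, in order")
    if len(table_a) < 2 or len(table_b) < 2:
        raise ValueError("need >= 2 samples per group")
    out = []
    for taxon in table_a.columns:
        a = table_a[taxon].to_numpy(dtype=float)
        b = table_b[taxon].to_numpy(dtype=float)
        if not a.any() and not b.any():
            out.append((taxon, 1.0, True))
            continue
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (max(len(a), len(b)) <= 20 and no_ties) else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        out.append((taxon, float(p), False))
    return pd.DataFrame(out, columns=["taxon", "p", "all_zero"]).set_index("taxon")


def kruskal_three(tables: list) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis p (chi-square, 2 df) per taxon for 3 groups."""
    if len(tables) != 3:
        raise ValueError("expected exactly three group tables")
    cols = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != cols:
            raise ValueError("group tables must share the same taxa, in order")
        if len(t) < 2:
            raise ValueError("need >= 2 samples per group")
    out = []
    for taxon in cols:
        vals = [t[taxon].to_numpy(dtype=float) for t in tables]
        pooled = np.concatenate(vals)
        if np.all(pooled == pooled[0]):
            out.append((taxon, 0.0, 1.0, True))
            continue
        h, p = stats.kruskal(*vals)
        out.append((taxon, float(h), float(p), False))
    return pd.DataFrame(out, columns=["taxon", "H", "p", "constant"]).set_index("taxon")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_front, mean_rear, eps: float = EPS):
    """log2((mean_front + eps) / (mean_rear + eps)); exactly antisymmetric."""
    mean_front = np.asarray(mean_front, dtype=float)
    mean_rear = np.asarray(mean_rear, dtype=float)
    if (mean_front < 0).any() or (mean_rear < 0).any():
        raise ValueError("means must be nonnegative")
    # difference of logs, not log of ratio: antisymmetry holds exactly in floats
    return np.log2(mean_front + eps) - np.log2(mean_rear + eps)


def compare_groups(
    props: pd.DataFrame,
    groups: pd.Series,
    front: str,
    rear: str,
    eps: float = EPS,
) -> pd.DataFrame:
    """Full pairwise comparison (front vs rear): p, BH q, log2FC, status."""
    a = props.loc[groups[groups == front].index]
    b = props.loc[groups[groups == rear].index]
    res = pairwise_wilcoxon(a, b)
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["log2fc"] = log2_fold_change(a.mean(axis=0), b.mean(axis=0), eps)
    res["comparison"] = f"{front}_vs_{rear}"
    res["status"] = volcano_status(res)
    return res


def volcano_status(res: pd.DataFrame, p_max: float = P_MAX, lfc_min: float = LFC_MIN,
                   use_q: bool = False) -> pd.Series:
    pcol = res["q"] if use_q else res["p"]
    status = pd.Series("ns", index=res.index)
    status[(pcol < p_max) & (res["log2fc"] > lfc_min)] = "enriched"
    status[(pcol < p_max) & (res["log2fc"] < -lfc_min)] = "depleted"
    return status


def volcano_classify(res: pd.DataFrame, p_max: float = P_MAX, lfc_min: float = LFC_MIN,
                     use_q: bool = False) -> dict:
    """Counts of enriched / depleted / ns taxa under the volcano thresholds."""
    status = volcano_status(res, p_max=p_max, lfc_min=lfc_min, use_q=use_q)
    return {
        "enriched": int((status == "enriched").sum()),
        "depleted": int((status == "depleted").sum()),
        "ns": int((status == "ns").sum()),
        "differential": int((status != "ns").sum()),
    }


def monotone_taxa(
    group_means: pd.DataFrame,
    kw_p: pd.Series,
    top_k: int = 10,
    p_max: float = P_MAX,
) -> dict:
    """Taxa with strictly monotone NC -> NM -> M mean abundance and KW p < p_max.

    ``group_means`` has columns NC, NM, M. Each direction is ranked by the
    absolute end-to-end change |mean(M) - mean(NC)| and truncated to ``top_k``.
    """
    for col in ("NC", "NM", "M"):
        if col not in group_means.columns:
            raise ValueError(f"group_means missing column {col}")
    sig = kw_p.reindex(group_means.index) < p_max
    nc, nm, m = (group_means[c] for c in ("NC", "NM", "M"))
    increasing = sig & (nc < nm) & (nm < m)
    decreasing = sig & (nc > nm) & (nm > m)
    magnitude = (m - nc).abs()

    def ranked(mask):
        return magnitude[mask].sort_values(ascending=False, kind="stable").index[:top_k].tolist()

    return {"increasing": ranked(increasing), "decreasing": ranked(decreasing)}
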
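"""Per-group co-occurrence networks from SparCC results.

An edge joins two key ASVs when their basis correlation is both strong
(|rho| >= r_min, default 0.3) and significant (p < alpha, default 0.05).
Isolated key ASVs stay in the node set — the robustness stage removes nodes
one by one over the full key-ASV set, so the node universe must not shrink
with the edge filter.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import CorrelationResult
from .tables_io import AsvTable


def build_network(
    corr: CorrelationResult,
    r_min: float = 0.3,
    alpha: float = 0.05,
    group: str = "",
    site: str = "",
) -> nx.Graph:
    """Threshold a correlation result into a simple undirected signed graph."""
    g = nx.Graph(group=group, site=site, r_min=r_min, alpha=alpha)
    g.add_nodes_from(corr.asv_ids)
    rho, pv = corr.rho, corr.pvalues
    p = len(corr.asv_ids)
    for i in range(p):
        for j in range(i + 1, p):
            r = rho[i, j]
            if np.isnan(r):
                continue
            if abs(r) >= r_min and pv[i, j] < alpha:
                g.add_edge(
                    corr.asv_ids[i], corr.asv_ids[j],
                    weight=float(r), sign=1 if r > 0 else -1,
                )
    return g


def network_summary(net: nx.Graph) -> dict:
    n = net.number_of_nodes()
    e = net.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    signs = [d["sign"] for _, _, d in net.edges(data=True)]
    return {
        "n_nodes": n,
        "n_edges": e,
        "density": density,
        "mean_degree": 2.0 * e / n if n else 0.0,
        "positive_edge_share": float(np.mean([s > 0 for s in signs])) if signs else np.nan,
        "group": net.graph.get("group", ""),
        "site": net.graph.get("site", ""),
    }


def shared_asv_counts(tables: dict) -> pd.DataFrame:
    """Venn regions of ASV presence between the two body sites, per group.

    ``tables`` maps ``(group, site)`` to an :class:`AsvTable`; an ASV counts
    as present in a group/site when it has a nonzero count in at least one
    sample. Returns one row per group with the two set sizes and the
    intersection.
    """
    groups = sorted({g for g, _ in tables})
    rows = []
    for g in groups:
        sets = {}
        for site in ("feces", "saliva"):
            tab = tables.get((g, site))
            if tab is None:
                sets[site] = set()
            else:
                present = (tab.counts > 0).any(axis=0)
                sets[site] = set(present.index[present])
        inter = sets["feces"] & sets["saliva"]
        rows.append({
            "group": g,
            "n_fecal_asvs": len(sets["feces"]),
            "n_salivary_asvs": len(sets["saliva"]),
            "n_shared": len(inter),
            "fecal_only": len(sets["feces"]) - len(inter),
            "salivary_only": len(sets["saliva"]) - len(inter),
        })
    return pd.DataFrame(rows).set_index("group")


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"asv_i": u, "asv_j": v, "rho": d["weight"], "sign": d["sign"]}
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["asv_i", "asv_j", "rho", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
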
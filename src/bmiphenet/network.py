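"""Disease comorbidity network: phi-correlation edges, Louvain communities,
and permutation significance.

Comorbidity strength between two binary diseases is the phi-correlation —
Pearson's correlation for binary indicators:

    phi_ij = (C_ij*N - P_i*P_j) / sqrt(P_i*P_j*(N-P_i)*(N-P_j))

where C_ij is the co-affected count, P_i and P_j the per-disease affected
counts and N the cohort size. Edge significance uses the t statistic
t = phi*sqrt((N-2)/(1-phi^2)) with N-2 df, adjusted for multiple testing
across all pairs; edges are retained at adjusted p < 0.05 and phi >= 0.2
(inclusive). Communities come from Louvain modularity maximization and are
tested against a degree-preserving rewiring null in which each null network
is re-partitioned and the size-nearest null community's modularity
contribution forms the reference distribution.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream, substream_seed
from .datatypes import DiseaseNetwork, PhecodeTable

logger = logging.getLogger(__name__)

__all__ = [
    "rollup_phecodes",
    "phi_correlation",
    "edge_significance",
    "build_network",
    "detect_communities",
    "community_significance",
    "hub_stats",
]


def rollup_phecodes(phecodes: PhecodeTable, selected: list[str]) -> PhecodeTable:
    """Merge selected dotted codes to their 3-digit (integer-part) parents.

    An individual is a case for the parent iff a case for any selected
    child; parent metadata takes the disease group of the first child seen.
    Leading zeros in the integer part are preserved.
    """
    if not selected:
        raise ValueError("selected codes must be nonempty")
    parents: dict[str, list[str]] = {}
    for code in selected:
        if code not in phecodes.status.columns:
            raise KeyError(f"selected code {code!r} not in phecode table")
        head = code.split(".")[0]
        if not head.isdigit():
            raise ValueError(f"unparseable phecode {code!r}")
        parents.setdefault(head, []).append(code)

    status = {}
    meta_rows = []
    meta = phecodes.meta.set_index("code")
    for parent, children in parents.items():
        status[parent] = (phecodes.status[children].sum(axis=1) > 0).astype(np.int8)
        first = children[0]
        meta_rows.append(
            {
                "code": parent,
                "description": f"rollup of {len(children)} code(s)",
                "disease_group": str(meta.loc[first, "disease_group"]) if first in meta.index else "",
            }
        )
    return PhecodeTable(status=pd.DataFrame(status, index=phecodes.status.index),
                        meta=pd.DataFrame(meta_rows))


def phi_correlation(c_ij: int, p_i: int, p_j: int, n: int) -> float:
    """phi = (C_ij*N - P_i*P_j) / sqrt(P_i*P_j*(N-P_i)*(N-P_j))."""
    if p_i <= 0 or p_i >= n or p_j <= 0 or p_j >= n:
        raise ValueError("phi undefined when a disease affects none or all individuals")
    if not (0 <= c_ij <= min(p_i, p_j)):
        raise ValueError("co-affected count outside [0, min(P_i, P_j)]")
    num = c_ij * n - p_i * p_j
    den = np.sqrt(float(p_i) * p_j * (n - p_i) * (n - p_j))
    return float(num / den)


def edge_significance(phi: float, n: int, df: int | None = None) -> tuple[float, float]:
    """t statistic and raw two-sided p for one phi value.

    t = phi*sqrt((n-2)/(1-phi^2)) referenced to a t distribution with n-2
    df (the standard test of a Pearson correlation). |phi| = 1 returns the
    underflow sentinel p = 0.0. Multiplicity adjustment across all tested
    pairs happens in ``build_network``.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(phi) >= 1.0:
        return float(np.sign(phi) * np.inf), 0.0
    dof = (n - 2) if df is None else df
    t = phi * np.sqrt(dof / (1.0 - phi**2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(p)


def build_network(
    rolled: PhecodeTable,
    phi_min: float = 0.2,
    alpha: float = 0.05,
    adjust: str = "bh",
    drop_isolated: bool = True,
) -> DiseaseNetwork:
    """Score all unordered code pairs and keep edges with adjusted p <
    ``alpha`` and phi >= ``phi_min`` (both thresholds as stated, phi
    inclusive). Isolated nodes are dropped from the graph by default.
    """
    codes = rolled.codes
    if len(codes) < 2:
        raise ValueError("need at least 2 codes to build a network")
    S = rolled.status[codes].to_numpy(dtype=np.int64)
    n = S.shape[0]
    counts = S.sum(axis=0)
    C = S.T @ S  # co-occurrence counts

    rows = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            phi = phi_correlation(int(C[i, j]), int(counts[i]), int(counts[j]), n)
            t, p_raw = edge_significance(phi, n)
            rows.append(
                {"code_i": codes[i], "code_j": codes[j], "c_ij": int(C[i, j]),
                 "p_i": int(counts[i]), "p_j": int(counts[j]), "n": n,
                 "phi": phi, "t_stat": t, "p_raw": p_raw}
            )
    pairs = pd.DataFrame(rows)
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    pairs["p_adj"] = multipletests(pairs["p_raw"].to_numpy(), method=method)[1]

    edges = pairs.loc[(pairs["p_adj"] < alpha) & (pairs["phi"] >= phi_min)].reset_index(drop=True)

    g = nx.Graph()
    if not drop_isolated:
        g.add_nodes_from(codes)
    for row in edges.itertuples(index=False):
        g.add_edge(row.code_i, row.code_j, phi=row.phi, p_adj=row.p_adj)

    groups = dict(zip(rolled.meta["code"], rolled.meta["disease_group"]))
    nx.set_node_attributes(g, {v: groups.get(v, "") for v in g.nodes}, "disease_group")
    return DiseaseNetwork(graph=g, edges=edges, all_pairs=pairs, node_groups=groups)


def detect_communities(net: DiseaseNetwork, seed: int = 0, weighted: bool = False) -> dict[str, int]:
    """Louvain modularity maximization on the retained-edge graph.

    Unweighted by default (phi-weighted via ``weighted=True``). Labels are
    integers assigned by descending community size (ties by smallest member
    code) so that re-runs with the same seed are identical. An edgeless
    graph puts every node in its own community.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        labels = {v: i for i, v in enumerate(sorted(g.nodes))}
    else:
        parts = nx.community.louvain_communities(
            g, weight="phi" if weighted else None, seed=substream_seed(seed, "louvain")
        )
        parts = sorted(parts, key=lambda c: (-len(c), min(c)))
        labels = {v: i for i, c in enumerate(parts) for v in c}
    net.communities = labels
    return labels


def _community_quality(g: nx.Graph, members: set) -> float:
    """Modularity contribution of one community: l_c/m - (d_c/2m)^2."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    sub = g.subgraph(members)
    l_c = sub.number_of_edges()
    d_c = sum(d for _, d in g.degree(members))
    return l_c / m - (d_c / (2.0 * m)) ** 2


def community_significance(
    net: DiseaseNetwork,
    labels: dict[str, int] | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Permutation p-value per community against a degree-preserving null.

    Each of ``n_null`` replicates rewires the graph by degree-preserving
    double edge swaps, re-partitions it with Louvain, and contributes the
    modularity quality of the size-nearest null community; the p-value is
    (1 + #{null quality >= observed}) / (1 + n_null). Communities whose
    quality is typical of rewired graphs are not significant.
    """
    if labels is None:
        labels = net.communities
    if not labels:
        raise ValueError("run detect_communities first")
    if n_null < 100:
        logger.warning("community_significance: n_null=%d < 100 gives unstable p-values", n_null)
    g = net.graph
    m = g.number_of_edges()
    comms: dict[int, set] = {}
    for v, lab in labels.items():
        comms.setdefault(lab, set()).add(v)
    observed = {lab: _community_quality(g, members) for lab, members in comms.items()}
    sizes = {lab: len(members) for lab, members in comms.items()}

    rng = substream(seed, "qs_null")
    exceed = {lab: 0 for lab in comms}
    for b in range(n_null):
        gb = g.copy()
        if m >= 2:
            try:
                nx.double_edge_swap(
                    gb, nswap=4 * m, max_tries=200 * m,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            except nx.NetworkXException:
                pass  # too few swappable edges; use the partly rewired graph
        parts = nx.community.louvain_communities(gb, seed=int(rng.integers(0, 2**31 - 1)))
        null_sizes = np.array([len(c) for c in parts])
        null_q = [_community_quality(gb, set(c)) for c in parts]
        for lab in comms:
            k = int(np.argmin(np.abs(null_sizes - sizes[lab])))
            if null_q[k] >= observed[lab]:
                exceed[lab] += 1
    pvals = {lab: (1.0 + exceed[lab]) / (1.0 + n_null) for lab in comms}
    net.community_p = pvals
    return pvals


def hub_stats(net: DiseaseNetwork, labels: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-node degree, community and cross-community reach.

    cross_links counts the distinct other communities among a node's
    neighbors. Sorted by degree descending, ties by code ascending.
    """
    if labels is None:
        labels = net.communities
    g = net.graph
    rows = []
    for v in g.nodes:
        neigh_comms = {labels.get(u) for u in g.neighbors(v)} if labels else set()
        own = labels.get(v) if labels else None
        rows.append(
            {"code": v, "degree": g.degree(v), "community": own,
             "cross_links": len(neigh_comms - {own}),
             "disease_group": net.node_groups.get(v, "")}
        )
    df = pd.DataFrame(rows, columns=["code", "degree", "community", "cross_links", "disease_group"])
    return df.sort_values(["degree", "code"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
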
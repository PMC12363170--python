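"""Co-occurrence graphs, guild/module detection, and per-sample topology.

The network is an undirected simple graph over the taxa that survived the
prevalence and correlation filters, with SparCC correlations as edge
weights.  Modules ("guilds") are found by greedy agglomerative modularity
maximisation with a deterministic lexicographic tie-break, and modules
holding more than 10% of the nodes are labelled M1, M2, ... by descending
size.  Per-sample topology comes from the subgraph induced by the taxa
present in that sample: modularity Q, mean degree, linkage density
(mean degree / node count), and mean max-normalised eigenvector centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables import AbundanceTable, to_relative
from scipy.stats import spearmanr

__all__ = [
    "ModulePartition",
    "SampleNetworkStats",
    "build_network",
    "modularity_score",
    "detect_modules",
    "sample_subnetwork",
    "eigenvector_centrality",
    "sample_network_properties",
    "module_relative_abundance",
    "ko_module_correlates",
    "write_edge_list",
    "write_graphml",
    "write_partition_tsv",
]

MAJOR_MODULE_FRACTION = 0.10


@dataclass
class ModulePartition:
    """Node -> module assignment with major-module labels and its Q."""

    membership: dict  # node -> module index (int)
    major_labels: dict  # module index -> "M1".."Mk"
    modularity: float

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9:
            raise ValueError(f"modularity {self.modularity} outside [-0.5, 1]")

    def label_of(self, node) -> str:
        """Major-module label for a node, or ``"other"``."""
        return self.major_labels.get(self.membership[node], "other")

    def modules(self) -> dict:
        """module index -> sorted list of member nodes."""
        out: dict = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, []).append(node)
        return {m: sorted(nodes) for m, nodes in out.items()}

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"node": node, "module": mod, "label": self.label_of(node)}
            for node, mod in sorted(self.membership.items(), key=lambda kv: str(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["node", "module", "label"])


@dataclass
class SampleNetworkStats:
    """Scalar topology of one sample's induced subnetwork."""

    sample_id: str
    n_nodes: int
    n_edges: int
    modularity: float
    mean_degree: float
    linkage_density: float
    centrality: float
    degenerate: bool = False


def build_network(edges: pd.DataFrame, nodes) -> nx.Graph:
    """Simple undirected graph from an edge list, keeping isolated nodes.

    ``edges`` needs columns feature_a/feature_b plus optional rho and sign.
    Self-loops and duplicate (unordered) pairs are rejected.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_set = set(nodes)
    seen = set()
    for row in edges.itertuples(index=False):
        a, b = row.feature_a, row.feature_b
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        if a not in node_set or b not in node_set:
            raise ValueError(f"edge endpoint not in node set: {(a, b)}")
        key = (a, b) if str(a) <= str(b) else (b, a)
        if key in seen:
            raise ValueError(f"duplicate edge for pair {key}")
        seen.add(key)
        attrs = {}
        if hasattr(row, "rho"):
            attrs["weight"] = float(row.rho)
            attrs["sign"] = 1 if row.rho >= 0 else -1
        g.add_edge(a, b, **attrs)
    return g


def modularity_score(g: nx.Graph, partition: dict) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2], unweighted.

    ``partition`` maps every node to a community id.  An edgeless graph has
    Q defined as 0 (with a warning): there is no null model to compare to.
    """
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    m = g.number_of_edges()
    if m == 0:
        warnings.warn("modularity of an edgeless graph defined as 0", stacklevel=2)
        return 0.0
    intra: dict = {}
    degree_sum: dict = {}
    for node in g.nodes:
        degree_sum[partition[node]] = degree_sum.get(partition[node], 0) + g.degree(node)
    for u, v in g.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    q = 0.0
    for c in degree_sum:
        q += intra.get(c, 0) / m - (degree_sum[c] / (2.0 * m)) ** 2
    return q


def detect_modules(g: nx.Graph, seed: int | None = None) -> ModulePartition:
    """Greedy agglomerative (CNM-style) modularity maximisation.

    Starts from singletons, repeatedly merges the connected community pair
    with maximal modularity gain (ties broken by the lexicographically
    smallest pair of community representatives, so the result is invariant
    to node input order), and returns the best-Q partition seen.  Isolated
    nodes stay singleton modules.  Modules with strictly more than 10% of
    the nodes get labels M1..Mk by descending size (ties by smallest member
    id).  ``seed`` is accepted for interface uniformity; the algorithm is
    deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(g.nodes, key=str)
    m = g.number_of_edges()
    # community state: each community keyed by its smallest member (as str sort)
    comm_of = {node: node for node in nodes}
    members: dict = {node: {node} for node in nodes}
    degree: dict = {node: g.degree(node) for node in nodes}

    def community_rep(c) -> str:
        return min(str(x) for x in members[c])

    if m == 0:
        membership = {node: i for i, node in enumerate(nodes)}
        members_by_idx = {i: {node} for i, node in enumerate(nodes)}
        return ModulePartition(
            membership=membership,
            major_labels=_major_labels(members_by_idx, len(nodes)),
            modularity=0.0,
        )

    # between-community edge counts
    between: dict = {}
    comm_degree: dict = {node: 0 for node in nodes}
    for node in nodes:
        comm_degree[node] = degree[node]
    for u, v in g.edges:
        cu, cv = comm_of[u], comm_of[v]
        if cu == cv:
            continue
        key = (cu, cv) if str(cu) <= str(cv) else (cv, cu)
        between[key] = between.get(key, 0) + 1

    def snapshot_q() -> float:
        part = {node: comm_of[node] for node in nodes}
        return modularity_score(g, part)

    best_q = snapshot_q()
    best_membership = {node: comm_of[node] for node in nodes}
    two_m = 2.0 * m
    while between:
        # pick max-dQ merge; tie-break by lexicographically smallest rep pair
        best = None
        for (ca, cb), e_ab in between.items():
            dq = e_ab / m - 2.0 * (comm_degree[ca] / two_m) * (comm_degree[cb] / two_m)
            key = tuple(sorted((community_rep(ca), community_rep(cb))))
            cand = (-dq, key)
            if best is None or cand < best[0]:
                best = (cand, ca, cb)
        _, ca, cb = best
        # merge cb into ca (keep the one with smaller rep as the surviving key)
        if community_rep(cb) < community_rep(ca):
            ca, cb = cb, ca
        members[ca] |= members[cb]
        for node in members[cb]:
            comm_of[node] = ca
        comm_degree[ca] += comm_degree.pop(cb)
        del members[cb]
        merged_between: dict = {}
        for (cx, cy), e in between.items():
            cx = ca if cx == cb else cx
            cy = ca if cy == cb else cy
            if cx == cy:
                continue
            key = (cx, cy) if str(cx) <= str(cy) else (cy, cx)
            merged_between[key] = merged_between.get(key, 0) + e
        between = merged_between
        q = snapshot_q()
        if q > best_q + 1e-12:
            best_q = q
            best_membership = {node: comm_of[node] for node in nodes}

    # relabel best membership to dense integer ids ordered by (size desc, rep)
    groups: dict = {}
    for node, c in best_membership.items():
        groups.setdefault(c, set()).add(node)
    ordered = sorted(groups.values(), key=lambda s: (-len(s), min(str(x) for x in s)))
    membership = {}
    members_by_idx = {}
    for idx, grp in enumerate(ordered):
        members_by_idx[idx] = grp
        for node in grp:
            membership[node] = idx
    return ModulePartition(
        membership=membership,
        major_labels=_major_labels(members_by_idx, len(nodes)),
        modularity=best_q,
    )


def _major_labels(members_by_key: dict, n_nodes: int) -> dict:
    """Label modules holding strictly more than 10% of nodes as M1..Mk."""
    sized = [
        (key, grp if isinstance(grp, set) else set(grp))
        for key, grp in members_by_key.items()
    ]
    major = [
        (key, grp)
        for key, grp in sized
        if len(grp) > MAJOR_MODULE_FRACTION * n_nodes
    ]
    major.sort(key=lambda kg: (-len(kg[1]), min(str(x) for x in kg[1])))
    return {key: f"M{i}" for i, (key, _) in enumerate(major, start=1)}


def sample_subnetwork(g: nx.Graph, abundances) -> nx.Graph:
    """Subgraph induced by the nodes with strictly positive abundance.

    ``abundances`` is a mapping/Series node -> abundance; nodes missing from
    it count as absent.
    """
    if isinstance(abundances, pd.Series):
        abundances = abundances.to_dict()
    present = [n for n in g.nodes if abundances.get(n, 0.0) > 0]
    return g.subgraph(present).copy()


def eigenvector_centrality(g: nx.Graph, tol: float = 1e-12, max_iter: int = 100_000) -> dict:
    """Max-normalised eigenvector centrality by power iteration.

    Computed on the largest connected component (ties broken by the
    component containing the smallest node id); nodes outside it get 0.
    Iterates x <- (A + I) x, which has the same leading eigenvector as A on
    a connected graph but cannot oscillate on bipartite ones.
    """
    if g.number_of_nodes() == 0:
        return {}
    if g.number_of_edges() == 0:
        return {n: 0.0 for n in g.nodes}
    components = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(str(x) for x in c))
    )
    comp = sorted(components[0], key=str)
    out = {n: 0.0 for n in g.nodes}
    if len(comp) == 1:
        out[comp[0]] = 1.0
        return out
    a = nx.to_numpy_array(g, nodelist=comp, weight=None) + np.eye(len(comp))
    x = np.ones(len(comp))
    for _ in range(max_iter):
        x_new = a @ x
        x_new /= np.linalg.norm(x_new)
        if np.linalg.norm(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    x = np.abs(x)
    x /= x.max()
    for node, value in zip(comp, x):
        out[node] = float(value)
    return out


def _subnetwork_stats(
    sub: nx.Graph, sample_id: str, seed=None, global_partition: ModulePartition | None = None
) -> SampleNetworkStats:
    n = sub.number_of_nodes()
    e = sub.number_of_edges()
    if n < 2 or e == 0:
        return SampleNetworkStats(
            sample_id=sample_id,
            n_nodes=n,
            n_edges=e,
            modularity=0.0,
            mean_degree=0.0,
            linkage_density=0.0,
            centrality=0.0,
            degenerate=True,
        )
    mean_degree = 2.0 * e / n
    if global_partition is None:
        q = detect_modules(sub, seed=seed).modularity
    else:
        q = modularity_score(sub, {node: global_partition.membership[node] for node in sub})
    cent = eigenvector_centrality(sub)
    return SampleNetworkStats(
        sample_id=sample_id,
        n_nodes=n,
        n_edges=e,
        modularity=q,
        mean_degree=mean_degree,
        linkage_density=mean_degree / n,
        centrality=float(np.mean([cent[x] for x in sub.nodes])),
        degenerate=False,
    )


def sample_network_properties(
    g: nx.Graph,
    table: AbundanceTable,
    seed: int | None = None,
    global_partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """Per-sample induced-subnetwork topology, one row per sample.

    Columns: n_nodes, n_edges, modularity, mean_degree, linkage_density
    (mean_degree / n_nodes), centrality (mean max-normalised eigenvector
    centrality), degenerate.  By default modularity re-detects modules on
    each subnetwork; pass ``global_partition`` to instead score the global
    module assignment restricted to the present nodes.  Subnetworks with
    fewer than 2 nodes or no edges report zeros and are flagged degenerate.
    """
    if table.kind != "relative":
        table = to_relative(table)
    rows = []
    for sample in table.sample_ids:
        sub = sample_subnetwork(g, table.data[sample])
        stats = _subnetwork_stats(sub, sample, seed=seed, global_partition=global_partition)
        rows.append(vars(stats))
    return pd.DataFrame(rows).set_index("sample_id")


def module_relative_abundance(
    partition: ModulePartition, table: AbundanceTable
) -> pd.DataFrame:
    """Summed relative abundance of each labelled module per sample.

    Rows are the major labels M1..Mk plus ``"other"`` (pooled unlabelled
    network taxa); columns are samples.  Module sums plus "other" equal the
    total network-taxon abundance in every sample.
    """
    if table.kind != "relative":
        table = to_relative(table)
    missing = [n for n in partition.membership if n not in set(table.feature_ids)]
    if missing:
        raise ValueError(f"partition nodes absent from table: {missing[:5]}")
    labels = sorted(set(partition.major_labels.values()), key=lambda s: int(s[1:]))
    rows = {}
    for label in labels:
        nodes = [n for n in partition.membership if partition.label_of(n) == label]
        rows[label] = table.data.loc[nodes].sum(axis=0)
    other_nodes = [n for n in partition.membership if partition.label_of(n) == "other"]
    rows["other"] = (
        table.data.loc[other_nodes].sum(axis=0)
        if other_nodes
        else pd.Series(0.0, index=table.data.columns)
    )
    return pd.DataFrame(rows).T


def ko_module_correlates(
    ko_table: AbundanceTable,
    module_abundances: pd.DataFrame,
    min_mean_abund: float = 1e-5,
    p_threshold: float = 0.05,
    r_threshold: float = 0.5,
    signed_mode: bool = False,
) -> pd.DataFrame:
    """Bipartite KO-module edges: Spearman |rho| > 0.5 and p < 0.05.

    KOs are first screened on mean relative abundance (> ``min_mean_abund``,
    computed on the column-normalised table); correlations are computed on
    the KO values as given against each labelled module's abundance.
    ``signed_mode`` keeps only positive rho above the threshold.
    """
    shared = [s for s in ko_table.sample_ids if s in set(module_abundances.columns)]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")
    rel = to_relative(ko_table)
    mean_abund = rel.data[shared].mean(axis=1)
    kept_kos = [k for k in ko_table.feature_ids if mean_abund[k] > min_mean_abund]
    rows = []
    for ko in kept_kos:
        x = ko_table.data.loc[ko, shared].to_numpy(float)
        for module in module_abundances.index:
            y = module_abundances.loc[module, shared].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearmanr(x, y)
            strong = rho > r_threshold if signed_mode else abs(rho) > r_threshold
            if strong and p < p_threshold:
                rows.append({"ko": ko, "module": module, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows, columns=["ko", "module", "rho", "p"])


def write_edge_list(g: nx.Graph, path) -> None:
    rows = []
    for u, v, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        rows.append(
            {
                "feature_a": u,
                "feature_b": v,
                "rho": data.get("weight", np.nan),
                "sign": data.get("sign", 1),
            }
        )
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_partition_tsv(partition: ModulePartition, path) -> None:
    partition.as_frame().to_csv(path, sep="\t", index=False)
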
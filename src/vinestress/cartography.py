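"""Co-expression network cartography and switch-gene mining.

The network is a Pearson correlation graph over the water-stress responsive
genes: an edge joins genes i and j iff |r(i,j)| is at or above a threshold,
with the signed r as the edge weight.  Node roles follow the heat
cartography: expression modules (k-means with silhouette-selected k), the
within-module degree z-score Z, a participation-style coefficient P, and the
average Pearson correlation with network neighbors (APCC).  The (Z, P)
plane is split into seven regions; hubs (Z >= 2.5) and non-hubs subdivide by
P.  APCC colors nodes into date hubs (low positive), party hubs (high
positive) and fight-club hubs (negative).  Switch genes are the "kinless"
non-hubs (region R4: links almost entirely outside their own module) with
negative APCC — candidate negative regulators of the transcriptome shift.

Two P variants are provided.  ``guimera`` is the classical participation
coefficient 1 - sum_m (k_im/k_i)^2, bounded by 1 - 1/M for M modules, so it
cannot reach the R4 band (P > 0.8) unless a node touches at least five
modules.  ``clusterphobic`` is 1 - (kappa_i/k_i)^2 with kappa_i the
within-own-module degree: it measures exactly the "links outside the own
group" property that defines switch genes and is the default for role
assignment; the guimera variant remains available per node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import ExpressionMatrix

logger = logging.getLogger("vinestress")

REGION_BOUNDS = {"r2_lo": 0.05, "r3_lo": 0.62, "r4_lo": 0.80}
HUB_REGION_BOUNDS = {"r6_lo": 0.30, "r7_lo": 0.75}
HUB_Z = 2.5


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_correlation_network(
    em: ExpressionMatrix,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
    threshold: float = 0.6,
) -> nx.Graph:
    """Thresholded Pearson co-expression graph.

    Edge iff |pearson(i, j)| >= threshold over the selected samples, weight
    = signed r.  Zero-variance genes are excluded (logged); nodes that end
    up isolated are retained.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    sub = em.subset(genes=genes, samples=samples)
    if sub.n_samples < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    X = sub.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("excluded %d zero-variance gene(s) from the network", int((~keep).sum()))
    ids = [g for g, k in zip(sub.gene_ids, keep) if k]
    R = np.corrcoef(X[keep])
    R = np.atleast_2d(R)
    graph = nx.Graph(threshold=threshold)
    graph.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(R[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        graph.add_edge(ids[i], ids[j], weight=float(R[i, j]))
    return graph


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def detect_modules(
    em: ExpressionMatrix,
    nodes: list[str],
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_restarts: int = 10,
    force_k: int | None = None,
) -> dict[str, int]:
    """k-means module partition of node expression profiles.

    Rows are standardized (zero mean, unit variance) so clusters group by
    profile shape; k is chosen by maximal mean silhouette over ``k_range``
    (``force_k`` overrides, and k = 1 puts everything in one module).
    """
    if len(nodes) < 2 and force_k != 1:
        raise ValueError("need >= 2 nodes to partition")
    X = em.subset(genes=nodes).values.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    if force_k == 1:
        return {g: 0 for g in nodes}
    if force_k is not None:
        km = KMeans(n_clusters=force_k, n_init=n_restarts, random_state=seed).fit(Xs)
        return dict(zip(nodes, (int(l) for l in km.labels_)))
    lo, hi = k_range
    hi = min(hi, len(nodes) - 1)
    best_labels, best_sil = None, -np.inf
    for k in range(max(2, lo), hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(Xs)
        if len(set(km.labels_)) < 2:
            continue
        sil = silhouette_score(Xs, km.labels_)
        if sil > best_sil:
            best_sil, best_labels = sil, km.labels_
    if best_labels is None:
        raise ValueError("no valid partition found in k_range")
    return dict(zip(nodes, (int(l) for l in best_labels)))


# ---------------------------------------------------------------------------
# node statistics
# ---------------------------------------------------------------------------

def within_module_degree_z(graph: nx.Graph, partition: dict[str, int]) -> dict[str, float]:
    """Z_i = (kappa_i - mean_m) / sd_m over the node's module m.

    kappa_i counts the node's links into its own module; a module whose
    members all share the same kappa (sd = 0) gets Z = 0 (logged).
    """
    kappa = {
        node: sum(1 for nb in graph.neighbors(node) if partition[nb] == partition[node])
        for node in graph.nodes
    }
    z: dict[str, float] = {}
    for module in set(partition.values()):
        members = [n for n in graph.nodes if partition[n] == module]
        vals = np.array([kappa[n] for n in members], dtype=float)
        sd = vals.std()
        if sd == 0.0:
            logger.info("module %s: uniform within-module degree, Z = 0", module)
            for n in members:
                z[n] = 0.0
        else:
            mean = vals.mean()
            for n in members:
                z[n] = float((kappa[n] - mean) / sd)
    return z


def participation_coefficient(
    graph: nx.Graph, partition: dict[str, int], variant: str = "guimera"
) -> dict[str, float]:
    """Module-spread of a node's links.

    ``guimera``: P_i = 1 - sum_m (k_im / k_i)^2 over all modules m;
    ``clusterphobic``: P_i = 1 - (kappa_i / k_i)^2 with kappa_i the
    within-own-module degree.  Isolated nodes get P = 0.
    """
    if variant not in ("guimera", "clusterphobic"):
        raise ValueError(f"unknown participation variant {variant!r}")
    out: dict[str, float] = {}
    for node in graph.nodes:
        k = graph.degree(node)
        if k == 0:
            out[node] = 0.0
            continue
        if variant == "guimera":
            per_module: dict[int, int] = {}
            for nb in graph.neighbors(node):
                per_module[partition[nb]] = per_module.get(partition[nb], 0) + 1
            out[node] = float(1.0 - sum((km / k) ** 2 for km in per_module.values()))
        else:
            kappa = sum(1 for nb in graph.neighbors(node) if partition[nb] == partition[node])
            out[node] = float(1.0 - (kappa / k) ** 2)
    return out


def apcc(graph: nx.Graph, em: ExpressionMatrix) -> dict[str, float]:
    """Average Pearson correlation of each node with its network neighbors.

    Edge weights already carry the signed correlations, so APCC_i is the
    mean incident edge weight; isolated nodes are undefined (NaN, logged).
    """
    out: dict[str, float] = {}
    n_isolated = 0
    for node in graph.nodes:
        weights = [graph[node][nb]["weight"] for nb in graph.neighbors(node)]
        if not weights:
            out[node] = float("nan")
            n_isolated += 1
        else:
            out[node] = float(np.mean(weights))
    if n_isolated:
        logger.info("%d isolated node(s): APCC undefined", n_isolated)
    return out


# ---------------------------------------------------------------------------
# regions and roles
# ---------------------------------------------------------------------------

def assign_region(
    z: float,
    p: float,
    hub_z: float = HUB_Z,
    bounds: dict[str, float] = REGION_BOUNDS,
    hub_bounds: dict[str, float] = HUB_REGION_BOUNDS,
) -> str:
    """Seven-region lookup on the (Z, P) plane.

    Non-hubs (Z < hub_z): R1 P <= 0.05, R2 <= 0.62, R3 <= 0.80, R4 above.
    Hubs: R5 P <= 0.30, R6 <= 0.75, R7 above.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"P must be in [0, 1], got {p}")
    if z >= hub_z:
        if p <= hub_bounds["r6_lo"]:
            return "R5"
        if p <= hub_bounds["r7_lo"]:
            return "R6"
        return "R7"
    if p <= bounds["r2_lo"]:
        return "R1"
    if p <= bounds["r3_lo"]:
        return "R2"
    if p <= bounds["r4_lo"]:
        return "R3"
    return "R4"


def classify_roles(
    topology: pd.DataFrame,
    party_cutoff: float = 0.5,
    hubs_only: bool = False,
    hub_z: float = HUB_Z,
) -> pd.Series:
    """APCC-based role per node: fight-club (< 0), date (0..cutoff], party (> cutoff).

    ``hubs_only`` restricts classification to nodes with Z >= hub_z; nodes
    with undefined APCC get 'none'.
    """
    roles = []
    for _, row in topology.iterrows():
        a = row["apcc"]
        if (hubs_only and row["Z"] < hub_z) or not np.isfinite(a):
            roles.append("none")
        elif a < 0:
            roles.append("fight_club_hub")
        elif a > party_cutoff:
            roles.append("party_hub")
        elif a > 0:
            roles.append("date_hub")
        else:
            roles.append("none")
    return pd.Series(roles, index=topology.index, name="role")


def find_switch_genes(topology: pd.DataFrame) -> set[str]:
    """Kinless anti-correlated nodes: region R4 (non-hub, P > 0.8) with APCC < 0.

    By construction the set is contained in the fight-club classification
    (APCC < 0).
    """
    mask = (topology["region"] == "R4") & (topology["apcc"] < 0)
    return set(topology.index[mask.fillna(False)])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class CartographyResult:
    graph: nx.Graph
    partition: dict[str, int]
    topology: pd.DataFrame
    switch_genes: set[str]

    @property
    def fight_club(self) -> set[str]:
        mask = self.topology["apcc"] < 0
        return set(self.topology.index[mask.fillna(False)])


def heat_cartography(
    graph: nx.Graph,
    em: ExpressionMatrix,
    partition: dict[str, int] | None = None,
    p_variant: str = "clusterphobic",
    party_cutoff: float = 0.5,
    hubs_only: bool = False,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
) -> CartographyResult:
    """Full cartography: modules, Z, both P variants, APCC, regions, roles.

    Region assignment and switch-gene mining use ``p_variant``; the other
    variant is reported alongside.  Node attributes are written back onto
    the graph so the GraphML export carries the topology.
    """
    nodes = list(graph.nodes)
    if partition is None:
        partition = detect_modules(em, nodes, k_range=k_range, seed=seed)
    z = within_module_degree_z(graph, partition)
    p_guimera = participation_coefficient(graph, partition, "guimera")
    p_cluster = participation_coefficient(graph, partition, "clusterphobic")
    chosen = p_cluster if p_variant == "clusterphobic" else p_guimera
    a = apcc(graph, em)
    topology = pd.DataFrame(
        {
            "degree": pd.Series({n: graph.degree(n) for n in nodes}),
            "module": pd.Series(partition),
            "Z": pd.Series(z),
            "P": pd.Series(chosen),
            "P_guimera": pd.Series(p_guimera),
            "P_clusterphobic": pd.Series(p_cluster),
            "apcc": pd.Series(a),
        }
    ).loc[nodes]
    topology["region"] = [assign_region(topology.at[n, "Z"], topology.at[n, "P"]) for n in nodes]
    topology["role"] = classify_roles(topology, party_cutoff=party_cutoff, hubs_only=hubs_only)
    switches = find_switch_genes(topology)
    topology.loc[sorted(switches), "role"] = "switch_gene"
    for n in nodes:
        graph.nodes[n].update(
            module=int(topology.at[n, "module"]),
            Z=float(topology.at[n, "Z"]),
            P=float(topology.at[n, "P"]),
            APCC=float(topology.at[n, "apcc"]) if np.isfinite(topology.at[n, "apcc"]) else None,
            region=topology.at[n, "region"],
            role=topology.at[n, "role"],
        )
    return CartographyResult(graph=graph, partition=partition, topology=topology,
                             switch_genes=switches)
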
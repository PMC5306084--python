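"""Transcription-factor co-expression network: k-NN mutual information,
CLR scoring, top-quantile edges, greedy-modularity communities, community
GO enrichment and up/down regulation overlay.

Pairwise mutual information is estimated with the Kraskov-Stoegbauer-
Grassberger (KSG) k-nearest-neighbour estimator (default k = 9).  CLR
(context likelihood of relatedness) turns the MI matrix into a background-
corrected score: z-scores of each pair against both genes' MI
distributions, combined as sqrt(z_i^2 + z_j^2).  Edges are kept for TF
pairs scoring in the top quantile (default top 0.1 %).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import hypergeom

from .consensus import GeneRegulation
from .io_model import GeneSetCollection, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Mutual information (KSG estimator, algorithm 1)
# ---------------------------------------------------------------------------


def _ksg_pair(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """KSG estimator I(X;Y) in nats for two 1-D samples (max-norm)."""
    n = x.size
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # distance to the k-th neighbour in the joint (Chebyshev) space
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # marginal counts of points strictly within eps, via sorted projections
    xs, ys = np.sort(x), np.sort(y)
    nx_ = (
        np.searchsorted(xs, x + eps, side="left")
        - np.searchsorted(xs, x - eps, side="right")
        - 1
    )
    ny_ = (
        np.searchsorted(ys, y + eps, side="left")
        - np.searchsorted(ys, y - eps, side="right")
        - 1
    )
    mi = (
        digamma(k)
        + digamma(n)
        - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    )
    return float(mi)


@dataclass
class MIMatrix:
    """Symmetric mutual-information estimates (nats) over selected genes."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.genes)):
            raise ValidationError("MI matrix shape does not match gene list")


def knn_mutual_information(
    expression: np.ndarray,
    genes: list[str],
    k: int = 9,
    seed: int = 0,
    jitter: float = 1e-10,
) -> MIMatrix:
    """Pairwise KSG MI over gene expression rows (genes × samples).

    A tiny seeded jitter breaks exact value ties (the estimator assumes
    continuous marginals); negative estimates are floored at 0; constant
    genes get MI 0 against everything.
    """
    expression = np.asarray(expression, dtype=float)
    n_genes, n_samples = expression.shape
    if n_genes != len(genes):
        raise ValidationError("gene list does not match expression rows")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n_samples < k + 2:
        raise ValidationError(f"need >= k+2 = {k + 2} samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    data = expression + jitter * rng.standard_normal(expression.shape)
    constant = expression.std(axis=1) == 0
    if constant.any():
        log.info("%d constant gene vector(s): MI set to 0", int(constant.sum()))
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        if constant[i]:
            continue
        for j in range(i + 1, n_genes):
            if constant[j]:
                continue
            est = max(0.0, _ksg_pair(data[i], data[j], k))
            mi[i, j] = mi[j, i] = est
    return MIMatrix(genes=list(genes), values=mi)


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------


def clr_scores(mi: MIMatrix) -> np.ndarray:
    """CLR background correction of an MI matrix.

    For gene i, z_i(j) = max(0, (MI_ij - mean_i) / sd_i) over i's
    off-diagonal row; score(i, j) = sqrt(z_i(j)^2 + z_j(i)^2).  Rows with
    zero MI variance contribute z = 0.
    """
    m = np.asarray(mi.values, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("CLR needs a square matrix")
    if not np.allclose(m, m.T):
        raise ValidationError("CLR needs a symmetric matrix")
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    means = np.array([m[i, off[i]].mean() for i in range(n)])
    sds = np.array([m[i, off[i]].std() for i in range(n)])
    zero_var = sds == 0
    if zero_var.any():
        log.info("%d MI row(s) with zero variance: z terms set to 0", int(zero_var.sum()))
    sds = np.where(zero_var, 1.0, sds)
    z = (m - means[:, None]) / sds[:, None]
    z = np.maximum(z, 0.0)
    z[zero_var, :] = 0.0
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return scores


# ---------------------------------------------------------------------------
# Network construction and analysis
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionNetwork:
    """TF nodes, CLR-scored edges, optional communities and node states."""

    graph: nx.Graph
    communities: list[frozenset[str]] = field(default_factory=list)
    retained_communities: list[int] = field(default_factory=list)
    node_state: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["clr_score"]) for u, v, d in self.graph.edges(data=True)]


def build_network(
    scores: np.ndarray,
    genes: list[str],
    tf_list: GeneSetCollection | frozenset[str],
    edge_quantile: float = 0.001,
) -> CoexpressionNetwork:
    """Restrict scores to TF × TF and keep the top-quantile pairs as edges.

    With m TF pairs, ceil(edge_quantile * m) edges are kept; pairs tied with
    the threshold score are all retained (superset rule).  Isolated TF
    nodes stay in the graph.
    """
    if isinstance(tf_list, GeneSetCollection):
        tfs: set[str] = set()
        for name in tf_list.names():
            tfs |= set(tf_list.members(name))
    else:
        tfs = set(tf_list)
    keep = [i for i, g in enumerate(genes) if g in tfs]
    if not keep:
        raise ValidationError("no overlap between TF list and scored genes")
    tf_genes = [genes[i] for i in keep]
    sub = np.asarray(scores)[np.ix_(keep, keep)]
    n = len(tf_genes)
    iu, ju = np.triu_indices(n, k=1)
    pair_scores = sub[iu, ju]
    n_pairs = pair_scores.size
    graph = nx.Graph()
    graph.add_nodes_from(tf_genes)
    if n_pairs:
        m = min(n_pairs, math.ceil(edge_quantile * n_pairs))
        if m > 0:
            threshold = np.sort(pair_scores)[::-1][m - 1]
            sel = pair_scores >= threshold  # keeps ties: superset
            if sel.sum() > m:
                log.info(
                    "threshold ties: keeping %d edges instead of %d",
                    int(sel.sum()),
                    m,
                )
            for i, j in zip(iu[sel], ju[sel]):
                graph.add_edge(tf_genes[i], tf_genes[j], clr_score=float(sub[i, j]))
    return CoexpressionNetwork(graph=graph)


def detect_communities(
    network: CoexpressionNetwork, min_size: int = 6, top_n: int = 18
) -> CoexpressionNetwork:
    """Greedy modularity-maximization partition of the network.

    Communities are ranked by size; the ``top_n`` largest are retained for
    enrichment, with those smaller than ``min_size`` flagged (dropped from
    the retained list).
    """
    if network.graph.number_of_nodes() == 0:
        raise ValidationError("empty network")
    graph = network.graph
    if graph.number_of_edges() == 0:
        comms = [frozenset([n]) for n in graph.nodes]
    else:
        comms = [
            frozenset(c)
            for c in nx.community.greedy_modularity_communities(graph, weight="clr_score")
        ]
    comms.sort(key=lambda c: (-len(c), sorted(c)[0]))
    retained = [
        i for i, c in enumerate(comms[:top_n]) if len(c) >= min_size
    ]
    network.communities = comms
    network.retained_communities = retained
    return network


def enrich_communities(
    network: CoexpressionNetwork,
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
    retained_only: bool = True,
) -> dict[int, list[tuple[str, float]]]:
    """One-sided Fisher (hypergeometric) term enrichment per community.

    Background is the full node set of the network; terms with unadjusted
    p < alpha are reported, sorted ascending by p.
    """
    if not network.communities:
        raise ValidationError("run detect_communities first")
    background = set(network.nodes)
    N = len(background)
    which = (
        network.retained_communities
        if retained_only
        else range(len(network.communities))
    )
    out: dict[int, list[tuple[str, float]]] = {}
    for ci in which:
        community = network.communities[ci] & background
        if not community:
            continue
        T = len(community)
        hits: list[tuple[str, float]] = []
        for name in gene_sets.names():
            members = gene_sets.members(name) & background
            D = len(members)
            if D == 0:
                continue
            O = len(members & community)
            p = float(hypergeom.sf(O - 1, N, D, T))
            if p < alpha:
                hits.append((name, p))
        hits.sort(key=lambda t: (t[1], t[0]))
        out[ci] = hits
    return out


def overlay_regulation(
    network: CoexpressionNetwork,
    regulation: dict[str, GeneRegulation],
) -> dict:
    """Mark TF nodes up/down from a gene-level regulation map.

    Inconsistently regulated TFs are set to ``none`` and flagged (removed
    from the affected counts).  Returns per-community affected counts and
    the fraction of all affected TFs falling in each community.
    """
    state: dict[str, str] = {}
    inconsistent: list[str] = []
    for node in network.nodes:
        reg = regulation.get(node)
        if reg is None or reg.status == "none":
            state[node] = "none"
        elif reg.status == "inconsistent":
            state[node] = "none"
            inconsistent.append(node)
        else:
            state[node] = reg.status
    network.node_state = state
    affected = {n for n, s in state.items() if s in ("up", "down")}
    per_community = []
    for ci, community in enumerate(network.communities):
        hits = community & affected
        per_community.append(
            {
                "community": ci,
                "size": len(community),
                "affected": len(hits),
                "fraction_of_affected": len(hits) / len(affected) if affected else 0.0,
            }
        )
    return {
        "node_state": state,
        "inconsistent_removed": sorted(inconsistent),
        "n_affected": len(affected),
        "per_community": per_community,
    }
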
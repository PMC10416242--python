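"""Hub scores and classical centralities of association networks.

The hub score is the Kleinberg/HITS score; on an undirected graph it is
the principal eigenvector of A·Aᵀ = A², computed here by power iteration
with a fixed all-ones start vector and rescaled so the maximum score is
1. Degree, betweenness (unnormalized, each unordered pair counted once)
and closeness (within-component, (n_c - 1) / sum of distances) use the
standard graph-library algorithms; isolated nodes score 0 everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netinfer import AssociationNetwork
from .taxonomy import RANKS, TaxonomyRecord

__all__ = [
    "CentralityProfile",
    "hub_scores",
    "centrality_profile",
    "top_hubs",
]

_POWER_TOL = 1e-10
_POWER_MAX_ITER = 10_000


@dataclass(frozen=True)
class CentralityProfile:
    node: str
    degree: int
    betweenness: float
    closeness: float
    hub_score: float


def hub_scores(network: AssociationNetwork) -> pd.Series:
    """Kleinberg hub score per node, scaled so the maximum is 1.

    On an undirected graph hub and authority scores coincide with the
    principal (Perron) eigenvector of the adjacency matrix, which spans
    the dominant eigenspace of A·Aᵀ. The square A·Aᵀ = A² is blind to the
    sign of the adjacency spectrum, so on bipartite components its top
    eigenspace is degenerate; power iteration therefore runs on the
    shifted matrix A + I, which has the same eigenvectors but isolates
    the Perron branch, making the result deterministic. All-ones start
    vector, tolerance 1e-10, rescaled so the maximum score is 1.

    An edgeless network scores every node 0 (with a warning). Isolated
    nodes always score 0.
    """
    nodes = list(network.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    if network.n_edges == 0:
        warnings.warn("network has no edges; all hub scores are 0", stacklevel=2)
        return pd.Series(np.zeros(n), index=nodes, name="hub_score")
    a = np.zeros((n, n))
    for i, j in network.edges:
        a[idx[i], idx[j]] = a[idx[j], idx[i]] = 1.0
    x = np.ones(n)
    x /= np.linalg.norm(x)
    for _ in range(_POWER_MAX_ITER):
        y = a @ x + x  # (A + I) x : Perron-branch power step
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - impossible with >=1 edge
            break
        y /= norm
        if np.abs(y - x).max() < _POWER_TOL:
            x = y
            break
        x = y
    x = np.abs(x)
    x[a.sum(axis=1) == 0] = 0.0  # isolates score exactly 0 by convention
    x /= x.max()
    return pd.Series(x, index=nodes, name="hub_score")


def centrality_profile(network: AssociationNetwork) -> pd.DataFrame:
    """Degree, betweenness, closeness and hub score for every node.

    Conventions: betweenness is the unnormalized Brandes pair-dependency
    sum with each unordered pair counted once; closeness is computed
    within each connected component as (n_c - 1) / sum of shortest-path
    distances; isolated nodes get 0 for everything.
    """
    g = network.to_networkx()
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    hubs = hub_scores(network) if network.n_edges else pd.Series(
        0.0, index=list(network.nodes)
    )
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=int),
            "betweenness": pd.Series(betweenness, dtype=float),
            "closeness": pd.Series(closeness, dtype=float),
            "hub_score": hubs.astype(float),
        }
    ).loc[list(network.nodes)]
    df.index.name = "node"
    return df


def top_hubs(
    scores: pd.Series,
    taxonomy: dict[str, TaxonomyRecord] | None = None,
    k: int = 20,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Top-k nodes by hub score, annotated with their lineages.

    Ties are broken by stable node-identifier order. Each row carries the
    hub score and, when taxonomy is given, the seven rank labels (MDM
    where flagged). Also returns the count of top-k rows that are MDM at
    each rank. ``k`` larger than the node count returns all nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(scores.index, key=lambda v: (-scores[v], str(v)))[:k]
    rows = []
    mdm_counts = dict.fromkeys(RANKS, 0)
    for node in order:
        row: dict[str, object] = {"node": node, "hub_score": float(scores[node])}
        if taxonomy is not None:
            rec = taxonomy.get(str(node))
            if rec is None:
                raise KeyError(f"node {node!r} missing from taxonomy")
            for rank, label, flag in zip(RANKS, rec.display_ranks(), rec.mdm_flags):
                row[rank] = label
                if flag:
                    mdm_counts[rank] += 1
        rows.append(row)
    return pd.DataFrame(rows), mdm_counts
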
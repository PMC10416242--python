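"""Compositional co-occurrence network inference.

Counts are mapped to the centered log-ratio (CLR) scale after adding a
pseudocount; each taxon's CLR column is then regressed on all others with
an L1 penalty (Meinshausen–Bühlmann neighborhood selection), and the
per-node neighborhoods are symmetrized into an undirected graph whose
edges represent pairs that are not conditionally independent. The penalty
is chosen by stability selection (StARS): the densest graph on the path
whose edge-selection instability across subsamples stays below a
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .abundance import AbundanceTable

__all__ = [
    "CompositionMatrix",
    "AssociationNetwork",
    "NonConvergenceError",
    "clr_transform",
    "null_penalty",
    "default_penalty_path",
    "neighborhood_fit",
    "stars_select",
    "symmetrize",
    "infer_network",
]

Edge = tuple[str, str]

_LASSO_TOL = 1e-6
_LASSO_MAX_ITER = 50_000


class NonConvergenceError(RuntimeError):
    """Coordinate descent failed to converge for one node's regression."""

    def __init__(self, node: str):
        self.node = node
        super().__init__(f"lasso regression did not converge for node {node!r}")


@dataclass(frozen=True)
class CompositionMatrix:
    """CLR-transformed abundances (samples x taxa); rows sum to ~0."""

    values: pd.DataFrame
    source_pseudocount: float

    def __post_init__(self) -> None:
        sums = self.values.to_numpy().sum(axis=1)
        if self.values.size and np.abs(sums).max() > 1e-8:
            raise ValueError("CLR rows must sum to 0 within 1e-8")

    @property
    def taxon_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationNetwork:
    """Undirected co-occurrence network with inference metadata."""

    nodes: list[str]
    edges: set[Edge]
    signs: dict[Edge, int] = field(default_factory=dict)
    penalty_path: np.ndarray | None = None
    selected_penalty: float | None = None
    instability_curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i!r}")
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge ({i!r}, {j!r}) references unknown node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        n = len(self.nodes)
        possible = n * (n - 1) // 2
        return len(self.edges) / possible if possible else 0.0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in sorted(self.edges):
            g.add_edge(*e, sign=self.signs.get(e, 0))
        return g

    def copy_with_edges(self, edges: set[Edge]) -> "AssociationNetwork":
        return AssociationNetwork(
            nodes=list(self.nodes),
            edges=set(edges),
            signs={e: s for e, s in self.signs.items() if e in edges},
            penalty_path=self.penalty_path,
            selected_penalty=self.selected_penalty,
            instability_curve=self.instability_curve,
        )


def _edge(i: str, j: str) -> Edge:
    return (i, j) if i <= j else (j, i)


def clr_transform(table: AbundanceTable, pseudocount: float = 1.0) -> CompositionMatrix:
    """Centered log-ratio transform of a count table.

    Each entry becomes ``log(count + pseudocount)`` minus its row mean, so
    every row sums to zero. The pseudocount (default 1) handles the zeros
    that dominate sparse OTU tables.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = table.counts().astype(float)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    logs = np.log(counts + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CompositionMatrix(
        values=pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        source_pseudocount=pseudocount,
    )


def _standardized(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (values - mu) / sd_safe
    z[:, sd == 0] = 0.0
    return z


def null_penalty(clr_matrix: CompositionMatrix) -> float:
    """Smallest penalty at which every neighborhood is empty.

    With standardized columns the lasso's null threshold for node j is the
    maximum absolute correlation with any other column; the global null
    penalty is the maximum over nodes.
    """
    z = _standardized(clr_matrix.values.to_numpy())
    n = z.shape[0]
    corr = np.abs(z.T @ z) / n
    np.fill_diagonal(corr, 0.0)
    return float(corr.max())


def default_penalty_path(
    clr_matrix: CompositionMatrix,
    length: int = 20,
    min_ratio: float = 1e-2,
) -> np.ndarray:
    """Log-spaced decreasing path from the null penalty down to its min_ratio."""
    lam_max = null_penalty(clr_matrix)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, num=length)


def neighborhood_fit(
    clr_matrix: CompositionMatrix, penalty: float
) -> dict[str, dict[str, int]]:
    """Per-node L1-penalized neighborhoods at one penalty.

    Each column is regressed (standardized response and predictors,
    coordinate descent, tolerance 1e-6) on all other columns; the
    neighbors of node j are the predictors with nonzero coefficients,
    mapped to the sign of their coefficient.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if clr_matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    z = _standardized(clr_matrix.values.to_numpy())
    taxa = clr_matrix.taxon_ids
    p = len(taxa)
    neighborhoods: dict[str, dict[str, int]] = {}
    mask = np.ones(p, dtype=bool)
    for j, node in enumerate(taxa):
        mask[:] = True
        mask[j] = False
        model = Lasso(
            alpha=penalty,
            fit_intercept=False,
            tol=_LASSO_TOL,
            max_iter=_LASSO_MAX_ITER,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(z[:, mask], z[:, j])
            except ConvergenceWarning as exc:
                raise NonConvergenceError(node) from exc
        coef = model.coef_
        others = [taxa[k] for k in range(p) if k != j]
        neighborhoods[node] = {
            other: int(np.sign(c)) for other, c in zip(others, coef) if c != 0.0
        }
    return neighborhoods


def _path_adjacency(values: np.ndarray, path: np.ndarray) -> np.ndarray:
    """OR-symmetrized boolean adjacency for every penalty on the path.

    Returns an array of shape (len(path), p, p). Uses the full
    regularization path solver per node for speed.
    """
    z = _standardized(values)
    n, p = z.shape
    selected = np.zeros((len(path), p, p), dtype=bool)
    for j in range(p):
        mask = np.ones(p, dtype=bool)
        mask[j] = False
        _, coefs, _ = lasso_path(
            z[:, mask], z[:, j], alphas=path, tol=_LASSO_TOL, max_iter=_LASSO_MAX_ITER
        )
        nonzero = coefs != 0.0  # (p-1, len(path))
        others = np.flatnonzero(mask)
        for a in range(len(path)):
            sel = others[nonzero[:, a]]
            selected[a, j, sel] = True
    return selected | selected.transpose(0, 2, 1)


def stars_select(
    clr_matrix: CompositionMatrix,
    penalty_path: np.ndarray | None = None,
    n_subsamples: int = 20,
    subsample_ratio: float | None = None,
    instability_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Stability-based penalty selection (StARS).

    For each penalty on the (strictly decreasing) path, networks are
    fitted on ``n_subsamples`` row subsamples drawn without replacement;
    the instability at a penalty is ``2 * mean over node pairs of
    p_hat * (1 - p_hat)`` where p_hat is the edge selection frequency.
    The selected penalty is the smallest (densest graph) whose
    running-supremum instability, accumulated from the sparse end of the
    path, stays at or below the threshold; if even the sparsest penalty
    is unstable, the sparsest penalty is returned.

    Returns ``(selected_penalty, penalty_path, instability_curve)``.
    """
    if penalty_path is None:
        penalty_path = default_penalty_path(clr_matrix)
    path = np.asarray(penalty_path, dtype=float)
    if path.size == 0:
        raise ValueError("penalty path is empty")
    if path.size > 1 and not np.all(np.diff(path) < 0):
        raise ValueError("penalty path must be strictly decreasing")
    if n_subsamples < 2:
        raise ValueError("need at least 2 subsamples")
    values = clr_matrix.values.to_numpy()
    n, p = values.shape
    if subsample_ratio is None:
        subsample_ratio = min(0.8, 10.0 * np.sqrt(n) / n)
    b = max(3, int(np.floor(subsample_ratio * n)))
    rng = np.random.default_rng(seed)
    freq = np.zeros((path.size, p, p))
    for _ in range(n_subsamples):
        rows = rng.choice(n, size=b, replace=False)
        freq += _path_adjacency(values[rows], path)
    phat = freq / n_subsamples
    iu = np.triu_indices(p, k=1)
    pair_inst = 2.0 * phat * (1.0 - phat)
    instability = np.array([pair_inst[a][iu].mean() for a in range(path.size)])
    run_sup = np.maximum.accumulate(instability)
    admissible = np.flatnonzero(run_sup <= instability_threshold)
    sel_idx = int(admissible[-1]) if admissible.size else 0
    return float(path[sel_idx]), path, instability


def symmetrize(
    neighborhoods: dict[str, dict[str, int]], rule: str = "OR"
) -> AssociationNetwork:
    """Combine directed neighborhoods into an undirected edge set.

    OR (default): an edge exists if either node selects the other.
    AND: both must select each other. Edge sign is the sign of the sum of
    the available coefficients' signs (0 if they conflict).
    """
    if rule not in ("OR", "AND"):
        raise ValueError(f"rule must be 'OR' or 'AND', got {rule!r}")
    nodes = list(neighborhoods)
    edges: set[Edge] = set()
    signs: dict[Edge, int] = {}
    for i, nbrs in neighborhoods.items():
        for j, sign_ij in nbrs.items():
            e = _edge(i, j)
            reverse = neighborhoods.get(j, {})
            if rule == "AND" and i not in reverse:
                continue
            edges.add(e)
            signs[e] = int(np.sign(sign_ij + reverse.get(i, 0)))
    return AssociationNetwork(nodes=nodes, edges=edges, signs=signs)


def infer_network(
    table: AbundanceTable,
    pseudocount: float = 1.0,
    penalty_path: np.ndarray | None = None,
    n_subsamples: int = 20,
    subsample_ratio: float | None = None,
    instability_threshold: float = 0.05,
    rule: str = "OR",
    seed: int = 0,
) -> AssociationNetwork:
    """End-to-end inference: CLR, StARS penalty selection, final MB fit."""
    clr = clr_transform(table, pseudocount)
    selected, path, curve = stars_select(
        clr,
        penalty_path=penalty_path,
        n_subsamples=n_subsamples,
        subsample_ratio=subsample_ratio,
        instability_threshold=instability_threshold,
        seed=seed,
    )
    nbrs = neighborhood_fit(clr, selected)
    net = symmetrize(nbrs, rule=rule)
    net.penalty_path = path
    net.selected_penalty = selected
    net.instability_curve = curve
    return net
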
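"""Synthetic microbiome data with known association structure.

Counts are generated under a logistic-normal-multinomial model: a latent
Gaussian vector with covariance equal to the inverse of a known sparse
precision matrix is softmax-mapped to a composition and then sampled as
multinomial counts at a per-sample sequencing depth. The precision
matrix's off-diagonal support defines the ground-truth association graph,
so conditional dependence on the CLR scale — exactly what neighborhood
selection estimates — is known by construction.

Taxonomy strings are generated SILVA/QIIME2-style with controllable
per-rank frequencies of "unknown" keywords, emulating the microbial dark
matter content of real classifier output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .taxonomy import RANKS, TaxonomyRecord

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_association_graph",
    "sample_counts",
    "generate_taxonomy",
    "generate_dataset",
]

#: Keywords planted into synthetic taxonomy strings to mark unknown ranks.
_PLANTED_KEYWORDS = ("uncultured", "unknown", "NA", "Incertae Sedis", "unidentified")

#: Magnitude of precision off-diagonals before conditioning. Negative
#: entries give positive partial correlations (cooperative co-occurrence).
_EDGE_WEIGHT = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults emulate a modest amplicon survey: tens of samples, sparse
    associations, sequencing depths of a few thousand reads, and unknown
    labels that grow more frequent toward the species level, as real
    classifier output does.
    """

    n_samples: int = 60
    n_taxa: int = 20
    graph_model: str = "band"
    edge_density: float = 0.1
    condition_target: float = 100.0
    depth_range: tuple[int, int] = (2000, 10000)
    mdm_fraction_by_rank: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        if self.graph_model not in ("band", "hub", "random"):
            raise ValueError("graph_model must be band, hub or random")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        if len(self.mdm_fraction_by_rank) != 7:
            raise ValueError("mdm_fraction_by_rank needs 7 entries")
        if any(not 0 <= f <= 1 for f in self.mdm_fraction_by_rank):
            raise ValueError("mdm fractions must lie in [0, 1]")
        if self.condition_target <= 1:
            raise ValueError("condition_target must exceed 1")


@dataclass(frozen=True)
class GroundTruth:
    """Known generating structure of a synthetic dataset."""

    precision_matrix: np.ndarray
    true_edges: frozenset[tuple[int, int]]
    taxonomy: tuple[TaxonomyRecord, ...] = ()
    diagonal_loading: float = 0.0

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision_matrix)


def _edge_list(n_taxa: int, graph_model: str, n_edges: int, rng) -> list[tuple[int, int]]:
    if graph_model == "band":
        # Fill off-diagonals in order of increasing bandwidth.
        edges = []
        for off in range(1, n_taxa):
            for i in range(n_taxa - off):
                edges.append((i, i + off))
                if len(edges) == n_edges:
                    return edges
        return edges
    if graph_model == "hub":
        # Partition nodes into g star groups; a group of size m contributes
        # m-1 edges, so g = n - e groups yield exactly e edges when feasible.
        g = max(1, n_taxa - n_edges)
        groups = np.array_split(np.arange(n_taxa), g)
        edges = []
        for grp in groups:
            hub = int(grp[0])
            edges.extend((min(hub, int(v)), max(hub, int(v))) for v in grp[1:])
        return edges
    # random: choose n_edges pairs uniformly without replacement
    all_pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    return [all_pairs[k] for k in sorted(idx)]


def generate_association_graph(
    n_taxa: int,
    graph_model: str = "band",
    edge_density: float = 0.1,
    condition_target: float = 100.0,
    seed: int = 0,
) -> GroundTruth:
    """Build a sparse positive-definite precision matrix with known support.

    ``edge_density`` is the fraction of the n(n-1)/2 possible edges
    (at least one edge is always placed). Off-diagonal entries are set to
    ``-0.5``; the diagonal starts at 1 and is loaded uniformly until the
    condition number does not exceed ``condition_target``, which keeps
    partial correlations strong while guaranteeing invertibility.
    """
    rng = np.random.default_rng(seed)
    max_edges = n_taxa * (n_taxa - 1) // 2
    n_edges = max(1, round(edge_density * max_edges))
    n_edges = min(n_edges, max_edges)
    edges = _edge_list(n_taxa, graph_model, n_edges, rng)
    prec = np.eye(n_taxa)
    for i, j in edges:
        prec[i, j] = prec[j, i] = -_EDGE_WEIGHT
    eigvals = np.linalg.eigvalsh(prec)
    lam_min, lam_max = eigvals[0], eigvals[-1]
    loading = 0.0
    if lam_min <= 0 or lam_max / lam_min > condition_target:
        loading = (lam_max - condition_target * lam_min) / (condition_target - 1)
        prec = prec + loading * np.eye(n_taxa)
    if np.linalg.eigvalsh(prec)[0] <= 0:
        raise RuntimeError(
            "precision matrix not positive definite after diagonal loading"
        )
    return GroundTruth(
        precision_matrix=prec,
        true_edges=frozenset((min(i, j), max(i, j)) for i, j in edges),
        diagonal_loading=loading,
    )


def sample_counts(
    ground_truth: GroundTruth,
    n_samples: int,
    depth_range: tuple[int, int] = (2000, 10000),
    seed: int = 0,
) -> AbundanceTable:
    """Draw a count table under the logistic-normal-multinomial model.

    Each sample draws a latent Gaussian vector with covariance equal to
    the inverse precision, maps it through a softmax to a composition,
    draws a depth uniformly on ``depth_range``, and samples multinomial
    counts. Every row sums to its drawn depth exactly.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    prec = ground_truth.precision_matrix
    n_taxa = prec.shape[0]
    cov = np.linalg.inv(prec)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise RuntimeError("degenerate covariance: cannot factorize") from exc
    latent = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    # Softmax per row (stable).
    z = latent - latent.max(axis=1, keepdims=True)
    expz = np.exp(z)
    comp = expz / expz.sum(axis=1, keepdims=True)
    lo, hi = depth_range
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.vstack(
        [rng.multinomial(depths[s], comp[s]) for s in range(n_samples)]
    )
    width_t = len(str(n_taxa))
    width_s = len(str(n_samples))
    df = pd.DataFrame(
        counts,
        index=[f"s{str(i + 1).zfill(width_s)}" for i in range(n_samples)],
        columns=[f"t{str(j + 1).zfill(width_t)}" for j in range(n_taxa)],
    )
    return AbundanceTable(df)


def generate_taxonomy(
    n_taxa: int,
    mdm_fraction_by_rank: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.9),
    seed: int = 0,
) -> list[TaxonomyRecord]:
    """Generate SILVA-style seven-rank lineages with planted unknown labels.

    Clean lineages follow a nested hierarchy (taxa sharing a phylum share
    the same label, etc.) so that rank aggregation has realistic label
    sharing. Independently at each rank, with the requested per-rank
    probability, the label is replaced by one of the unknown-classification
    keywords. Records are returned un-relabeled; apply
    :func:`umbranet.taxonomy.relabel_mdm` to propagate MDM flags downward.
    """
    if len(mdm_fraction_by_rank) != 7:
        raise ValueError("mdm_fraction_by_rank needs 7 entries")
    if any(not 0 <= f <= 1 for f in mdm_fraction_by_rank):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # Number of distinct groups per rank grows geometrically with depth.
    n_groups = [
        max(1, min(n_taxa, int(np.ceil(n_taxa / 2 ** (6 - r)))))
        for r in range(7)
    ]
    width_t = len(str(n_taxa))
    records = []
    for t in range(n_taxa):
        labels = []
        parent = "Bacteria" if rng.random() < 0.9 else "Archaea"
        labels.append(parent)
        for r in range(1, 7):
            grp = t % n_groups[r]
            labels.append(f"{RANKS[r].capitalize()}{grp + 1:03d}")
        for r in range(7):
            if rng.random() < mdm_fraction_by_rank[r]:
                labels[r] = _PLANTED_KEYWORDS[rng.integers(len(_PLANTED_KEYWORDS))]
        records.append(
            TaxonomyRecord(
                taxon_id=f"t{str(t + 1).zfill(width_t)}",
                ranks=tuple(labels),
            )
        )
    return records


def generate_dataset(spec: SyntheticSpec) -> tuple[AbundanceTable, GroundTruth]:
    """Full synthetic dataset: graph, counts and taxonomy from one spec.

    Child seeds for the three stages are derived from ``spec.seed`` by
    counter so each stage is independently reproducible.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_graph, s_counts, s_tax = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    gt = generate_association_graph(
        spec.n_taxa,
        spec.graph_model,
        spec.edge_density,
        spec.condition_target,
        seed=s_graph,
    )
    table = sample_counts(gt, spec.n_samples, spec.depth_range, seed=s_counts)
    taxonomy = generate_taxonomy(spec.n_taxa, spec.mdm_fraction_by_rank, seed=s_tax)
    gt = GroundTruth(
        precision_matrix=gt.precision_matrix,
        true_edges=gt.true_edges,
        taxonomy=tuple(taxonomy),
        diagonal_loading=gt.diagonal_loading,
    )
    return table, gt
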
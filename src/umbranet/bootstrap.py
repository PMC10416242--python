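"""Permutation bootstrap for edge significance.

Each taxon's abundance vector is independently shuffled across samples,
breaking sample–abundance associations while conserving every taxon's
marginal distribution. A network is rebuilt from each permuted table and
the recurrence of every original edge is counted: edges that keep
reappearing under the permutation null are likely spurious and are
removed. At the reference configuration (B = 5000 replicates, alpha =
0.05) an edge is removed when it appears in more than 250 bootstrap
networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .netinfer import (
    AssociationNetwork,
    NonConvergenceError,
    clr_transform,
    infer_network,
    neighborhood_fit,
    symmetrize,
)

__all__ = [
    "EdgeSupport",
    "BootstrapConfig",
    "removal_threshold",
    "permute_table",
    "bootstrap_edge_support",
    "filter_edges",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap parameters. Defaults follow the reference analysis
    (5000 replicates, alpha 0.05, penalty reused across replicates)."""

    B: int = 5000
    alpha: float = 0.05
    reuse_penalty: bool = True
    seed: int = 0
    pseudocount: float = 1.0
    rule: str = "OR"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class EdgeSupport:
    """Bootstrap occurrence count and verdict for one original edge."""

    edge: tuple[str, str]
    bootstrap_count: int
    retained: bool


def removal_threshold(B: int, alpha: float) -> int:
    """Maximum admissible bootstrap count: edges with count strictly
    greater than ``floor(alpha * B)`` are removed (250 at B=5000,
    alpha=0.05)."""
    return int(np.floor(alpha * B))


def permute_table(table: AbundanceTable, seed: int = 0) -> AbundanceTable:
    """Independently permute each taxon's abundances across samples.

    Conserves each taxon's multiset of values; per-sample sums are
    generally not conserved.
    """
    rng = np.random.default_rng(seed)
    values = table.counts().copy()
    for j in range(values.shape[1]):
        values[:, j] = values[rng.permutation(values.shape[0]), j]
    return AbundanceTable(
        pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    )


def bootstrap_edge_support(
    table: AbundanceTable,
    original_network: AssociationNetwork,
    config: BootstrapConfig = BootstrapConfig(),
) -> list[EdgeSupport]:
    """Count original-edge recurrence over B permutation-null networks.

    When ``config.reuse_penalty`` (default) each replicate refits the
    neighborhoods at the original network's selected penalty; otherwise
    the full stability selection is re-run per replicate. Replicates whose
    fit does not converge are dropped and logged; the effective B is the
    number of completed replicates and the removal threshold scales with
    it.
    """
    if original_network.selected_penalty is None and config.reuse_penalty:
        raise ValueError(
            "original network carries no selected penalty; refit or set reuse_penalty=False"
        )
    child_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(config.seed).spawn(config.B)
    ]
    original_edges = sorted(original_network.edges)
    counts = {e: 0 for e in original_edges}
    b_effective = 0
    for b in range(config.B):
        permuted = permute_table(table, seed=child_seeds[b])
        try:
            if config.reuse_penalty:
                clr = clr_transform(permuted, config.pseudocount)
                nbrs = neighborhood_fit(clr, original_network.selected_penalty)
                net = symmetrize(nbrs, rule=config.rule)
            else:
                net = infer_network(
                    permuted,
                    pseudocount=config.pseudocount,
                    rule=config.rule,
                    seed=child_seeds[b],
                )
        except NonConvergenceError as exc:
            logger.warning("bootstrap replicate %d dropped: %s", b, exc)
            continue
        b_effective += 1
        for e in original_edges:
            if e in net.edges:
                counts[e] += 1
    if b_effective == 0:
        raise RuntimeError("no bootstrap replicate converged")
    if b_effective < config.B:
        logger.warning(
            "bootstrap completed with %d of %d replicates", b_effective, config.B
        )
    thr = removal_threshold(b_effective, config.alpha)
    return [
        EdgeSupport(edge=e, bootstrap_count=counts[e], retained=counts[e] <= thr)
        for e in original_edges
    ]


def filter_edges(
    original_network: AssociationNetwork,
    supports: list[EdgeSupport],
    config: BootstrapConfig = BootstrapConfig(),
) -> AssociationNetwork:
    """Remove edges whose bootstrap count exceeds ``floor(alpha * B)``.

    The node set is unchanged; isolated nodes are allowed. Every original
    edge must carry a support record.
    """
    support_map = {s.edge: s for s in supports}
    missing = [e for e in original_network.edges if e not in support_map]
    if missing:
        raise KeyError(f"missing support records for edges: {sorted(missing)}")
    thr = removal_threshold(config.B, config.alpha)
    kept = {
        e for e in original_network.edges if support_map[e].bootstrap_count <= thr
    }
    return original_network.copy_with_edges(kept)
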
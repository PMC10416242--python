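"""Model/Results interface over the network-inference pipeline.

:class:`CooccurrenceNetworkModel` is built from an abundance table (and
optionally taxonomy); ``fit()`` runs CLR + stability-selected
Meinshausen–Bühlmann neighborhood selection and returns a
:class:`CooccurrenceNetworkResults` carrying the network, the penalty
path with its instability curve, and post-fit analyses: permutation
bootstrap edge filtering, hub/centrality scoring, and the MDM-removal
degradation comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .bootstrap import BootstrapConfig, bootstrap_edge_support, filter_edges
from .degradation import DegradationReport, build_report, random_known_removal_null, remove_nodes
from .hubs import centrality_profile, hub_scores, top_hubs
from .netinfer import AssociationNetwork, clr_transform, infer_network
from .taxonomy import TaxonomyRecord

__all__ = ["CooccurrenceNetworkModel", "CooccurrenceNetworkResults"]


class CooccurrenceNetworkModel:
    """Compositional co-occurrence network model for one abundance table.

    Parameters
    ----------
    table : AbundanceTable
        Samples x taxa counts.
    taxonomy : dict[str, TaxonomyRecord], optional
        Lineages (post MDM-relabel) keyed by taxon id; enables annotated
        hub tables and the degradation analysis.
    pseudocount : float
        Added to counts before the CLR transform.

    Examples
    --------
    >>> model = CooccurrenceNetworkModel(table, taxonomy=tax)
    >>> res = model.fit(seed=1)
    >>> res.summary()
    """

    def __init__(self, table, taxonomy=None, pseudocount: float = 1.0):
        if isinstance(table, pd.DataFrame):
            table = AbundanceTable(table)
        self.table: AbundanceTable = table
        if taxonomy is not None and not isinstance(taxonomy, dict):
            taxonomy = {rec.taxon_id: rec for rec in taxonomy}
        self.taxonomy: dict[str, TaxonomyRecord] | None = taxonomy
        self.pseudocount = pseudocount

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, taxonomy=None, **kwargs):
        """Build from a samples x taxa DataFrame."""
        return cls(AbundanceTable(df), taxonomy=taxonomy, **kwargs)

    def fit(
        self,
        penalty_path=None,
        n_subsamples: int = 20,
        subsample_ratio: float | None = None,
        instability_threshold: float = 0.05,
        rule: str = "OR",
        seed: int = 0,
    ) -> "CooccurrenceNetworkResults":
        network = infer_network(
            self.table,
            pseudocount=self.pseudocount,
            penalty_path=penalty_path,
            n_subsamples=n_subsamples,
            subsample_ratio=subsample_ratio,
            instability_threshold=instability_threshold,
            rule=rule,
            seed=seed,
        )
        return CooccurrenceNetworkResults(model=self, network=network, rule=rule)


@dataclass
class CooccurrenceNetworkResults:
    """Fitted network plus post-fit analyses."""

    model: CooccurrenceNetworkModel
    network: AssociationNetwork
    rule: str = "OR"
    edge_supports: list | None = None
    filtered_network: AssociationNetwork | None = None

    # -- estimates -------------------------------------------------------
    @property
    def selected_penalty(self) -> float:
        return self.network.selected_penalty

    @property
    def instability_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "penalty": self.network.penalty_path,
                "instability": self.network.instability_curve,
            }
        )

    def analysis_network(self) -> AssociationNetwork:
        """The bootstrap-filtered network if available, else the raw fit."""
        return self.filtered_network if self.filtered_network is not None else self.network

    # -- post-fit analyses ----------------------------------------------
    def bootstrap_filter(
        self, B: int = 5000, alpha: float = 0.05, reuse_penalty: bool = True, seed: int = 0
    ) -> AssociationNetwork:
        """Permutation bootstrap edge filter; stores supports and the
        filtered network on the results object."""
        config = BootstrapConfig(
            B=B,
            alpha=alpha,
            reuse_penalty=reuse_penalty,
            seed=seed,
            pseudocount=self.model.pseudocount,
            rule=self.rule,
        )
        self.edge_supports = bootstrap_edge_support(self.model.table, self.network, config)
        self.filtered_network = filter_edges(self.network, self.edge_supports, config)
        return self.filtered_network

    def hub_scores(self) -> pd.Series:
        return hub_scores(self.analysis_network())

    def centrality(self) -> pd.DataFrame:
        return centrality_profile(self.analysis_network())

    def top_hubs(self, k: int = 20):
        return top_hubs(self.hub_scores(), taxonomy=self.model.taxonomy, k=k)

    def mdm_nodes(self, rank: str = "genus") -> list[str]:
        """Nodes whose lineage is MDM at ``rank`` (requires taxonomy).

        Unknown labels accumulate toward the species level, so "MDM at
        any rank" would flag nearly every OTU in realistic data; the
        rank-specific definition matches how rank-level networks label
        their unknown nodes.
        """
        if self.model.taxonomy is None:
            raise ValueError("taxonomy required to identify MDM nodes")
        return [
            v
            for v in self.network.nodes
            if str(v) in self.model.taxonomy
            and self.model.taxonomy[str(v)].is_mdm_at(rank)
        ]

    def degradation(
        self, mdm_nodes=None, n_reps: int = 100, seed: int = 0, rank: str = "genus"
    ) -> DegradationReport:
        """MDM-removal degradation analysis on the analysis network."""
        net = self.analysis_network()
        if mdm_nodes is None:
            mdm_nodes = self.mdm_nodes(rank)
        no_mdm = remove_nodes(net, mdm_nodes)
        nulls = random_known_removal_null(net, mdm_nodes, n_reps=n_reps, seed=seed)
        return build_report(net, no_mdm, nulls, rank=rank)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        net = self.network
        lines = [
            "Co-occurrence Network Results (MB neighborhood selection)",
            "=" * 58,
            f"Samples:             {self.model.table.n_samples}",
            f"Taxa (nodes):        {len(net.nodes)}",
            f"Pseudocount:         {self.model.pseudocount}",
            f"Symmetrization:      {self.rule}",
            f"Selected penalty:    {net.selected_penalty:.6g} (StARS)",
            f"Edges:               {net.n_edges}",
            f"Density:             {net.density():.4f}",
        ]
        if self.edge_supports is not None:
            kept = sum(s.retained for s in self.edge_supports)
            lines += [
                f"Bootstrap supports:  {len(self.edge_supports)} edges tested, "
                f"{kept} retained",
            ]
        if self.filtered_network is not None:
            lines += [f"Filtered edges:      {self.filtered_network.n_edges}"]
        scores = None
        if net.n_edges:
            scores = self.hub_scores().sort_values(ascending=False).head(5)
            lines += ["", "Top hub scores:"]
            for node, s in scores.items():
                lines.append(f"  {node:<24} {s:.4f}")
        return "\n".join(lines)
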
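"""Network degradation analysis: what happens when the unknowns go away.

The network rebuilt without microbial-dark-matter (MDM) nodes is compared
with the original network and with a size-matched null in which the same
number of *known* nodes is removed uniformly at random (default 100
replicates). Per-node centrality distributions (degree, betweenness,
closeness) are compared with two-sided Wilcoxon rank-sum tests, and
fragmentation is summarized by component counts. If MDM nodes hold the
network together, the MDM-removed network degrades more than the
size-matched null.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .hubs import centrality_profile
from .netinfer import AssociationNetwork

__all__ = [
    "DegradationReport",
    "remove_nodes",
    "random_known_removal_null",
    "wilcoxon_compare",
    "p_to_stars",
    "build_report",
]

METRICS = ("degree", "betweenness", "closeness")
COMPARISONS = (("original", "no_mdm"), ("original", "null"), ("no_mdm", "null"))

#: Significance bands: ns p>0.05; * p<=0.05; ** p<=0.01; *** p<=0.001; **** p<=0.0001.
_STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

_EXACT_MAX_GROUP = 8


def remove_nodes(network: AssociationNetwork, node_set) -> AssociationNetwork:
    """Induced subgraph on the surviving nodes."""
    node_set = set(node_set)
    unknown = node_set - set(network.nodes)
    if unknown:
        raise KeyError(f"unknown node ids: {sorted(unknown)}")
    nodes = [v for v in network.nodes if v not in node_set]
    edges = {e for e in network.edges if e[0] not in node_set and e[1] not in node_set}
    return AssociationNetwork(
        nodes=nodes,
        edges=edges,
        signs={e: s for e, s in network.signs.items() if e in edges},
        penalty_path=network.penalty_path,
        selected_penalty=network.selected_penalty,
        instability_curve=network.instability_curve,
    )


def random_known_removal_null(
    network: AssociationNetwork,
    mdm_nodes,
    n_reps: int = 100,
    seed: int = 0,
) -> list[AssociationNetwork]:
    """Size-matched null: remove |mdm_nodes| random *known* nodes per replicate.

    Keeps the network order identical to the MDM-removed network so metric
    changes attributable to size alone are controlled for.
    """
    mdm = set(mdm_nodes)
    unknown = mdm - set(network.nodes)
    if unknown:
        raise KeyError(f"mdm nodes not in network: {sorted(unknown)}")
    known = [v for v in network.nodes if v not in mdm]
    if len(known) < len(mdm):
        raise ValueError(
            f"null undefined: only {len(known)} known nodes but {len(mdm)} to remove"
        )
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        drop = rng.choice(len(known), size=len(mdm), replace=False)
        reps.append(remove_nodes(network, {known[i] for i in drop}))
    return reps


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test with midrank ties.

    For group sizes of at most 8 each, the null distribution of the
    U statistic is enumerated exactly over all rank assignments and the
    two-sided p-value is twice the smaller tail (capped at 1). For larger
    groups the normal approximation with continuity correction and tie
    correction is used. Two samples whose pooled values are all identical
    give p = 1 by convention.

    Returns ``(U_a, p_value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.all(pooled == pooled[0]):
        return u_a, 1.0
    if n1 <= _EXACT_MAX_GROUP and n2 <= _EXACT_MAX_GROUP:
        offset = (n1 * (n1 + 1)) / 2
        us = [
            sum(ranks[list(combo)]) - offset
            for combo in itertools.combinations(range(n1 + n2), n1)
        ]
        us = np.asarray(us)
        total = len(us)
        p_low = np.sum(us <= u_a + 1e-12) / total
        p_high = np.sum(us >= u_a - 1e-12) / total
        return u_a, float(min(1.0, 2.0 * min(p_low, p_high)))
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u_a, 1.0
    diff = u_a - mean_u
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var_u)
    return u_a, float(min(1.0, 2.0 * norm.sf(abs(z))))


def p_to_stars(p: float) -> str:
    """Map a p-value to the conventional significance band."""
    for cut, label in _STAR_BANDS:
        if p <= cut:
            return label
    return "ns"


def _fragmentation(network: AssociationNetwork) -> dict:
    g = network.to_networkx()
    n = g.number_of_nodes()
    comps = list(nx.connected_components(g)) if n else []
    largest = max((len(c) for c in comps), default=0)
    return {
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "n_components": len(comps),
        "largest_component_fraction": largest / n if n else 0.0,
    }


@dataclass
class DegradationReport:
    """Centrality distributions and tests for original / no-MDM / null."""

    rank: str | None
    distributions: dict  # metric -> {"original": [...], "no_mdm": [...], "null": [...]}
    wilcoxon_p: dict  # (metric, "a_vs_b") -> p-value
    stars: dict  # same keys -> band label
    fragmentation: dict  # network label -> fragmentation summary
    n_removed: int
    n_reps: int

    def to_json(self) -> str:
        payload = {
            "rank": self.rank,
            "n_removed": self.n_removed,
            "n_reps": self.n_reps,
            "fragmentation": self.fragmentation,
            "wilcoxon_p": {
                f"{metric}:{pair}": p for (metric, pair), p in self.wilcoxon_p.items()
            },
            "stars": {
                f"{metric}:{pair}": s for (metric, pair), s in self.stars.items()
            },
            "distributions": self.distributions,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (network, metric, value) table for box plots."""
        rows = []
        for metric, nets in self.distributions.items():
            for net_label, values in nets.items():
                for v in values:
                    rows.append({"network": net_label, "metric": metric, "value": v})
        return pd.DataFrame(rows, columns=["network", "metric", "value"])


def plot_degradation(report: "DegradationReport", path=None):
    """Minimal box-plot of the three centrality distributions per network."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(METRICS), figsize=(4 * len(METRICS), 4))
    for ax, metric in zip(np.atleast_1d(axes), METRICS):
        dist = report.distributions[metric]
        labels = [k for k in ("original", "no_mdm", "null") if dist.get(k)]
        ax.boxplot([dist[k] for k in labels], tick_labels=labels)
        ax.set_title(metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def build_report(
    original: AssociationNetwork,
    no_mdm: AssociationNetwork,
    null_replicates: list[AssociationNetwork],
    rank: str | None = None,
) -> DegradationReport:
    """Assemble the degradation comparison.

    Per metric, compares original vs no-MDM, original vs the pooled null
    distribution, and no-MDM vs pooled null, attaching star bands and
    fragmentation counts. Null replicate node values are pooled into one
    distribution.
    """
    prof = {
        "original": centrality_profile(original),
        "no_mdm": centrality_profile(no_mdm),
    }
    null_profiles = [centrality_profile(r) for r in null_replicates]
    distributions: dict = {}
    wilcoxon_p: dict = {}
    stars: dict = {}
    for metric in METRICS:
        dist = {
            "original": prof["original"][metric].tolist(),
            "no_mdm": prof["no_mdm"][metric].tolist(),
            "null": [v for p in null_profiles for v in p[metric].tolist()],
        }
        distributions[metric] = dist
        for a, b in COMPARISONS:
            if not dist[a] or not dist[b]:
                continue
            _, p = wilcoxon_compare(dist[a], dist[b])
            key = (metric, f"{a}_vs_{b}")
            wilcoxon_p[key] = p
            stars[key] = p_to_stars(p)
    fragmentation = {
        "original": _fragmentation(original),
        "no_mdm": _fragmentation(no_mdm),
    }
    if null_replicates:
        null_frags = [_fragmentation(r) for r in null_replicates]
        fragmentation["null_mean"] = {
            k: float(np.mean([f[k] for f in null_frags])) for k in null_frags[0]
        }
    return DegradationReport(
        rank=rank,
        distributions=distributions,
        wilcoxon_p=wilcoxon_p,
        stars=stars,
        fragmentation=fragmentation,
        n_removed=len(original.nodes) - len(no_mdm.nodes),
        n_reps=len(null_replicates),
    )
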
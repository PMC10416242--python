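"""End-to-end pipeline: relabel -> filter -> aggregate -> infer ->
bootstrap-filter -> hubs -> degradation, per taxonomic rank.

Driven by a YAML/dict config; every stage's randomness flows from one
master seed via counter-derived child seeds, and a run manifest records
the config snapshot, seeds, artifact digests, version and timestamps so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abundance import AbundanceTable
from .bootstrap import BootstrapConfig, bootstrap_edge_support, filter_edges
from .degradation import build_report, random_known_removal_null, remove_nodes
from .hubs import centrality_profile, hub_scores, top_hubs
from .io import (
    read_abundance,
    read_taxonomy,
    write_abundance,
    write_edge_supports,
    write_network,
    write_taxonomy,
)
from .model import CooccurrenceNetworkModel
from .netinfer import default_penalty_path, clr_transform
from .synthetic import SyntheticSpec, generate_dataset
from .taxonomy import (
    DEFAULT_MDM_KEYWORDS,
    FilterConfig,
    TaxonomyRecord,
    aggregate_to_rank,
    filter_taxa,
    relabel_mdm,
)

__all__ = ["DEFAULT_CONFIG", "DEMO_CONFIG", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Reference defaults: 5000 bootstrap replicates, alpha 0.05, 100 null
#: replicates, top-20 hub tables.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "umbranet_out",
    "ranks": ["phylum", "class", "order", "family", "genus"],
    "filter": {
        "min_samples": 2,
        "exclude_domains": ["Eukaryota"],
        "chloroplast_ranks": ["order", "family", "genus"],
    },
    "mdm_keywords": sorted(DEFAULT_MDM_KEYWORDS),
    "network": {
        "pseudocount": 1.0,
        "path_length": 20,
        "path_min_ratio": 0.01,
        "n_subsamples": 20,
        "subsample_ratio": None,
        "instability_threshold": 0.05,
        "rule": "OR",
    },
    "bootstrap": {"B": 5000, "alpha": 0.05, "reuse_penalty": True},
    "hubs": {"k": 20},
    "degradation": {"n_reps": 100},
}

#: Scaled-down profile for demos and smoke runs.
DEMO_CONFIG: dict = {
    **DEFAULT_CONFIG,
    "synthetic": {
        "n_samples": 60,
        "n_taxa": 20,
        "graph_model": "band",
        "edge_density": 0.1,
        "condition_target": 100.0,
        "depth_range": [2000, 10000],
        "mdm_fraction_by_rank": [0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.9],
    },
    "ranks": ["phylum", "genus"],
    "filter": {**DEFAULT_CONFIG["filter"], "min_samples": 2},
    "bootstrap": {"B": 200, "alpha": 0.05, "reuse_penalty": True},
    "degradation": {"n_reps": 25},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seeds(master: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(master).spawn(n)
    ]


def run_pipeline(config: dict, base_config: dict | None = None) -> dict:
    """Execute the full pipeline and write artifacts under ``outdir``.

    ``config`` is merged over :data:`DEFAULT_CONFIG` (or ``base_config``).
    Either a ``synthetic`` block or an ``input`` block (abundance +
    taxonomy paths) must be present. Returns the run manifest.
    """
    cfg = _merge(base_config or DEFAULT_CONFIG, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg["seed"])
    seed_sim, seed_net, seed_boot, seed_null = _child_seeds(master_seed, 4)
    manifest: dict = {
        "tool": "umbranet",
        "version": __version__,
        "config": cfg,
        "seeds": {
            "master": master_seed,
            "simulate": seed_sim,
            "network": seed_net,
            "bootstrap": seed_boot,
            "null": seed_null,
        },
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "artifacts": {},
    }

    def _record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _digest(path),
        }

    # -- stage: obtain data ---------------------------------------------
    stage = "load"
    try:
        if "synthetic" in cfg:
            spec = SyntheticSpec(
                n_samples=cfg["synthetic"]["n_samples"],
                n_taxa=cfg["synthetic"]["n_taxa"],
                graph_model=cfg["synthetic"].get("graph_model", "band"),
                edge_density=cfg["synthetic"].get("edge_density", 0.1),
                condition_target=cfg["synthetic"].get("condition_target", 100.0),
                depth_range=tuple(cfg["synthetic"].get("depth_range", (2000, 10000))),
                mdm_fraction_by_rank=tuple(
                    cfg["synthetic"].get(
                        "mdm_fraction_by_rank", (0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 0.9)
                    )
                ),
                seed=seed_sim,
            )
            table, truth = generate_dataset(spec)
            taxonomy_raw = list(truth.taxonomy)
            write_abundance(table, outdir / "abundance.tsv")
            _record("abundance", outdir / "abundance.tsv")
            write_taxonomy(taxonomy_raw, outdir / "taxonomy.tsv")
            _record("taxonomy", outdir / "taxonomy.tsv")
            with open(outdir / "true_edges.tsv", "w") as fh:
                fh.write("node_i\tnode_j\n")
                for i, j in sorted(truth.true_edges):
                    fh.write(f"{i}\t{j}\n")
            _record("true_edges", outdir / "true_edges.tsv")
        elif "input" in cfg:
            table = read_abundance(
                cfg["input"]["abundance"],
                format=cfg["input"].get("format", "tsv"),
                orientation=cfg["input"].get("orientation"),
            )
            taxonomy_raw = read_taxonomy(cfg["input"]["taxonomy"])
        else:
            raise ValueError("config needs a 'synthetic' or 'input' block")
        manifest["stages"][stage] = {
            "n_samples": table.n_samples,
            "n_taxa": table.n_taxa,
        }
    except Exception:
        logger.exception("stage %r failed", stage)
        raise

    # -- stage: relabel + filter ----------------------------------------
    stage = "relabel_filter"
    try:
        keywords = frozenset(cfg["mdm_keywords"])
        taxonomy = {
            rec.taxon_id: relabel_mdm(rec, keywords) for rec in taxonomy_raw
        }
        fcfg = FilterConfig(
            min_samples=int(cfg["filter"]["min_samples"]),
            exclude_domains=frozenset(cfg["filter"]["exclude_domains"]),
            chloroplast_ranks=frozenset(cfg["filter"]["chloroplast_ranks"]),
        )
        table = filter_taxa(table, taxonomy, fcfg)
        manifest["stages"][stage] = {
            "n_taxa_retained": table.n_taxa,
            "prevalence_percent": fcfg.prevalence_percent(table.n_samples),
        }
    except Exception:
        logger.exception("stage %r failed", stage)
        raise

    # -- per-rank analysis ----------------------------------------------
    net_cfg = cfg["network"]
    boot_cfg = cfg["bootstrap"]
    for rank in cfg["ranks"]:
        rank_dir = outdir / rank
        rank_dir.mkdir(exist_ok=True)
        stage = f"{rank}:aggregate"
        try:
            agg_table, meta = aggregate_to_rank(table, taxonomy, rank)
            meta.to_csv(rank_dir / "nodes.tsv", sep="\t")
            _record(f"{rank}/nodes", rank_dir / "nodes.tsv")
        except Exception:
            logger.exception("stage %r failed", stage)
            raise

        stage = f"{rank}:infer"
        try:
            clr = clr_transform(agg_table, net_cfg["pseudocount"])
            path = default_penalty_path(
                clr, length=net_cfg["path_length"], min_ratio=net_cfg["path_min_ratio"]
            )
            model = CooccurrenceNetworkModel(
                agg_table, pseudocount=net_cfg["pseudocount"]
            )
            res = model.fit(
                penalty_path=path,
                n_subsamples=net_cfg["n_subsamples"],
                subsample_ratio=net_cfg["subsample_ratio"],
                instability_threshold=net_cfg["instability_threshold"],
                rule=net_cfg["rule"],
                seed=seed_net,
            )
            res.instability_curve.to_csv(
                rank_dir / "instability.tsv", sep="\t", index=False
            )
            _record(f"{rank}/instability", rank_dir / "instability.tsv")
            write_network(
                res.network,
                graphml_path=rank_dir / "network.graphml",
                edgelist_path=rank_dir / "network_edges.tsv",
            )
            _record(f"{rank}/network", rank_dir / "network_edges.tsv")
            manifest["stages"][stage] = {
                "selected_penalty": res.selected_penalty,
                "n_edges": res.network.n_edges,
            }
        except Exception:
            logger.exception("stage %r failed", stage)
            raise

        stage = f"{rank}:bootstrap"
        try:
            filtered = res.bootstrap_filter(
                B=int(boot_cfg["B"]),
                alpha=float(boot_cfg["alpha"]),
                reuse_penalty=bool(boot_cfg["reuse_penalty"]),
                seed=seed_boot,
            )
            write_edge_supports(res.edge_supports, rank_dir / "edge_supports.tsv")
            _record(f"{rank}/edge_supports", rank_dir / "edge_supports.tsv")
            write_network(
                filtered,
                graphml_path=rank_dir / "filtered_network.graphml",
                edgelist_path=rank_dir / "filtered_network_edges.tsv",
            )
            _record(f"{rank}/filtered_network", rank_dir / "filtered_network_edges.tsv")
            manifest["stages"][stage] = {"n_edges_filtered": filtered.n_edges}
        except Exception:
            logger.exception("stage %r failed", stage)
            raise

        stage = f"{rank}:hubs"
        try:
            scores = hub_scores(filtered) if filtered.n_edges else None
            prof = centrality_profile(filtered)
            prof.to_csv(rank_dir / "centrality.tsv", sep="\t")
            _record(f"{rank}/centrality", rank_dir / "centrality.tsv")
            if scores is not None:
                node_tax = {
                    node: TaxonomyRecord(
                        taxon_id=node,
                        ranks=_node_ranks(meta, node),
                        mdm_flags=_node_flags(meta, node),
                    )
                    for node in filtered.nodes
                }
                hub_table, mdm_counts = top_hubs(
                    scores, taxonomy=node_tax, k=int(cfg["hubs"]["k"])
                )
                hub_table.to_csv(rank_dir / "top_hubs.tsv", sep="\t", index=False)
                _record(f"{rank}/top_hubs", rank_dir / "top_hubs.tsv")
                manifest["stages"][stage] = {"mdm_counts": mdm_counts}
        except Exception:
            logger.exception("stage %r failed", stage)
            raise

        stage = f"{rank}:degradation"
        try:
            mdm_nodes = meta.index[meta["is_mdm"]].tolist()
            mdm_nodes = [v for v in mdm_nodes if v in set(filtered.nodes)]
            known = [v for v in filtered.nodes if v not in set(mdm_nodes)]
            if len(known) < len(mdm_nodes):
                manifest["stages"][stage] = {
                    "skipped": "fewer known than MDM nodes; null undefined"
                }
            else:
                no_mdm = remove_nodes(filtered, mdm_nodes)
                nulls = random_known_removal_null(
                    filtered,
                    mdm_nodes,
                    n_reps=int(cfg["degradation"]["n_reps"]),
                    seed=seed_null,
                )
                report = build_report(filtered, no_mdm, nulls, rank=rank)
                (rank_dir / "degradation.json").write_text(report.to_json())
                _record(f"{rank}/degradation", rank_dir / "degradation.json")
                report.to_long_frame().to_csv(
                    rank_dir / "degradation_long.tsv", sep="\t", index=False
                )
                _record(f"{rank}/degradation_long", rank_dir / "degradation_long.tsv")
                manifest["stages"][stage] = {
                    "n_removed": report.n_removed,
                    "stars": {f"{m}:{p}": s for (m, p), s in report.stars.items()},
                }
        except Exception:
            logger.exception("stage %r failed", stage)
            raise

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest


def _node_ranks(meta, node) -> tuple[str, ...]:
    rank_cols = [
        c
        for c in ("domain", "phylum", "class", "order", "family", "genus", "species")
        if c in meta.columns
    ]
    labels = [str(meta.loc[node, c]) for c in rank_cols]
    return tuple((labels + [""] * 7)[:7])


def _node_flags(meta, node) -> tuple[bool, ...]:
    flag = bool(meta.loc[node, "is_mdm"])
    depth = len(
        [
            c
            for c in ("domain", "phylum", "class", "order", "family", "genus", "species")
            if c in meta.columns
        ]
    )
    flags = [False] * 7
    if flag:
        flags[depth - 1] = True
    return tuple(flags)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
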
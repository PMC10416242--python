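"""Taxonomy handling: microbial dark matter (MDM) relabeling, taxon
filtering, rank aggregation and cross-dataset comparison.

A lineage is a seven-rank tuple (domain, phylum, class, order, family,
genus, species), SILVA/QIIME2 style, optionally carrying ``d__``-type
prefixes. Taxa whose label at some rank matches an "unknown" keyword
("uncultured", "unknown", "NA", "Incertae Sedis", ...) are re-classified
as microbial dark matter at that rank and every rank below it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

from .abundance import AbundanceTable

__all__ = [
    "RANKS",
    "MDM_LABEL",
    "DEFAULT_MDM_KEYWORDS",
    "TaxonomyRecord",
    "FilterConfig",
    "relabel_mdm",
    "filter_taxa",
    "aggregate_to_rank",
    "compare_datasets",
]

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Label written onto every rank flagged as microbial dark matter.
MDM_LABEL = "MDM"

#: Default keyword vocabulary marking an unassigned/unknown classification.
#: The vocabulary is explicitly open-ended and user-extensible.
DEFAULT_MDM_KEYWORDS: frozenset[str] = frozenset(
    {
        "uncultured",
        "unknown",
        "unidentified",
        "NA",
        "unknown_family",
        "Incertae Sedis",
        "metagenome",
        "",
    }
)

_RANK_PREFIXES = tuple(f"{r[0]}__" for r in RANKS)  # d__, p__, c__, o__, f__, g__, s__


def _normalize_label(label: str) -> str:
    """Strip a QIIME2 rank prefix and normalize for keyword matching."""
    s = label.strip()
    for p in _RANK_PREFIXES:
        if s.startswith(p):
            s = s[len(p):]
            break
    return s.strip().replace("_", " ").lower()


def _label_is_mdm(label: str, keywords: frozenset[str]) -> bool:
    norm = _normalize_label(label)
    for kw in keywords:
        kw_norm = kw.strip().replace("_", " ").lower()
        # Very short keywords ("NA", empty label) are matched exactly:
        # substring matching would flag e.g. "Cyanobacteria".
        if len(kw_norm) <= 2:
            if norm == kw_norm:
                return True
        elif kw_norm in norm:
            return True
    return False


@dataclass(frozen=True)
class TaxonomyRecord:
    """One taxon's seven-rank lineage with per-rank MDM flags.

    After :func:`relabel_mdm` the flags are downward monotone: once a
    rank is flagged, every rank below it is flagged too, and flagged
    ranks carry the label :data:`MDM_LABEL`.
    """

    taxon_id: str
    ranks: tuple[str, str, str, str, str, str, str]
    mdm_flags: tuple[bool, bool, bool, bool, bool, bool, bool] = (False,) * 7

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError("a lineage has exactly 7 ranks")
        if len(self.mdm_flags) != 7:
            raise ValueError("mdm_flags has exactly 7 entries")

    def label(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def is_mdm_at(self, rank: str) -> bool:
        return self.mdm_flags[RANKS.index(rank)]

    def display_ranks(self) -> tuple[str, ...]:
        """Labels with rank prefixes stripped (MDM labels pass through)."""
        out = []
        for lbl in self.ranks:
            s = lbl.strip()
            for p in _RANK_PREFIXES:
                if s.startswith(p):
                    s = s[len(p):]
                    break
            out.append(s.strip())
        return tuple(out)


@dataclass(frozen=True)
class FilterConfig:
    """Prevalence / lineage filtering rules applied before network inference.

    ``min_samples`` is the prevalence threshold (a taxon must be present,
    i.e. nonzero, in at least this many samples). ``exclude_domains``
    removes whole domains (eukaryotes by default, to focus comparisons on
    the prokaryotic community). A "Chloroplast" label on any rank in
    ``chloroplast_ranks`` removes organellar sequences.
    """

    min_samples: int = 2
    exclude_domains: frozenset[str] = frozenset({"Eukaryota"})
    chloroplast_ranks: frozenset[str] = frozenset({"order", "family", "genus"})

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        unknown = set(self.chloroplast_ranks) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks in chloroplast_ranks: {sorted(unknown)}")

    def prevalence_percent(self, n_samples_total: int, ndigits: int = 1) -> float:
        """The prevalence threshold as a percentage of the sample count.

        E.g. a threshold of 15 out of 24 samples is 62.5%.
        """
        if n_samples_total < 1:
            raise ValueError("n_samples_total must be >= 1")
        return round(100.0 * self.min_samples / n_samples_total, ndigits)


def relabel_mdm(
    record: TaxonomyRecord,
    keyword_set: frozenset[str] | set[str] = DEFAULT_MDM_KEYWORDS,
) -> TaxonomyRecord:
    """Re-classify a lineage as microbial dark matter with downward propagation.

    The first rank (from domain downwards) whose label matches any keyword
    — case-insensitive, prefix-stripped; short keywords like "NA" matched
    exactly, longer ones as substrings — and every rank below it receive
    the label ``"MDM"`` and a True flag. Higher ranks are untouched.

    A taxon flagged "unknown" at the order level therefore becomes MDM at
    the order, family, genus and species levels.
    """
    if not keyword_set:
        raise ValueError("keyword_set must not be empty")
    kws = frozenset(keyword_set)
    first = None
    for i, lbl in enumerate(record.ranks):
        if _label_is_mdm(lbl, kws):
            first = i
            break
    if first is None:
        return replace(record, mdm_flags=(False,) * 7)
    labels = list(record.ranks)
    flags = [False] * 7
    for i in range(first, 7):
        labels[i] = MDM_LABEL
        flags[i] = True
    return replace(record, ranks=tuple(labels), mdm_flags=tuple(flags))


def _taxonomy_index(taxonomy) -> dict[str, TaxonomyRecord]:
    if isinstance(taxonomy, dict):
        return taxonomy
    return {rec.taxon_id: rec for rec in taxonomy}


def filter_taxa(
    table: AbundanceTable,
    taxonomy,
    config: FilterConfig = FilterConfig(),
) -> AbundanceTable:
    """Apply prevalence, domain-exclusion and chloroplast rules.

    Retains exactly the taxa with nonzero abundance in at least
    ``config.min_samples`` samples, whose domain is not excluded, and
    which carry no "Chloroplast" label on the configured ranks. The
    sample set is unchanged. Idempotent.
    """
    tax = _taxonomy_index(taxonomy)
    missing = [t for t in table.taxon_ids if t not in tax]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing}")
    prevalence = table.prevalence()
    keep = []
    chloro_idx = [RANKS.index(r) for r in config.chloroplast_ranks]
    excl = {d.lower() for d in config.exclude_domains}
    for t in table.taxon_ids:
        rec = tax[t]
        disp = rec.display_ranks()
        if prevalence[t] < config.min_samples:
            continue
        if disp[0].lower() in excl:
            continue
        if any("chloroplast" in disp[i].lower() for i in chloro_idx):
            continue
        keep.append(t)
    return AbundanceTable(table.data.loc[:, keep].copy())


def aggregate_to_rank(
    table: AbundanceTable,
    taxonomy,
    rank: str,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Sum taxa sharing the identical lineage prefix down to ``rank``.

    Node identity is the full prefix of (display) labels from domain down
    to ``rank``, so an MDM label does not merge across distinct known
    parents: "Proteobacteria;MDM" and "Cyanobacteria;MDM" are distinct
    genus-level nodes. Total counts are conserved exactly.

    Returns the aggregated table plus a lineage map indexed by node id
    with one column per retained rank and an ``is_mdm`` flag (MDM at
    ``rank``).
    """
    if rank not in RANKS[1:-1]:
        raise ValueError(
            f"rank must be one of {RANKS[1:-1]}, got {rank!r}"
        )
    tax = _taxonomy_index(taxonomy)
    missing = [t for t in table.taxon_ids if t not in tax]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing}")
    depth = RANKS.index(rank) + 1
    groups: dict[tuple[str, ...], list[str]] = {}
    for t in table.taxon_ids:
        prefix = tax[t].display_ranks()[:depth]
        groups.setdefault(prefix, []).append(t)
    node_ids = [";".join(prefix) for prefix in groups]
    agg = pd.DataFrame(
        {
            node_id: table.data.loc[:, members].sum(axis=1)
            for node_id, members in zip(node_ids, groups.values())
        },
        index=table.data.index,
    )
    meta = pd.DataFrame(
        [
            {
                **dict(zip(RANKS[:depth], prefix)),
                "is_mdm": tax[members[0]].is_mdm_at(rank),
                "n_members": len(members),
            }
            for prefix, members in groups.items()
        ],
        index=pd.Index(node_ids, name="node"),
    )
    return AbundanceTable(agg), meta


def compare_datasets(taxonomy_sets: dict[str, list], rank: str) -> dict:
    """Cross-dataset comparison of known classifications at one rank.

    For each distinct known (non-MDM) label at ``rank``, determines which
    datasets contain it, and returns upset-style intersection counts plus
    per-dataset unique counts.

    Returns a dict with keys ``intersections`` (mapping a tuple of sorted
    dataset names to the count of labels found in exactly those datasets),
    ``unique`` (dataset -> count of labels found only there) and
    ``labels`` (the label membership itself).
    """
    if len(taxonomy_sets) < 2:
        raise ValueError("need at least two datasets to compare")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    label_sets: dict[str, set[str]] = {}
    for name, records in taxonomy_sets.items():
        labels = set()
        for rec in records:
            if not rec.is_mdm_at(rank):
                lbl = rec.display_ranks()[RANKS.index(rank)]
                if lbl and lbl != MDM_LABEL:
                    labels.add(lbl)
        label_sets[name] = labels
    membership: dict[str, tuple[str, ...]] = {}
    for lbl in set().union(*label_sets.values()):
        member_of = tuple(sorted(n for n, s in label_sets.items() if lbl in s))
        membership[lbl] = member_of
    intersections: dict[tuple[str, ...], int] = {}
    names = sorted(label_sets)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            intersections[combo] = 0
    for member_of in membership.values():
        intersections[member_of] += 1
    unique = {n: intersections[(n,)] for n in names}
    return {"intersections": intersections, "unique": unique, "labels": membership}
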
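import numpy as np
import pandas as pd
import pytest

from umbranet import AbundanceTable, AssociationNetwork, TaxonomyRecord


def make_network(nodes, edges, **kwargs) -> AssociationNetwork:
    """Construct a network from an iterable of (i, j) pairs."""
    return AssociationNetwork(
        nodes=list(nodes),
        edges={(i, j) if i <= j else (j, i) for i, j in edges},
        **kwargs,
    )


def clean_record(taxon_id="t1", **overrides) -> TaxonomyRecord:
    ranks = dict(
        domain="Bacteria",
        phylum="Proteobacteria",
        class_="Alphaproteobacteria",
        order="Rhodobacterales",
        family="Rhodobacteraceae",
        genus="Labrenzia",
        species="Labrenzia_sp",
    )
    ranks.update(overrides)
    order = ["domain", "phylum", "class_", "order", "family", "genus", "species"]
    return TaxonomyRecord(taxon_id=taxon_id, ranks=tuple(ranks[k] for k in order))


@pytest.fixture
def small_table() -> AbundanceTable:
    """4 samples x 4 taxa with prevalences (1, 2, 3, 0)."""
    df = pd.DataFrame(
        {
            "t1": [5, 0, 0, 0],
            "t2": [3, 2, 0, 0],
            "t3": [1, 1, 1, 0],
            "t4": [0, 0, 0, 0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return AbundanceTable(df)


@pytest.fixture
def small_taxonomy(small_table):
    return {t: clean_record(taxon_id=t) for t in small_table.taxon_ids}


@pytest.fixture
def path3() -> AssociationNetwork:
    return make_network(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def star4() -> AssociationNetwork:
    return make_network(
        ["hub", "l1", "l2", "l3"], [("hub", "l1"), ("hub", "l2"), ("hub", "l3")]
    )
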
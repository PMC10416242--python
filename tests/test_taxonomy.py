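"""MDM relabeling, filtering, aggregation and cross-dataset comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umbranet import (
    AbundanceTable,
    DEFAULT_MDM_KEYWORDS,
    FilterConfig,
    MDM_LABEL,
    RANKS,
    TaxonomyRecord,
    aggregate_to_rank,
    compare_datasets,
    filter_taxa,
    relabel_mdm,
)
from conftest import clean_record


class TestRelabelMDM:
    def test_unknown_at_order_propagates_downward(self):
        """An 'unknown' order becomes MDM at order, family, genus, species."""
        rec = relabel_mdm(clean_record(order="unknown"))
        assert rec.mdm_flags == (False, False, False, True, True, True, True)
        assert rec.ranks[3:] == (MDM_LABEL,) * 4
        assert rec.ranks[:3] == ("Bacteria", "Proteobacteria", "Alphaproteobacteria")

    def test_clean_lineage_unchanged(self):
        rec = clean_record()
        out = relabel_mdm(rec)
        assert out.mdm_flags == (False,) * 7
        assert out.ranks == rec.ranks

    def test_na_domain_flags_everything(self):
        rec = relabel_mdm(clean_record(domain="NA"))
        assert rec.mdm_flags == (True,) * 7
        assert rec.ranks == (MDM_LABEL,) * 7

    @pytest.mark.parametrize(
        "label",
        ["uncultured", "Uncultured bacterium", "d__unknown", "Incertae Sedis",
         "Rhizobiales_Incertae_Sedis", "unknown_family", "", "marine metagenome"],
    )
    def test_keyword_variants_match(self, label):
        rec = relabel_mdm(clean_record(genus=label))
        assert rec.is_mdm_at("genus") and rec.is_mdm_at("species")
        assert not rec.is_mdm_at("family")

    def test_na_is_not_substring_matched(self):
        """'NA' must not flag labels merely containing 'na'."""
        rec = relabel_mdm(clean_record(phylum="Cyanobacteria", genus="Anabaena"))
        assert rec.mdm_flags == (False,) * 7

    def test_empty_keyword_set_rejected(self):
        with pytest.raises(ValueError):
            relabel_mdm(clean_record(), keyword_set=frozenset())

    def test_prefix_stripped_before_matching(self):
        rec = relabel_mdm(clean_record(species="s__uncultured organism"))
        assert rec.is_mdm_at("species")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        flags=st.lists(st.booleans(), min_size=7, max_size=7),
        kw=st.sampled_from(sorted(DEFAULT_MDM_KEYWORDS - {""})),
    )
    def test_flags_downward_monotone(self, flags, kw):
        """After relabeling, a flagged rank implies all lower ranks flagged."""
        labels = tuple(kw if f else f"Clade{i}x" for i, f in enumerate(flags))
        rec = relabel_mdm(TaxonomyRecord(taxon_id="t", ranks=labels))
        out = rec.mdm_flags
        for i in range(6):
            assert not (out[i] and not out[i + 1])
        if any(flags):
            assert out[min(i for i, f in enumerate(flags) if f)]


class TestFilterTaxa:
    def test_prevalence_rule(self, small_table, small_taxonomy):
        out = filter_taxa(small_table, small_taxonomy, FilterConfig(min_samples=2))
        assert out.taxon_ids == ["t2", "t3"]
        assert out.sample_ids == small_table.sample_ids

    def test_eukaryote_domain_removed(self, small_table, small_taxonomy):
        small_taxonomy["t3"] = clean_record(taxon_id="t3", domain="Eukaryota")
        out = filter_taxa(small_table, small_taxonomy, FilterConfig(min_samples=2))
        assert out.taxon_ids == ["t2"]

    def test_chloroplast_rank_scope(self, small_table, small_taxonomy):
        small_taxonomy["t3"] = clean_record(taxon_id="t3", order="Chloroplast")
        cfg_on = FilterConfig(min_samples=2)
        assert "t3" not in filter_taxa(small_table, small_taxonomy, cfg_on).taxon_ids
        cfg_restricted = FilterConfig(
            min_samples=2, chloroplast_ranks=frozenset({"family", "genus"})
        )
        assert "t3" in filter_taxa(small_table, small_taxonomy, cfg_restricted).taxon_ids

    def test_missing_taxonomy_is_hard_error(self, small_table, small_taxonomy):
        del small_taxonomy["t2"]
        with pytest.raises(KeyError, match="t2"):
            filter_taxa(small_table, small_taxonomy)

    def test_idempotent(self, small_table, small_taxonomy):
        cfg = FilterConfig(min_samples=2)
        once = filter_taxa(small_table, small_taxonomy, cfg)
        twice = filter_taxa(once, small_taxonomy, cfg)
        assert once == twice

    @pytest.mark.parametrize(
        "min_samples,total,expected", [(15, 24, 62.5), (34, 55, 61.8), (2, 14, 14.3)]
    )
    def test_prevalence_percent(self, min_samples, total, expected):
        cfg = FilterConfig(min_samples=min_samples)
        assert cfg.prevalence_percent(total) == expected


class TestAggregateToRank:
    def _taxonomy(self):
        return {
            "t1": clean_record(taxon_id="t1", class_="ClassA"),
            "t2": clean_record(taxon_id="t2", class_="ClassB"),
        }

    def _table(self):
        df = pd.DataFrame({"t1": [4, 1], "t2": [2, 3]}, index=["s1", "s2"])
        return AbundanceTable(df)

    def test_same_phylum_merges(self):
        agg, meta = aggregate_to_rank(self._table(), self._taxonomy(), "phylum")
        assert agg.n_taxa == 1
        np.testing.assert_array_equal(agg.counts().ravel(), [6, 4])

    def test_mdm_distinct_under_different_parents(self):
        tax = {
            "t1": relabel_mdm(clean_record(taxon_id="t1", phylum="Proteobacteria", genus="unknown")),
            "t2": relabel_mdm(clean_record(taxon_id="t2", phylum="Cyanobacteria", genus="unknown")),
        }
        agg, meta = aggregate_to_rank(self._table(), tax, "genus")
        assert agg.n_taxa == 2
        assert meta["is_mdm"].all()

    def test_total_counts_conserved(self):
        table = self._table()
        for rank in ("phylum", "class", "order", "family", "genus"):
            agg, _ = aggregate_to_rank(table, self._taxonomy(), rank)
            assert agg.counts().sum() == table.counts().sum()

    def test_species_rank_rejected(self):
        with pytest.raises(ValueError):
            aggregate_to_rank(self._table(), self._taxonomy(), "species")
        with pytest.raises(ValueError):
            aggregate_to_rank(self._table(), self._taxonomy(), "domain")


def brute_force_memberships(sets):
    """Independent set-algebra oracle: label -> sorted tuple of owners."""
    out = {}
    for lbl in set().union(*sets.values()):
        out[lbl] = tuple(sorted(n for n, s in sets.items() if lbl in s))
    return out


class TestCompareDatasets:
    @staticmethod
    def _records(name, labels):
        return [
            clean_record(taxon_id=f"{name}{i}", phylum=lbl)
            for i, lbl in enumerate(labels)
        ]

    def test_two_sets_enumeration(self):
        sets = {"A": self._records("a", ["X", "Y"]), "B": self._records("b", ["Y", "Z"])}
        out = compare_datasets(sets, "phylum")
        assert out["intersections"][("A", "B")] == 1
        assert out["intersections"][("A",)] == 1
        assert out["intersections"][("B",)] == 1
        assert out["unique"] == {"A": 1, "B": 1}

    def test_identical_sets_all_shared(self):
        sets = {
            "A": self._records("a", ["X", "Y"]),
            "B": self._records("b", ["X", "Y"]),
            "C": self._records("c", ["X", "Y"]),
        }
        out = compare_datasets(sets, "phylum")
        assert out["intersections"][("A", "B", "C")] == 2
        assert all(v == 0 for k, v in out["intersections"].items() if len(k) < 3)

    def test_three_sets_match_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        pool = [f"P{i}" for i in range(12)]
        raw = {
            name: set(rng.choice(pool, size=rng.integers(3, 9), replace=False))
            for name in ("A", "MG", "MT")
        }
        shared = "CorePhylum"
        for s in raw.values():
            s.add(shared)
        sets = {n: self._records(n.lower(), sorted(s)) for n, s in raw.items()}
        out = compare_datasets(sets, "phylum")
        oracle = brute_force_memberships(raw)
        for subset, count in out["intersections"].items():
            expected = sum(1 for owners in oracle.values() if owners == subset)
            assert count == expected
        assert out["labels"][shared] == ("A", "MG", "MT")

    def test_mdm_labels_excluded(self):
        sets = {
            "A": [relabel_mdm(clean_record(taxon_id="a1", phylum="unknown"))],
            "B": [relabel_mdm(clean_record(taxon_id="b1", phylum="unknown"))],
        }
        out = compare_datasets(sets, "phylum")
        assert all(v == 0 for v in out["intersections"].values())

    def test_requires_two_datasets(self):
        with pytest.raises(ValueError):
            compare_datasets({"A": []}, "phylum")
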
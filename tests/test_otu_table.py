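"""OTU table data model, I/O, taxonomic/rare-OTU filters and rarefaction."""

import json

import numpy as np
import pytest
from scipy.stats import hypergeom

from melibiome.otu_table import (
    CHLOROPLAST_RULES,
    MITOCHONDRIA_RULES,
    UNASSIGNED,
    WOLBACHIA_RULES,
    OtuTable,
    OtuTableError,
    SampleMetadata,
    SampleType,
    TaxonRule,
    TaxonomyLineage,
    filter_rare_otus,
    filter_taxa,
    rarefy,
    read_metadata,
    read_otu_table,
    relative_abundance,
    write_metadata,
    write_otu_table,
)
from conftest import make_table


class TestTaxonomyLineage:
    @pytest.mark.parametrize(
        "raw",
        [
            "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__Rickettsiaceae; g__Wolbachia",
            "k__Bacteria; p__Cyanobacteria; c__Chloroplast",
            "Unassigned",
            "k__Bacteria",
            "",
        ],
    )
    def test_round_trip(self, raw):
        assert TaxonomyLineage.parse(raw).serialize() == raw

    def test_rank_lookup(self):
        lin = TaxonomyLineage.parse("k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales")
        assert lin.name_at("order") == "Lactobacillales"
        assert lin.name_at("genus") is None

    def test_out_of_order_ranks_rejected(self):
        with pytest.raises(OtuTableError, match="order"):
            TaxonomyLineage.parse("p__Proteobacteria; k__Bacteria")

    @pytest.mark.parametrize(
        "raw,expected",
        [("", True), ("Unassigned", True), ("k__Bacteria", True),
         ("k__Bacteria; p__Firmicutes", False)],
    )
    def test_unassigned_definition(self, raw, expected):
        assert TaxonomyLineage.parse(raw).is_unassigned is expected


class TestReadWrite:
    def test_tsv_shape_and_round_trip(self, tmp_path, small_table):
        path = tmp_path / "table.tsv"
        write_otu_table(small_table, path)
        back = read_otu_table(path, format="tsv")
        assert back.counts.shape == (3, 4)
        np.testing.assert_array_equal(back.counts, small_table.counts)
        assert back.sample_ids == small_table.sample_ids
        assert back.otu_ids == small_table.otu_ids
        assert [t.raw for t in back.taxonomy] == [t.raw for t in small_table.taxonomy]

    def test_duplicate_sample_column_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#OTU_ID\tsampA\tsampA\ttaxonomy\n"
            "otu1\t3\t4\tk__Bacteria; p__Firmicutes\n"
        )
        with pytest.raises(OtuTableError, match="sampA"):
            read_otu_table(path)

    def test_non_integer_cell_locates_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#OTU_ID\ts1\ttaxonomy\notu1\t3.7\tk__Bacteria; p__Firmicutes\n"
        )
        with pytest.raises(OtuTableError, match="otu1.*s1"):
            read_otu_table(path)

    def test_biom_json_sparse(self, tmp_path, small_table):
        doc = {
            "format": "Biological Observation Matrix 1.0",
            "matrix_type": "sparse",
            "shape": [4, 3],  # OTUs x samples on disk
            "rows": [
                {"id": o, "metadata": {"taxonomy": t.raw}}
                for o, t in zip(small_table.otu_ids, small_table.taxonomy)
            ],
            "columns": [{"id": s} for s in small_table.sample_ids],
            "data": [
                [j, i, int(small_table.counts[i, j])]
                for i in range(3)
                for j in range(4)
                if small_table.counts[i, j]
            ],
        }
        path = tmp_path / "t.biom"
        path.write_text(json.dumps(doc))
        back = read_otu_table(path, format="biom_json")
        np.testing.assert_array_equal(back.counts, small_table.counts)
        assert back.sample_ids == small_table.sample_ids

    def test_metadata_round_trip(self, tmp_path):
        records = [
            SampleMetadata("fr1", SampleType.FRASS, age_days=15, weight_mg=5.2,
                           survived_15d=True, family_id="fam01"),
            SampleMetadata("pl1", SampleType.PLANT_EPIPHYTE),
        ]
        path = tmp_path / "meta.tsv"
        write_metadata(records, path)
        back = read_metadata(path)
        assert back[0].weight_mg == pytest.approx(5.2)
        assert back[0].survived_15d is True
        assert back[1].age_days is None and back[1].weight_mg is None

    def test_plant_sample_with_age_rejected(self):
        with pytest.raises(OtuTableError, match="plant"):
            SampleMetadata("p", SampleType.PLANT_ENDOPHYTE, age_days=15)

    def test_frass_sample_requires_age(self):
        with pytest.raises(OtuTableError, match="age"):
            SampleMetadata("f", SampleType.FRASS)


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(OtuTableError, match="negative"):
            make_table([[1, -2]])

    def test_duplicate_otu_id_rejected(self):
        with pytest.raises(OtuTableError, match="dup"):
            make_table([[1, 2]], otu_ids=["dup", "dup"])

    def test_taxonomy_length_must_match(self):
        with pytest.raises(OtuTableError, match="taxonomy"):
            make_table([[1, 2]], lineages=["k__Bacteria; p__Firmicutes"])


CHLORO = "k__Bacteria; p__Cyanobacteria; c__Chloroplast; o__Streptophyta"
MITO = "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__mitochondria"
WOLB = "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__Rickettsiaceae; g__Wolbachia"
BACT = "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; g__Lactococcus"


class TestFilterTaxa:
    def test_wolbachia_genus_match(self):
        t = make_table([[1, 2, 3]], lineages=[WOLB, BACT, BACT])
        out = filter_taxa(t, WOLBACHIA_RULES)
        assert out.n_otus == 2 and "otu0" not in out.otu_ids

    def test_wolbachia_order_fallback_without_genus(self):
        # genus rank absent: falls back to order Rickettsiales
        rick_no_genus = "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales"
        t = make_table([[1, 2]], lineages=[rick_no_genus, BACT])
        assert filter_taxa(t, WOLBACHIA_RULES).n_otus == 1

    def test_no_match_is_identity(self, small_table):
        out = filter_taxa(small_table, [TaxonRule("genus", "Nothing")])
        np.testing.assert_array_equal(out.counts, small_table.counts)
        assert out.otu_ids == small_table.otu_ids

    def test_host_dna_fixture_leaves_five(self):
        # 2 chloroplast + 1 mitochondrial + 5 bacterial -> 5 remain
        lineages = [CHLORO, BACT, CHLORO, MITO, BACT, BACT, BACT, BACT]
        t = make_table([list(range(1, 9))], lineages=lineages)
        out = filter_taxa(t, [*CHLOROPLAST_RULES, *MITOCHONDRIA_RULES])
        assert out.n_otus == 5
        assert out.otu_ids == ["otu1", "otu4", "otu5", "otu6", "otu7"]  # order preserved

    def test_unassigned_rule(self):
        t = make_table([[1, 2, 3]], lineages=["Unassigned", "k__Bacteria", BACT])
        assert filter_taxa(t, [UNASSIGNED]).n_otus == 1

    def test_all_removed_is_error(self):
        t = make_table([[1]], lineages=[WOLB])
        with pytest.raises(OtuTableError, match="every OTU"):
            filter_taxa(t, WOLBACHIA_RULES)

    def test_idempotent(self, small_table):
        rules = [TaxonRule("genus", "Taxon0")]
        once = filter_taxa(small_table, rules)
        twice = filter_taxa(once, rules)
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_zero_sum_samples_retained(self):
        t = make_table([[5, 0], [0, 3]], lineages=[BACT, WOLB])
        out = filter_taxa(t, WOLBACHIA_RULES)
        assert out.n_samples == 2
        assert out.sample_sums().tolist() == [5, 0]


class TestFilterRareOtus:
    def test_retained_if_above_threshold_anywhere(self):
        # 2% in one sample, 0% elsewhere -> retained at the 1% threshold
        t = make_table([[2, 98], [0, 100]])
        out = filter_rare_otus(t, 0.01)
        assert out.n_otus == 2

    def test_removed_if_below_everywhere(self):
        t = make_table([[1, 199], [1, 199]])  # 0.5% in every sample
        out = filter_rare_otus(t, 0.01)
        assert out.otu_ids == ["otu1"]

    def test_zero_threshold_is_identity(self, small_table):
        out = filter_rare_otus(small_table, 0.0)
        np.testing.assert_array_equal(out.counts, small_table.counts)

    def test_zero_sum_sample_warns_not_fails(self):
        t = make_table([[0, 0], [10, 90]])
        with pytest.warns(UserWarning, match="zero total"):
            out = filter_rare_otus(t, 0.01)
        assert out.n_otus == 2

    def test_idempotent(self):
        t = make_table([[2, 98, 0], [0, 100, 1]])
        once = filter_rare_otus(t, 0.01)
        twice = filter_rare_otus(once, 0.01)
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestRarefy:
    def test_row_sums_and_bounds(self):
        t = make_table([[5, 5]])
        out = rarefy(t, 4, seed=0).table
        assert out.counts.sum() == 4
        assert np.all(out.counts <= [5, 5])

    def test_shallow_sample_dropped_and_reported(self):
        t = make_table([[1, 2], [5, 5]], sample_ids=["shallow", "deep"])
        res = rarefy(t, 4, seed=0)
        assert res.dropped_sample_ids == ["shallow"]
        assert res.table.sample_ids == ["deep"]

    def test_exact_depth_retained_unchanged(self):
        t = make_table([[2, 2]])
        res = rarefy(t, 4, seed=0)
        np.testing.assert_array_equal(res.table.counts, [[2, 2]])
        assert res.dropped_sample_ids == []

    def test_zero_category_gets_no_mass(self):
        t = make_table([[1000, 0]])
        out = rarefy(t, 500, seed=1).table
        np.testing.assert_array_equal(out.counts, [[500, 0]])

    def test_all_below_depth_is_error(self):
        t = make_table([[1, 1]])
        with pytest.raises(OtuTableError, match="fewer"):
            rarefy(t, 10, seed=0)

    def test_reproducible_and_sample_keyed_streams(self):
        t = make_table([[30, 20, 10], [15, 25, 5]], sample_ids=["x", "y"])
        a = rarefy(t, 20, seed=42).table
        b = rarefy(t, 20, seed=42).table
        np.testing.assert_array_equal(a.counts, b.counts)
        # dropping one sample must not shift the other's draw
        solo = rarefy(t.select_samples(["y"]), 20, seed=42).table
        np.testing.assert_array_equal(solo.counts[0], a.counts[1])

    def test_hypergeometric_mean(self):
        # mean rarefied count over many seeds matches depth * count / total
        row = np.array([30, 15, 5])
        t = make_table([row])
        depth = 20
        draws = np.array(
            [rarefy(t, depth, seed=s).table.counts[0] for s in range(1000)]
        )
        total = row.sum()
        for j in range(3):
            mean_expected = hypergeom.mean(total, row[j], depth)
            se = hypergeom.std(total, row[j], depth) / np.sqrt(1000)
            assert abs(draws[:, j].mean() - mean_expected) < 3 * se


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5, 0, 0], [0.5, 0.5, 0, 0]), ([2, 2, 3, 3], [0.2, 0.2, 0.3, 0.3])],
    )
    def test_known_values(self, counts, expected):
        t = make_table([counts])
        np.testing.assert_allclose(relative_abundance(t)[0], expected)

    def test_rows_sum_to_one_after_rarefaction(self, small_table):
        rel = relative_abundance(rarefy(small_table, 6, seed=0).table)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0)

    def test_zero_row_names_sample(self):
        t = make_table([[0, 0]], sample_ids=["empty"])
        with pytest.raises(OtuTableError, match="empty"):
            relative_abundance(t)
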
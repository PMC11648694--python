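"""I/O round trips, validation errors, and taxonomy table operations."""

import numpy as np
import pandas as pd
import pytest

from coregrad import (
    FeatureTable,
    FormatError,
    collapse_taxonomy,
    family_composition,
    filter_taxa,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)
from coregrad.data_model import (
    read_distance_matrix,
    write_distance_matrix,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from conftest import make_taxonomy, random_table


class TestFeatureTableIO:
    def test_parse_small_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("feature_id\ts1\ts2\n# a comment\nf1\t3\t0\nf2\t1\t5\n")
        table = read_feature_table(p)
        assert table.feature_ids == ["f1", "f2"]
        assert table.sample_ids == ["s1", "s2"]
        assert table.counts.tolist() == [[3, 0], [1, 5]]

    def test_round_trip(self, tmp_path, small_table):
        p = tmp_path / "t.tsv"
        write_feature_table(small_table, p)
        assert read_feature_table(p) == small_table

    def test_duplicate_sample_column_named(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("feature_id\ts1\ts1\nf1\t3\t0\n")
        with pytest.raises(FormatError, match="s1"):
            read_feature_table(p)

    @pytest.mark.parametrize(
        "body,err",
        [
            ("f1\t-3\t0\n", ValueError),
            ("f1\t3.5\t0\n", ValueError),
            ("f1\t3\n", FormatError),
        ],
    )
    def test_bad_cells_and_ragged_rows(self, tmp_path, body, err):
        p = tmp_path / "t.tsv"
        p.write_text("feature_id\ts1\ts2\n" + body)
        with pytest.raises(err):
            read_feature_table(p)

    def test_negative_counts_rejected_in_constructor(self):
        with pytest.raises(ValueError):
            FeatureTable(pd.DataFrame({"s1": [-1]}, index=["f1"]))


class TestTreeAndMetadataIO:
    def test_newick_round_trip(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        tree = read_tree(p)
        assert sorted(leaf.name for leaf in tree.tips()) == ["A", "B", "C", "D"]
        total = sum(n.length or 0 for n in tree.postorder(include_self=False))
        assert total == pytest.approx(6, abs=1e-9)

    def test_unrooted_tree_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1,C:1);\n")
        with pytest.raises(ValueError, match="rooted"):
            read_tree(p)

    def test_invalid_stage_lists_allowed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample_id\tstage\tsite\tlatitude_deg_n\taltitude_masl\ttransect\n"
            "s1\tadult\tx\t19.0\t100\tlatitudinal\n"
        )
        with pytest.raises(ValueError, match="larva"):
            read_metadata(p)

    def test_metadata_round_trip(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample_id\tstage\tsite\tlatitude_deg_n\taltitude_masl\ttransect\n"
            "s1\tlarva\tx\t19.5\t100\tlatitudinal\n"
            "s2\tpulp\ty\t21.0\t0\taltitudinal\n"
        )
        meta = read_metadata(p)
        p2 = tmp_path / "m2.tsv"
        write_metadata(meta, p2)
        pd.testing.assert_frame_equal(meta, read_metadata(p2))

    def test_partial_lineage_parses(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("f1\tBacteria;Proteobacteria;;;;;\n")
        tax = read_taxonomy(p)
        assert (tax.loc["f1"] != "").sum() == 2

    def test_lineage_gap_rejected(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("f1\tBacteria;;Gammaproteobacteria;;;;\n")
        with pytest.raises(FormatError, match="gap"):
            read_taxonomy(p)

    def test_taxonomy_round_trip(self, tmp_path, small_taxonomy):
        p = tmp_path / "tax.tsv"
        write_taxonomy(small_taxonomy, p)
        pd.testing.assert_frame_equal(read_taxonomy(p), small_taxonomy)

    def test_distance_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        pts = rng.random((5, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        import skbio

        dm = skbio.DistanceMatrix(d, [f"s{i}" for i in range(5)])
        p = tmp_path / "d.tsv"
        write_distance_matrix(dm, p)
        back = read_distance_matrix(p)
        assert list(back.ids) == list(dm.ids)
        np.testing.assert_allclose(back.data, dm.data, atol=1e-9)


class TestFilterTaxa:
    def test_chloroplast_removed(self, small_table):
        tax = make_taxonomy(
            {
                "f1": ["Bacteria", "Cyanobacteria", "Oxy", "Chloroplast"],
                "f2": ["Bacteria", "Proteobacteria"],
                "f3": ["Bacteria", "Firmicutes"],
            }
        )
        out = filter_taxa(small_table, tax)
        assert out.feature_ids == ["f2", "f3"]
        pd.testing.assert_frame_equal(out.data, small_table.data.loc[["f2", "f3"]])

    def test_empty_terms_identity(self, small_table, small_taxonomy):
        assert filter_taxa(small_table, small_taxonomy, []) == small_table

    def test_all_match_warns_not_errors(self, small_table, small_taxonomy):
        with pytest.warns(UserWarning, match="every feature"):
            out = filter_taxa(small_table, small_taxonomy, ["Bacteria"])
        assert out.shape == (0, 2)

    def test_orphan_feature_listed(self, small_table, small_taxonomy):
        with pytest.raises(ValueError, match="f3"):
            filter_taxa(small_table, small_taxonomy.drop("f3"), ["x"])


class TestCollapse:
    def test_genus_additivity(self, small_table, small_taxonomy):
        out = collapse_taxonomy(small_table, small_taxonomy, "genus")
        assert out.data.loc["Acetobacter", "s1"] == 3 + 0
        assert out.data.loc["Acetobacter", "s2"] == 1 + 5

    def test_species_level_identity_row_count(self, small_table, small_taxonomy):
        out = collapse_taxonomy(small_table, small_taxonomy, "species")
        assert out.shape[0] == small_table.shape[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_column_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        genera = [f"G{rng.integers(3)}" for _ in table.feature_ids]
        tax = make_taxonomy(
            {f: ["Bacteria", "P", "C", "O", "F", g] for f, g in zip(table.feature_ids, genera)}
        )
        for rank in ("phylum", "family", "genus"):
            out = collapse_taxonomy(table, tax, rank)
            # oracle: direct summation of the raw columns
            assert out.data.sum(0).tolist() == table.data.sum(0).tolist()

    def test_unclassified_labeled_by_parent(self, small_table):
        tax = make_taxonomy(
            {
                "f1": ["Bacteria", "Proteobacteria"],
                "f2": ["Bacteria", "Proteobacteria"],
                "f3": ["Bacteria", "Firmicutes"],
            }
        )
        out = collapse_taxonomy(small_table, tax, "genus")
        assert sorted(out.feature_ids) == [
            "Unclassified Firmicutes",
            "Unclassified Proteobacteria",
        ]

    def test_filter_collapse_commute_above_rank(self):
        # excluding at an order-rank term commutes with collapsing at family
        # when distinct orders never share a family label
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = random_table(rng, n_features=8)
            lineages = {}
            for f in table.feature_ids:
                if rng.random() < 0.3:
                    order, fam = "Chloroplast", "ChloroFam"
                else:
                    order = f"O{rng.integers(2)}"
                    fam = f"{order}_F{rng.integers(2)}"
                lineages[f] = ["Bacteria", "P", "C", order, fam]
            tax = make_taxonomy(lineages)
            a = collapse_taxonomy(filter_taxa(table, tax), tax, "family")
            collapsed = collapse_taxonomy(table, tax, "family")
            fam_tax = make_taxonomy(
                {lbl: ["Bacteria", "P", "C",
                       "Chloroplast" if lbl == "ChloroFam" else lbl.split("_")[0], lbl]
                 for lbl in collapsed.feature_ids}
            )
            b = filter_taxa(collapsed, fam_tax)
            pd.testing.assert_frame_equal(a.data.sort_index(), b.data.sort_index())


class TestFamilyComposition:
    def test_single_family_is_one(self, small_table):
        tax = make_taxonomy(
            {f: ["Bacteria", "P", "C", "O", "OneFam"] for f in ["f1", "f2", "f3"]}
        )
        out = family_composition(small_table, tax)
        assert out.shape[0] == 1
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_threshold_boundary_is_strict(self):
        # means 0.6 / 0.35 / 0.05 at threshold 0.05: 0.05 is not < 0.05,
        # so no Others row appears
        table = FeatureTable(
            pd.DataFrame({"s1": [60, 35, 5], "s2": [60, 35, 5]}, index=["f1", "f2", "f3"])
        )
        tax = make_taxonomy(
            {f: ["Bacteria", "P", "C", "O", fam] for f, fam in
             zip(["f1", "f2", "f3"], ["FamA", "FamB", "FamC"])}
        )
        out = family_composition(table, tax, min_mean_abundance=0.05)
        assert sorted(out.index) == ["FamA", "FamB", "FamC"]
        assert "Others" not in out.index

    @pytest.mark.parametrize("seed", range(3))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        tax = make_taxonomy(
            {f: ["Bacteria", "P", "C", "O", f"F{rng.integers(4)}"] for f in table.feature_ids}
        )
        out = family_composition(table, tax)
        np.testing.assert_allclose(out.sum(0), 1.0, atol=1e-9)

    def test_zero_total_sample_named(self, small_taxonomy):
        table = FeatureTable(
            pd.DataFrame({"good": [3, 1, 1], "empty": [0, 0, 0]},
                         index=["f1", "f2", "f3"])
        )
        with pytest.raises(ValueError, match="empty"):
            family_composition(table, small_taxonomy)
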
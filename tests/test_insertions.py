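"""BED ingest, unique-event collapsing, and per-gene tallies."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trapscreen.annotation import GeneModel, OrientationPolicy
from trapscreen.errors import ParseError, ValidationError
from trapscreen.insertions import (
    InsertionSite,
    count_per_gene,
    deduplicate,
    filter_min_reads,
    pool_datasets,
    read_insertions,
    sites_frame,
)


class TestReadInsertions:
    def test_reads_strands_positions_and_scores(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text(
            "chr1\t999\t1000\tx\t5\t+\n"
            "chr1\t2000\t2001\tx\t1\t-\n"
            "chr2\t10\t11\tx\tnoscore\t+\n"
        )
        df = read_insertions(bed, "s1")
        assert list(df["strand"]) == ["+", "-", "+"]
        assert df.loc[0, "position"] == 999 and df.loc[0, "read_count"] == 5
        assert df.loc[2, "read_count"] == 1  # non-numeric score defaults to 1
        assert (df["sample_id"] == "s1").all()

    def test_empty_file(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert len(read_insertions(bed, "s1")) == 0

    def test_missing_strand_column_is_format_error(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t11\tx\t1\n")
        with pytest.raises(ParseError, match="strand"):
            read_insertions(bed, "s1")

    def test_wide_record_reduced_to_start(self, tmp_path):
        bed = tmp_path / "wide.bed"
        bed.write_text("chr1\t100\t150\tx\t1\t+\n")
        df = read_insertions(bed, "s1")
        assert df.loc[0, "position"] == 100


class TestDeduplicate:
    def test_collapses_by_position_and_strand_summing_reads(self):
        df = sites_frame([
            InsertionSite("chr1", 500, "+", "s1", 3),
            InsertionSite("chr1", 500, "+", "s1", 4),
            InsertionSite("chr1", 500, "-", "s1", 1),
        ])
        out = deduplicate(df)
        assert len(out) == 2  # opposite strands stay distinct events
        plus = out[out["strand"] == "+"].iloc[0]
        assert plus["read_count"] == 7

    def test_mixed_samples_rejected(self):
        df = sites_frame([
            InsertionSite("chr1", 1, "+", "a"),
            InsertionSite("chr1", 2, "+", "b"),
        ])
        with pytest.raises(ValidationError, match="sample"):
            deduplicate(df)

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.sampled_from(["+", "-"]),
                      st.integers(1, 5)),
            max_size=40,
        )
    )
    def test_idempotent_and_sorted(self, raw):
        df = sites_frame([InsertionSite("chr1", p, s, "s1", rc)
                          for p, s, rc in raw])
        once = deduplicate(df)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))
        keys = list(zip(once["position"], once["strand"]))
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))
        assert once["read_count"].sum() == (df["read_count"].sum() if len(df) else 0)

    def test_min_reads_filter(self):
        df = sites_frame([
            InsertionSite("chr1", 1, "+", "s1", 1),
            InsertionSite("chr1", 2, "+", "s1", 3),
        ])
        assert len(filter_min_reads(df, 2)) == 1
        assert len(filter_min_reads(df, 1)) == 2


class TestCountPerGene:
    def test_balanced_gene(self, plus_gene):
        sites = [InsertionSite("chr1", 2000 + i, "+", "s1") for i in range(10)]
        sites += [InsertionSite("chr1", 3000 + i, "-", "s1") for i in range(10)]
        ds = count_per_gene(sites_frame(sites), [plus_gene])
        assert ds.gene("GENE_P").sense == 10
        assert ds.gene("GENE_P").antisense == 10
        assert ds.library_total == 20

    def test_site_in_overlapping_genes_counted_for_each(self):
        g1 = GeneModel("A", "A", "chr1", 0, 1000, "+")
        g2 = GeneModel("B", "B", "chr1", 500, 1500, "+")
        df = sites_frame([InsertionSite("chr1", 700, "+", "s1")])
        ds = count_per_gene(df, [g1, g2])
        assert ds.gene("A").sense == 1 and ds.gene("B").sense == 1

    def test_intergenic_sites_leave_genes_at_zero(self, toy_genes):
        df = sites_frame([InsertionSite("chr1", 100, "+", "s1"),
                          InsertionSite("chr1", 7000, "-", "s1")])
        ds = count_per_gene(df, toy_genes)
        assert (ds.counts["total"] == 0).all()
        assert ds.library_total == 2

    def test_exonic_antisense_policy_moves_counts(self, plus_gene):
        df = sites_frame([
            InsertionSite("chr1", 1200, "-", "s1"),  # exonic antisense
            InsertionSite("chr1", 2000, "-", "s1"),  # intronic antisense
        ])
        default = count_per_gene(df, [plus_gene])
        strict = count_per_gene(df, [plus_gene],
                                OrientationPolicy(exonic_antisense_disruptive=True))
        assert (default.gene("GENE_P").sense, default.gene("GENE_P").antisense) == (0, 2)
        assert (strict.gene("GENE_P").sense, strict.gene("GENE_P").antisense) == (1, 1)

    @given(st.permutations(range(6)))
    def test_invariant_to_site_order(self, order):
        toy_genes = [
            GeneModel("GENE_P", "GENE_P", "chr1", 1000, 5000, "+"),
            GeneModel("GENE_M", "GENE_M", "chr1", 8000, 12000, "-"),
        ]
        base = [
            InsertionSite("chr1", 1100, "+", "s1"),
            InsertionSite("chr1", 2500, "-", "s1"),
            InsertionSite("chr1", 4500, "+", "s1"),
            InsertionSite("chr1", 8500, "-", "s1"),
            InsertionSite("chr1", 11500, "+", "s1"),
            InsertionSite("chr1", 300, "+", "s1"),
        ]
        shuffled = [base[i] for i in order]
        a = count_per_gene(sites_frame(base), toy_genes)
        b = count_per_gene(sites_frame(shuffled), toy_genes)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_genic_counts_bounded_by_unique_sites(self, toy_genes):
        df = deduplicate(sites_frame(
            [InsertionSite("chr1", 1000 + 7 * i, "+" if i % 3 else "-", "s1")
             for i in range(300)]
        ))
        ds = count_per_gene(df, toy_genes)
        # non-overlapping genes: genic tallies sum to exactly the genic sites
        assert ds.counts["total"].sum() <= ds.library_total


class TestPooling:
    def test_pool_sums_counts_and_library_totals(self, toy_genes):
        d1 = count_per_gene(sites_frame([InsertionSite("chr1", 2000, "+", "a")]),
                            toy_genes, sample_id="a", condition="control")
        d2 = count_per_gene(sites_frame([InsertionSite("chr1", 2001, "+", "b")]),
                            toy_genes, sample_id="b", condition="control")
        pooled = pool_datasets([d1, d2])
        assert pooled.gene("GENE_P").sense == 2
        assert pooled.library_total == 2

    def test_pooling_across_conditions_rejected(self, toy_genes):
        d1 = count_per_gene(sites_frame([InsertionSite("chr1", 2000, "+", "a")]),
                            toy_genes, sample_id="a", condition="control")
        d2 = count_per_gene(sites_frame([InsertionSite("chr1", 2001, "+", "b")]),
                            toy_genes, sample_id="b", condition="treated")
        with pytest.raises(ValidationError, match="condition"):
            pool_datasets([d1, d2])
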
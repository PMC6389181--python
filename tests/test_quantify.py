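"""Strand-aware counting and RPKM: assignment rules, round-trip, conservation."""

import numpy as np
import pandas as pd
import pytest

from cisnat.catalog import GeneModel, build_catalog
from cisnat.quantify import (
    StrandedAlignment,
    StrandedCountTable,
    assign_read,
    compute_rpkm,
    count_reads,
    count_sample,
    detect_expressed,
)


def gene(gid="g1", start=1000, end=2000, strand="+"):
    return GeneModel(gene_id=gid, transcript_id=f"{gid}-01", chrom="chr1",
                     strand=strand, start=start, end=end, exon_length=end - start)


def aln(start, end, orientation="+", unique=True, chrom="chr1", rid="r"):
    return StrandedAlignment(read_id=rid, chrom=chrom, start=start, end=end,
                             orientation=orientation, is_unique=unique)


class TestAssignRead:
    @pytest.mark.parametrize(
        "read_orient, gene_strand, strandedness, expected",
        [
            ("+", "+", "forward", "sense"),
            ("-", "+", "forward", "antisense"),
            ("+", "-", "forward", "antisense"),
            ("-", "-", "forward", "sense"),
            ("+", "+", "reverse", "antisense"),
            ("-", "+", "reverse", "sense"),
        ],
    )
    def test_orientation_rules(self, read_orient, gene_strand, strandedness, expected):
        g = gene(strand=gene_strand)
        assert assign_read(aln(1200, 1275, read_orient), g, strandedness) == expected

    def test_multimapper_never_assigned(self):
        assert assign_read(aln(1200, 1275, unique=False), gene()) is None

    def test_no_overlap_returns_none(self):
        assert assign_read(aln(100, 175), gene()) is None
        assert assign_read(aln(2000, 2075), gene()) is None  # half-open: abuts, no overlap

    def test_one_bp_overlap_counts(self):
        g = gene()
        assert assign_read(aln(925, 1001), g) == "sense"
        assert assign_read(aln(1999, 2074), g) == "sense"


class TestCountSample:
    def test_counts_and_library_size(self):
        catalog = build_catalog([gene()])
        alns = [aln(1100, 1175, "+"), aln(1200, 1275, "-"),
                aln(5000, 5075, "+"),                      # outside any locus
                aln(1300, 1375, "+", unique=False)]        # multimapper
        counts, n = count_sample(alns, catalog)
        assert counts == {("g1", "sense"): 1, ("g1", "antisense"): 1}
        assert n == 3  # unique alignments only

    def test_empty_input_gives_zero_table(self):
        catalog = build_catalog([gene()])
        counts, n = count_sample([], catalog)
        assert counts == {} and n == 0

    def test_read_spanning_two_eligible_loci_is_ambiguous(self):
        catalog = build_catalog([gene("a", 1000, 2000), gene("b", 2010, 3000)])
        counts, _ = count_sample([aln(1990, 2065)], catalog)  # touches both
        assert counts == {}

    def test_unknown_chromosome_rejected(self):
        catalog = build_catalog([gene()])
        with pytest.raises(ValueError, match="unknown chromosome"):
            count_sample([aln(0, 75, chrom="chrX")], catalog, known_chroms={"chr1"})

    def test_excluded_loci_receive_no_counts(self):
        catalog = build_catalog([gene("a", 1000, 2000, "+"), gene("b", 1500, 2500, "-")])
        counts, n = count_sample([aln(1100, 1175)], catalog)
        assert counts == {} and n == 1


class TestRoundTrip:
    def test_quantification_recovers_simulated_counts_exactly(self, small_experiment):
        catalog = build_catalog(small_experiment["genes"])
        table = count_reads(small_experiment["sam_paths"], catalog)
        truth = small_experiment["counts"]
        eligible = catalog.eligible_transcript_ids
        t = truth[truth["transcript_id"].isin(eligible)].set_index(
            ["transcript_id", "strand_class", "sample_id"])["count"]
        got = table.counts.set_index(["transcript_id", "strand_class", "sample_id"])["count"]
        merged = pd.concat([t, got], axis=1, keys=["truth", "got"]).fillna(0)
        assert (merged["truth"] == merged["got"]).all()

    def test_strandedness_flip_swaps_sense_and_antisense(self, small_experiment):
        catalog = build_catalog(small_experiment["genes"])
        fwd = count_reads(small_experiment["sam_paths"], catalog, strandedness="forward")
        rev = count_reads(small_experiment["sam_paths"], catalog, strandedness="reverse")
        f = fwd.counts.set_index(["transcript_id", "strand_class", "sample_id"])["count"]
        r = rev.counts.set_index(["transcript_id", "strand_class", "sample_id"])["count"]
        for (tx, cls, s), v in f.items():
            other = "antisense" if cls == "sense" else "sense"
            assert r[(tx, other, s)] == v

    def test_conservation_of_assigned_reads(self, small_experiment):
        catalog = build_catalog(small_experiment["genes"])
        table = count_reads(small_experiment["sam_paths"], catalog)
        truth = small_experiment["counts"]
        eligible = catalog.eligible_transcript_ids
        for sample, n in table.library_sizes.items():
            sample_total = truth[truth["sample_id"] == sample]["count"].sum()
            assert n == sample_total  # zero multimappers: every read is unique
            assigned = table.counts[table.counts["sample_id"] == sample]["count"].sum()
            expected = truth[(truth["sample_id"] == sample)
                             & truth["transcript_id"].isin(eligible)]["count"].sum()
            assert assigned == expected
            assert assigned <= n


class TestRpkm:
    def make_table(self, c, n, tx="g1-01"):
        df = pd.DataFrame({"transcript_id": [tx], "strand_class": ["sense"],
                           "sample_id": ["s1"], "count": [c]})
        return StrandedCountTable(counts=df, library_sizes={"s1": n})

    def test_unit_case(self):
        expr = compute_rpkm(self.make_table(1000, 10**6), {"g1-01": 1000})
        assert expr["rpkm"].iloc[0] == pytest.approx(1000.0)

    def test_hand_evaluated_case(self):
        expr = compute_rpkm(self.make_table(25, 5 * 10**6), {"g1-01": 2500})
        assert expr["rpkm"].iloc[0] == pytest.approx(2.0)

    def test_zero_count_gives_zero_rpkm(self):
        expr = compute_rpkm(self.make_table(0, 10**6), {"g1-01": 1000})
        assert expr["rpkm"].iloc[0] == 0.0

    def test_homogeneity(self):
        base = compute_rpkm(self.make_table(100, 10**6), {"g1-01": 500})["rpkm"].iloc[0]
        assert compute_rpkm(self.make_table(200, 10**6), {"g1-01": 500})["rpkm"].iloc[0] \
            == pytest.approx(2 * base)
        assert compute_rpkm(self.make_table(100, 2 * 10**6), {"g1-01": 500})["rpkm"].iloc[0] \
            == pytest.approx(base / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(self.make_table(10, 10**6), {"g1-01": 0})

    def test_zero_library_with_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(self.make_table(10, 0), {"g1-01": 1000})


class TestDetectExpressed:
    def test_flags_follow_min_reads(self):
        df = pd.DataFrame({
            "transcript_id": ["a", "a", "b", "b"],
            "strand_class": ["sense"] * 4,
            "sample_id": ["s1", "s2", "s1", "s2"],
            "count": [0, 0, 1, 0],
        })
        table = StrandedCountTable(counts=df, library_sizes={"s1": 10, "s2": 10})
        flags = detect_expressed(table).set_index("transcript_id")["expressed"]
        assert not flags["a"] and flags["b"]

    def test_expressed_set_matches_simulated_truth(self, small_experiment):
        catalog = build_catalog(small_experiment["genes"])
        table = count_reads(small_experiment["sam_paths"], catalog)
        flags = detect_expressed(table, min_reads=1)
        truth = small_experiment["counts"]
        expected = (
            truth[truth["transcript_id"].isin(catalog.eligible_transcript_ids)]
            .groupby(["transcript_id", "strand_class"])["count"].max() >= 1
        )
        got = flags.set_index(["transcript_id", "strand_class"])["expressed"]
        assert got.sort_index().equals(expected.sort_index().rename("expressed"))
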
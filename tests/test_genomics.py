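import numpy as np
import pytest

from tlpcensus import synthetic_data as synth
from tlpcensus.genomics import (
    exon_count_profile,
    find_clusters,
    interval_union_length,
    te_coverage,
)
from tlpcensus.io_formats import GeneModel, RepeatInterval, read_gff3, read_repeats

from tests.oracles import per_base_union_length


def gene(gid, start, end, family=True, chrom="chr1", strand="+"):
    return GeneModel(
        gene_id=gid, chrom=chrom, strand=strand, exons=[(start, end)], family_flag=family
    )


class TestIntervalUnion:
    def test_overlap_merged(self):
        assert interval_union_length([(0, 10), (5, 15)]) == 15

    def test_empty_list(self):
        assert interval_union_length([]) == 0

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_union_length([(5, 5)])

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 40))
            starts = rng.integers(0, 9_900, k)
            lengths = rng.integers(1, 500, k)
            ivs = [(int(s), int(min(s + l, 10_000))) for s, l in zip(starts, lengths)]
            assert interval_union_length(ivs) == per_base_union_length(ivs)


class TestTECoverage:
    def test_single_repeat_half_region(self):
        cov = te_coverage(("chr1", 0, 1000), [RepeatInterval("chr1", 0, 500, "LTR_Gypsy")])
        assert cov.class_fraction["LTR_Gypsy"] == pytest.approx(0.5)
        assert cov.total_fraction == pytest.approx(0.5)

    def test_overlapping_classes_union(self):
        reps = [
            RepeatInterval("chr1", 0, 600, "LTR_Gypsy"),
            RepeatInterval("chr1", 400, 800, "DNA_transposon"),
        ]
        cov = te_coverage(("chr1", 0, 1000), reps)
        assert cov.class_fraction["LTR_Gypsy"] == pytest.approx(0.6)
        assert cov.class_fraction["DNA_transposon"] == pytest.approx(0.4)
        assert cov.total_fraction == pytest.approx(0.8)

    def test_repeats_clipped_and_other_chroms_ignored(self):
        reps = [
            RepeatInterval("chr1", 900, 1500, "LTR_Copia"),
            RepeatInterval("chr2", 0, 1000, "LTR_Gypsy"),
        ]
        cov = te_coverage(("chr1", 0, 1000), reps)
        assert cov.class_bp == {"LTR_Copia": 100}
        assert "LTR_Gypsy" not in cov.class_fraction

    def test_enrichment_ratio(self):
        cov = te_coverage(
            ("chr1", 0, 1000),
            [RepeatInterval("chr1", 0, 370, "LTR_Gypsy")],
            background={"LTR_Gypsy": 0.05},
        )
        assert cov.enrichment["LTR_Gypsy"] == pytest.approx(7.4)

    def test_generator_locus_hits_planned_fractions_exactly(self, tmp_path):
        _, rep_text, truth = synth.generate_locus(seed=1)
        p = tmp_path / "r.tsv"
        p.write_text(rep_text)
        reps = read_repeats(p)
        cov = te_coverage((truth.chrom, *truth.cluster_span), reps)
        assert cov.total_fraction == truth.te_fractions["total"] == 0.52
        assert cov.class_fraction["LTR_Gypsy"] == truth.te_fractions["LTR_Gypsy"] == 0.37


class TestClusters:
    def test_three_spaced_family_genes_form_cluster(self):
        genes = [gene("a", 0, 1000), gene("b", 10_000, 11_000), gene("c", 20_000, 21_000)]
        (cl,) = find_clusters(genes)
        assert cl.members == ["a", "b", "c"]
        assert cl.span == (0, 21_000) and cl.span_bp == 21_000
        assert cl.exclusive

    def test_gap_exceeded_no_cluster(self):
        genes = [gene("a", 0, 1000), gene("b", 1_100_000, 1_101_000)]
        assert find_clusters(genes, min_size=2) == []

    def test_interleaved_non_family_gene_breaks_exclusivity(self):
        genes = [
            gene("a", 0, 1000),
            gene("x", 5_000, 6_000, family=False),
            gene("b", 10_000, 11_000),
            gene("c", 20_000, 21_000),
        ]
        (cl,) = find_clusters(genes)
        assert cl.members == ["a", "b", "c"]
        assert not cl.exclusive
        assert find_clusters(genes, require_family_only=True) == []

    def test_invariant_under_input_order_and_strand(self):
        genes = [
            gene("a", 0, 1000),
            gene("b", 10_000, 11_000),
            gene("c", 20_000, 21_000, strand="-"),
            gene("d", 500_000, 501_000, family=False),
        ]
        flipped = [
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                exons=list(g.exons),
                family_flag=g.family_flag,
            )
            for g in reversed(genes)
        ]
        a = [(c.members, c.span, c.exclusive) for c in find_clusters(genes)]
        b = [(c.members, c.span, c.exclusive) for c in find_clusters(flipped)]
        assert a == b

    def test_generator_cluster_detected_exactly(self, tmp_path):
        gff_text, _, truth = synth.generate_locus(seed=2, n_other=4)
        p = tmp_path / "l.gff3"
        p.write_text(gff_text)
        genes = read_gff3(p, family_ids=truth.family_ids)
        (cl,) = find_clusters(genes)
        assert cl.members == truth.cluster_members
        assert cl.span == truth.cluster_span
        assert cl.exclusive == truth.cluster_exclusive

    def test_interleaved_plan_detected_as_non_exclusive(self, tmp_path):
        gff_text, _, truth = synth.generate_locus(
            seed=2, cluster_plan=synth.ClusterPlan(interleave_other=1)
        )
        p = tmp_path / "l.gff3"
        p.write_text(gff_text)
        genes = read_gff3(p, family_ids=truth.family_ids)
        (cl,) = find_clusters(genes)
        assert not cl.exclusive and not truth.cluster_exclusive


class TestExonProfile:
    def test_counts_match_planted_values(self, tmp_path):
        plan = synth.ClusterPlan(exon_counts=(1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2))
        gff_text, _, truth = synth.generate_locus(cluster_plan=plan, seed=4)
        p = tmp_path / "l.gff3"
        p.write_text(gff_text)
        genes = read_gff3(p, family_ids=truth.family_ids)
        profile = exon_count_profile(genes)
        assert profile == truth.exon_counts
        assert profile["TLPfam001"] == 2
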
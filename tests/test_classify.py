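import pytest

from tlpcensus import synthetic_data as synth
from tlpcensus.classify import (
    classify_architecture,
    column_conservation,
    detect_kinase_domain,
    detect_tm_segment,
    reddd_score,
)
from tlpcensus.io_formats import Alignment

ALL_ARCHITECTURES = ("typical", "small", "tlp_kinase", "small_tlp_kinase")


class TestKinaseDetection:
    def test_found_downstream_on_kinase_scaffold(self):
        rec, truth = synth.generate_protein(synth.ScaffoldSpec("tlp_kinase"), seed=5)
        region = detect_kinase_domain(
            rec.sequence[truth.domain_end :], offset=truth.domain_end
        )
        assert region is not None
        assert region.start == truth.kinase_start
        assert region.catalytic_asp_positions == truth.catalytic_asp_positions
        # both catalytic positions hold aspartate
        for pos in region.catalytic_asp_positions:
            assert rec.sequence[pos] == "D"

    def test_absent_on_typical_scaffold(self):
        rec, truth = synth.generate_protein(synth.ScaffoldSpec("typical"), seed=6)
        assert detect_kinase_domain(rec.sequence[truth.domain_end :]) is None

    def test_motifs_out_of_order_rejected(self):
        seq = "GAGAAG" + "A" * 97 + "DFG" + "A" * 24 + "HRD" + "A" * 200
        assert detect_kinase_domain(seq) is None


class TestTMDetection:
    def test_hydrophobic_run_in_polar_context(self):
        seq = "S" * 30 + "I" * 19 + "S" * 30
        tm = detect_tm_segment(seq)
        assert tm is not None
        assert (tm.start, tm.end) == (30, 49)
        assert tm.mean_hydropathy == pytest.approx(4.5)

    def test_all_aspartate_has_no_tm(self):
        assert detect_tm_segment("D" * 40) is None

    def test_sequence_shorter_than_window_is_none(self):
        assert detect_tm_segment("IIII") is None

    def test_stlpk_tm_lies_between_domain_and_kinase(self):
        rec, truth = synth.generate_protein(synth.ScaffoldSpec("small_tlp_kinase"), seed=8)
        tm = detect_tm_segment(
            rec.sequence, region=(truth.domain_end, truth.kinase_start)
        )
        assert (tm.start, tm.end) == (truth.tm_start, truth.tm_end)
        assert truth.domain_end < tm.start and tm.end < truth.kinase_start


class TestArchitecture:
    @pytest.mark.parametrize("arch", ALL_ARCHITECTURES)
    def test_generator_roundtrip_label(self, arch):
        for seed in range(25):
            rec, _ = synth.generate_protein(synth.ScaffoldSpec(arch), seed=seed)
            assert classify_architecture(rec).label == arch

    def test_order_invariance(self):
        records = [
            synth.generate_protein(synth.ScaffoldSpec(a), seed=s)[0]
            for a in ALL_ARCHITECTURES
            for s in range(3)
        ]
        forward = {r.id: classify_architecture(r).label for r in records}
        backward = {r.id: classify_architecture(r).label for r in reversed(records)}
        assert forward == backward

    def test_truncated_scaffold_is_incomplete(self):
        rec, truth = synth.generate_protein(synth.ScaffoldSpec("typical"), seed=9)
        from tlpcensus.io_formats import ProteinRecord

        trunc = ProteinRecord(id="t", sequence=rec.sequence[: truth.c_motif_start])
        cls = classify_architecture(trunc)
        assert cls.label == "incomplete"
        assert cls.evidence["complete_domain"] is False


class TestReddd:
    def make_alignment(self):
        #             cols: 0123456789
        # ref ungapped pos:  0 1234 56
        ref = "A-REDDD-AA"
        rows = (
            ref,
            ref,  # identical copy
            "A-KEDDD-AA",  # K at the R column -> equivalent
            "A-RDDDD-AA",  # D at the E column -> equivalent
            "A-RGDDD-AA",  # G at the E column -> divergent
            "A-RED-D-AA",  # gap at a D column -> divergent
        )
        ids = ("ref", "dup", "kr", "de", "ge", "gap")
        return Alignment(ids, rows)

    def test_self_alignment_all_identical(self):
        aln = self.make_alignment()
        report = reddd_score(aln, "ref", (1, 2, 3, 4, 5))
        assert report.columns == (2, 3, 4, 5, 6)
        assert report.status["ref"] == ("identical",) * 5
        assert report.status["dup"] == ("identical",) * 5

    def test_equivalent_and_divergent_statuses(self):
        report = reddd_score(self.make_alignment(), "ref", (1, 2, 3, 4, 5))
        assert report.status["kr"][0] == "equivalent"
        assert report.status["de"][1] == "equivalent"
        assert report.status["ge"][1] == "divergent"
        assert report.status["gap"][3] == "divergent"
        # fully conserved = identical or equivalent at all five positions
        assert report.n_fully_conserved == 4

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            reddd_score(self.make_alignment(), "nope", (1, 2, 3, 4, 5))

    def test_position_beyond_reference_raises(self):
        with pytest.raises(ValueError, match="outside"):
            reddd_score(self.make_alignment(), "ref", (1, 2, 3, 4, 50))


class TestColumnConservation:
    def test_four_level_binning(self):
        cols = ("CCCCCCCC", "AAGGSSAA", "ACDEACDE", "ACDEFGHI")
        aln = Alignment(
            tuple(f"s{i}" for i in range(8)),
            tuple("".join(col[i] for col in cols) for i in range(8)),
        )
        # distinct non-gap residues per column: 1 / 3 / 4 / 8
        assert list(column_conservation(aln)) == [1, 2, 3, 4]

    def test_levels_on_hand_built_columns(self):
        rows = ["C", "C", "C", "C"], ["A", "A", "G", "S"], ["A", "C", "D", "E"], ["A", "-", "-", "-"]
        aln = Alignment(
            ("a", "b", "c", "d"),
            tuple("".join(col[i] for col in rows) for i in range(4)),
        )
        levels = column_conservation(aln)
        # distinct non-gap residues per column: 1 / 3 / 4 / 1
        assert list(levels) == [1, 2, 3, 1]

    def test_high_diversity_column_is_level_four(self):
        aln = Alignment(
            tuple(f"s{i}" for i in range(8)), tuple("ACDEFGHI"[i] for i in range(8))
        )
        assert list(column_conservation(aln)) == [4]
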
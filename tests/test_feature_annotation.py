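import numpy as np
import pytest

from g4scape.genome_io import GenomeIndex, Interval, IntervalSet, coverage_fraction
from g4scape.g4_predict import PRESETS
from g4scape.feature_annotation import (
    GenomicContext,
    LadMap,
    RepeatRecord,
    compare_peaksets,
    consensus_g4_count,
    genome_repartition,
    genomic_context_profile,
    lad_colocalization,
    peak_repeat_profile,
    read_rmsk,
)

UCSC_HEADER = "#bin\tgenoName\tgenoStart\tgenoEnd\trepName\trepClass\trepFamily\tmilliDiv\n"


@pytest.fixture
def gi():
    return GenomeIndex({"chr1": 100_000})


class TestReadRmsk:
    def test_full_ucsc_dialect(self, tmp_path, gi):
        p = tmp_path / "rmsk.tsv"
        p.write_text(
            UCSC_HEADER
            + "1\tchr1\t100\t600\tL1PA3\tLINE\tL1\t35\n"
            + "1\tchr1\t700\t900\tAluSx\tSINE\tAlu\t110\n"
            + "1\tchr1\t950\t990\tMLT1\tLTR\tERVL-MaLR\t200\n"
        )
        recs = read_rmsk(p, gi)
        assert len(recs) == 3
        assert recs[0].repeat_class == "LINE" and recs[0].repeat_family == "L1"
        assert recs[0].milli_div == 35
        assert recs[1].repeat_name == "AluSx"

    def test_minimal_dialect_parses_identically(self, tmp_path, gi):
        full = tmp_path / "full.tsv"
        full.write_text(UCSC_HEADER + "1\tchr1\t100\t600\tL1PA3\tLINE\tL1\t35\n")
        minimal = tmp_path / "min.tsv"
        minimal.write_text("chr1\t100\t600\tL1PA3\tLINE\tL1\t35\n")
        assert read_rmsk(full, gi) == read_rmsk(minimal, gi)

    def test_coordinate_violation_reports_line(self, tmp_path, gi):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t100\t600\tL1\tLINE\tL1\nchr1\t600\t100\tL1\tLINE\tL1\n")
        with pytest.raises(ValueError, match=":2:"):
            read_rmsk(p, gi)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#genoName\tgenoStart\tgenoEnd\trepName\nchr1\t1\t2\tL1\n")
        with pytest.raises(ValueError, match="missing rmsk columns"):
            read_rmsk(p)


def _rep(gi, start, end, name, cls, fam):
    return RepeatRecord(Interval("chr1", start, end, name=name), name, cls, fam)


class TestRepeatProfile:
    def test_peak_counted_in_every_touched_class(self, gi):
        peaks = IntervalSet([Interval("chr1", 100, 1000)], gi)
        reps = [
            _rep(gi, 150, 300, "L1PA3", "LINE", "L1"),
            _rep(gi, 500, 600, "AluSx", "SINE", "Alu"),
        ]
        prof = peak_repeat_profile(peaks, reps, "class")
        assert prof["LINE"] == 1.0 and prof["SINE"] == 1.0

    def test_no_overlap_gives_zero(self, gi):
        peaks = IntervalSet([Interval("chr1", 10, 20)], gi)
        reps = [_rep(gi, 5000, 6000, "L1PA3", "LINE", "L1")]
        prof = peak_repeat_profile(peaks, reps, "class")
        assert prof["LINE"] == 0.0

    def test_empty_peaks_rejected(self, gi):
        with pytest.raises(ValueError):
            peak_repeat_profile(IntervalSet([], gi), [], "class")

    def test_planted_line_fraction_recovered(self, study):
        prof = peak_repeat_profile(study.peaks_a, study.repeats, "class")
        planted = study.spec.p_peak_on_conserved
        assert prof["LINE"] == pytest.approx(planted, abs=0.03)

    def test_name_level_membership_rolls_up_to_family(self, study):
        by_name = peak_repeat_profile(study.peaks_a, study.repeats, "name")
        by_family = peak_repeat_profile(study.peaks_a, study.repeats, "family")
        # membership is monotone under coarsening: family >= any single name
        assert by_family["L1"] >= by_name.max() - 1e-12


class TestLadColocalization:
    def _lads(self, gi):
        clad = IntervalSet([Interval("chr1", 0, 10_000)], gi)
        flad = IntervalSet([Interval("chr1", 10_000, 15_000)], gi)
        return LadMap(clad, flad)

    def test_peak_inside_clad(self, gi):
        res = lad_colocalization(IntervalSet([Interval("chr1", 100, 200)], gi),
                                 self._lads(gi))
        assert res == {"cLAD": 1.0, "fLAD": 0.0, "nonLAD": 0.0}

    def test_straddling_peak_counted_in_both(self, gi):
        res = lad_colocalization(IntervalSet([Interval("chr1", 9_500, 10_500)], gi),
                                 self._lads(gi))
        assert res["cLAD"] == 1.0 and res["fLAD"] == 1.0 and res["nonLAD"] == 0.0

    def test_random_peaks_match_lad_coverage(self, study):
        from conftest import random_interval_set

        rng = np.random.default_rng(44)
        peaks = random_interval_set(study.genome, 1000, rng, max_width=200)
        res = lad_colocalization(peaks, study.lads)
        assert 1 - res["nonLAD"] == pytest.approx(study.spec.lad_coverage, abs=0.05)

    def test_membership_bookkeeping_conserves_peaks(self, study):
        res = lad_colocalization(study.peaks_a, study.lads)
        assert 0 <= res["cLAD"] <= 1 and 0 <= res["fLAD"] <= 1
        # nonLAD is the exact complement of the union membership
        union = 1 - res["nonLAD"]
        assert union <= res["cLAD"] + res["fLAD"] + 1e-12


class TestGenomeRepartition:
    def test_half_covered(self):
        gi = GenomeIndex({"c": 1000})
        feats = {"x": IntervalSet([Interval("c", 0, 500)], gi)}
        res = genome_repartition(feats, gi)
        assert res == {"x": 0.5, "complement": 0.5}

    def test_empty_map_complement_one(self):
        gi = GenomeIndex({"c": 1000})
        assert genome_repartition({}, gi) == {"complement": 1.0}

    def test_overlap_double_counted_per_name_not_in_union(self):
        gi = GenomeIndex({"c": 1000})
        feats = {
            "a": IntervalSet([Interval("c", 0, 400)], gi),
            "b": IntervalSet([Interval("c", 200, 600)], gi),
        }
        res = genome_repartition(feats, gi)
        assert res["a"] == 0.4 and res["b"] == 0.4
        assert res["complement"] == pytest.approx(0.4)


class TestGenomicContext:
    def _ctx(self, gi):
        return GenomicContext(
            IntervalSet([Interval("chr1", 0, 1000)], gi),
            IntervalSet([Interval("chr1", 5000, 5400)], gi),
            IntervalSet([Interval("chr1", 800, 1200)], gi),
        )

    def test_gene_body_only(self, gi):
        res = genomic_context_profile(IntervalSet([Interval("chr1", 10, 20)], gi),
                                      self._ctx(gi))
        assert res == {"gene_body": 1.0, "enhancer": 0.0, "cpg_island": 0.0,
                       "none_of_these": 0.0}

    def test_double_membership(self, gi):
        res = genomic_context_profile(IntervalSet([Interval("chr1", 900, 950)], gi),
                                      self._ctx(gi))
        assert res["gene_body"] == 1.0 and res["cpg_island"] == 1.0

    def test_no_context_overlap(self, gi):
        res = genomic_context_profile(IntervalSet([Interval("chr1", 90_000, 90_100)], gi),
                                      self._ctx(gi))
        assert res["none_of_these"] == 1.0


class TestComparePeaksets:
    def test_many_to_one_asymmetry(self, gi):
        a = IntervalSet([Interval("chr1", 0, 1000)], gi)
        b = IntervalSet([Interval("chr1", 10, 20), Interval("chr1", 500, 510)], gi)
        res = compare_peaksets(a, b)
        assert res == {"specific_a": 0, "shared_a": 1, "specific_b": 0, "shared_b": 2}

    def test_disjoint_sets(self, gi):
        a = IntervalSet([Interval("chr1", 0, 10)], gi)
        b = IntervalSet([Interval("chr1", 100, 110)], gi)
        res = compare_peaksets(a, b)
        assert res["shared_a"] == 0 and res["shared_b"] == 0

    def test_identical_sets(self, gi):
        a = IntervalSet([Interval("chr1", 0, 10), Interval("chr1", 50, 70)], gi)
        res = compare_peaksets(a, a)
        assert res["shared_a"] == res["shared_b"] == 2

    def test_swap_symmetry(self, study):
        ab = compare_peaksets(study.peaks_a, study.peaks_b)
        ba = compare_peaksets(study.peaks_b, study.peaks_a)
        assert ab["shared_a"] == ba["shared_b"]
        assert ab["specific_a"] == ba["specific_b"]


class TestConsensusScan:
    def test_planted_motifs_recovered(self):
        from g4scape.synthetic_data import l1_like_consensus

        cons = l1_like_consensus(n_motifs=3)
        res = consensus_g4_count({"L1syn": cons}, PRESETS["canonical"])
        assert len(res["L1syn"]) == 3

    def test_all_t_consensus_empty(self):
        res = consensus_g4_count({"t": "T" * 500}, PRESETS["canonical"])
        assert res["t"] == []

    def test_count_unchanged_by_motif_free_flanks(self):
        core = "GGGAGGGAGGGAGGG"
        with_flanks = "ACT" * 50 + core + "ACT" * 50
        a = consensus_g4_count({"x": core}, PRESETS["canonical"])
        b = consensus_g4_count({"x": with_flanks}, PRESETS["canonical"])
        assert len(a["x"]) == len(b["x"])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            consensus_g4_count({"x": ""}, PRESETS["canonical"])
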
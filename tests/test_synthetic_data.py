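import numpy as np
import pytest

from g4scape.genome_io import Interval, IntervalSet, coverage_fraction
from g4scape.g4_predict import PRESETS, find_g4_motifs
from g4scape.expression_link import upregulated_fraction
from g4scape.synthetic_data import (
    SimSpec,
    l1_like_consensus,
    make_genome,
    plant_repeats,
    simulate_all,
    simulate_de_table,
    simulate_lads,
    simulate_paired_intensities,
    simulate_peaks,
    tile_genes,
)


class TestMakeGenome:
    def test_lengths_match_spec(self):
        spec = SimSpec(chrom_lengths={"a": 1000, "b": 2500}, seed=1)
        seqs, gi = make_genome(spec)
        assert {c: len(s) for c, s in seqs.items()} == {"a": 1000, "b": 2500}
        assert gi.total_length == 3500

    def test_gc_content_within_binomial_bound(self):
        spec = SimSpec(chrom_lengths={"c": 1_000_000}, gc_content=0.41, seed=2)
        seqs, _ = make_genome(spec)
        gc = sum(seqs["c"].count(b) for b in "GC") / 1_000_000
        assert gc == pytest.approx(0.41, abs=0.01)

    def test_seed_determinism(self):
        a, _ = make_genome(SimSpec(chrom_lengths={"c": 5000}, seed=9))
        b, _ = make_genome(SimSpec(chrom_lengths={"c": 5000}, seed=9))
        c, _ = make_genome(SimSpec(chrom_lengths={"c": 5000}, seed=10))
        assert a == b and a != c


class TestPlantRepeats:
    def test_consensus_carries_exactly_three_canonical_motifs(self):
        cons = l1_like_consensus()
        assert len(find_g4_motifs(cons, PRESETS["canonical"], "both")) == 3

    def test_zero_divergence_retains_all_motifs(self):
        spec = SimSpec(chrom_lengths={"c": 500_000}, n_repeat_copies=20,
                       conserved_fraction=1.0, seed=3)
        seqs, _ = make_genome(spec)
        _, records, truth = plant_repeats(seqs, spec)
        assert (truth.n_motifs_retained == 3).all()
        assert len(records) == 20

    def test_divergence_degrades_motifs(self):
        spec = SimSpec(chrom_lengths={"c": 1_000_000}, n_repeat_copies=50,
                       conserved_fraction=0.0, divergence_rate=0.3, seed=4)
        seqs, _ = make_genome(spec)
        _, _, truth = plant_repeats(seqs, spec)
        assert truth.n_motifs_retained.mean() < 3.0

    def test_copies_do_not_overlap(self, study):
        ivs = sorted(
            (r.interval.chrom, r.interval.start, r.interval.end)
            for r in study.repeats
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2


class TestSimulatePeaks:
    def test_all_peaks_on_conserved_when_p_one(self, study):
        spec = SimSpec(seed=6, p_peak_on_conserved=1.0, n_peaks=100)
        peaks, labels = simulate_peaks(study.repeats, study.repeat_truth,
                                       spec, study.genome)
        assert all(lab == "on_conserved" for lab in labels)
        cons = study.repeat_truth[study.repeat_truth.conserved]
        cons_set = IntervalSet(
            [Interval(r.chrom, int(r.start), int(r.end))
             for r in cons.itertuples()], study.genome
        )
        from g4scape.genome_io import count_overlaps
        assert (count_overlaps(peaks, cons_set) > 0).all()

    def test_background_only_matches_repeat_coverage(self, study):
        spec = SimSpec(seed=7, p_peak_on_conserved=0.0, n_peaks=2000)
        peaks, labels = simulate_peaks(study.repeats, study.repeat_truth,
                                       spec, study.genome)
        assert all(lab == "background" for lab in labels)
        rep_set = IntervalSet([r.interval for r in study.repeats], study.genome)
        from g4scape.genome_io import count_overlaps
        hit = (count_overlaps(peaks, rep_set) > 0).mean()
        # expected ~ coverage of repeats dilated by peak width
        cov = coverage_fraction(rep_set, study.genome)
        assert hit == pytest.approx(cov * (1 + 500 / 1200), abs=0.04)

    def test_peak_count_and_min_width(self, study):
        assert len(study.peaks_a) == study.spec.n_peaks
        assert min(iv.length for iv in study.peaks_a) >= 50


class TestSimulateLads:
    def test_target_coverage_hit(self, study):
        union = IntervalSet(
            list(study.lads.clad) + list(study.lads.flad), study.genome
        )
        assert coverage_fraction(union, study.genome) == pytest.approx(0.5, abs=0.02)

    def test_zero_coverage_empty_map(self):
        spec = SimSpec(chrom_lengths={"c": 200_000}, lad_coverage=0.0, seed=1)
        lads = simulate_lads(make_genome(spec)[1], spec)
        assert len(lads.clad) == 0 and len(lads.flad) == 0

    def test_clad_flad_disjoint(self, study):
        from g4scape.genome_io import count_overlaps
        assert (count_overlaps(study.lads.clad, study.lads.flad) == 0).all()


class TestSimulateDe:
    def test_baseline_fraction_recovered(self):
        spec = SimSpec(chrom_lengths={"c": 2_000_000}, n_genes=10_000,
                       frac_up=0.51, seed=8)
        de, _, _ = simulate_de_table(spec, flagged_genes=set())
        assert upregulated_fraction(de) == pytest.approx(0.51, abs=0.01)

    def test_null_bias_indistinguishable(self):
        spec = SimSpec(chrom_lengths={"c": 500_000}, n_genes=2000, frac_up=0.5,
                       planted_down_bias=0.5, seed=9)
        de, genes, flagged = simulate_de_table(spec)
        by_id = {r.gene_id: r for r in de}
        flag_up = np.mean([by_id[g].log2fc > 0 for g in flagged])
        assert flag_up == pytest.approx(0.5, abs=0.2)

    def test_gene_tiling_disjoint_and_named(self, study):
        ivs = sorted((iv.chrom, iv.start, iv.end) for iv in study.genes)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2
        assert all(iv.name for iv in study.genes)

    def test_unknown_flagged_gene_rejected(self):
        spec = SimSpec(chrom_lengths={"c": 100_000}, n_genes=10, seed=2)
        with pytest.raises(ValueError, match="outside the gene universe"):
            simulate_de_table(spec, flagged_genes={"nope"})


class TestPairedIntensities:
    def test_rho_one_gives_perfect_correlation(self):
        from g4scape.coloc_stats import pearson_profile

        p = simulate_paired_intensities(1.0, 500, seed=3)
        assert pearson_profile(p) == pytest.approx(1.0, abs=1e-6)

    def test_rho_zero_near_zero(self):
        from g4scape.coloc_stats import pearson_profile

        p = simulate_paired_intensities(0.0, 10_000, seed=4)
        assert abs(pearson_profile(p)) < 0.03

    def test_seed_determinism(self):
        a = simulate_paired_intensities(0.5, 100, seed=5)
        b = simulate_paired_intensities(0.5, 100, seed=5)
        assert np.array_equal(a.a, b.a) and np.array_equal(a.b, b.b)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_paired_intensities(1.5, 10)


class TestStudyFiles:
    def test_written_files_reload_consistently(self, tmp_path):
        from g4scape.genome_io import read_bed, read_fasta
        from g4scape.feature_annotation import read_rmsk
        from g4scape.expression_link import read_de_table

        spec = SimSpec(chrom_lengths={"c": 300_000}, n_repeat_copies=20,
                       n_peaks=50, n_genes=300, seed=12)
        study = simulate_all(spec, tmp_path)
        seqs, gi = read_fasta(tmp_path / "genome.fa")
        assert gi == study.genome and seqs == study.seqs
        peaks = read_bed(tmp_path / "peaks_condition_a.bed", gi)
        assert [(p.chrom, p.start, p.end) for p in peaks] == [
            (p.chrom, p.start, p.end) for p in study.peaks_a
        ]
        assert read_rmsk(tmp_path / "rmsk.tsv", gi)[0].repeat_class == "LINE"
        de = read_de_table(tmp_path / "de_table.tsv")
        assert len(de) == len(study.de)
        assert (tmp_path / "truth.json").exists()

    def test_byte_determinism_of_outputs(self, tmp_path):
        spec = SimSpec(chrom_lengths={"c": 200_000}, n_repeat_copies=10,
                       n_peaks=20, n_genes=100, seed=13)
        simulate_all(spec, tmp_path / "a")
        simulate_all(spec, tmp_path / "b")
        for name in ("genome.fa", "peaks_condition_a.bed", "rmsk.tsv",
                     "de_table.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
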
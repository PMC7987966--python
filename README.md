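# g4scape

G-quadruplex (G4) landscape analysis for ChIP-seq peak sets.

G-quadruplexes are four-stranded DNA structures built from stacked guanine
tetrads. Genome-wide, their formation potential is written in the sequence —
four runs of ≥ 3 guanines separated by 1–12 nt loops — while their actual
formation is read out by structure-specific antibodies (1H6, BG4) as ChIP-seq
peaks. `g4scape` is for researchers who have such peak sets and want to know:
which peaks contain predicted G4 motifs; whether peaks colocalize with repeat
families (LINE/L1, SINE/Alu), lamina-associated domains (LADs) or genomic
context more than chance; how peak sets differ between conditions; and
whether genes carrying intragenic peaks are transcriptionally biased.

## Core methods

- **Motif prediction** — greedy regex scan `(?:G{k,}\w{a,b}){r,}G{k,}` on
  both strands (canonical preset: k = 3, loops 1–12, 4 runs), plus an
  exhaustive QGRS-style G-score,
  `20·(t−2) + Σ(loop_max−lᵢ) − (max l − min l)`.
- **Permutation enrichment** — width-preserving random repositioning of
  peaks; Z = (obs − μ₀)/σ₀ and empirical p = (1 + #{null ≥ obs})/(N + 1).
- **Annotation** — non-exclusive membership fractions against repeats
  (UCSC rmsk tables), cLAD/fLAD maps and gene/enhancer/CpG context;
  per-set shared/specific peak comparison.
- **Expression linkage** — exact binomial tails for direction bias of a gene
  set against a baseline upregulated fraction (e.g. 51%):
  p_down = P(X ≤ k_up), p_up = P(X ≥ k_up), X ~ Binomial(n, p₀).
- **Synthetic studies** — a generator that plants G4-bearing repeat copies,
  peaks, LADs, DE tables and paired intensities with known truth, so the
  whole pipeline runs and is testable at desk scale.

## Worked example

Generate a synthetic study and test whether its peaks are enriched on the
conserved (G4-retaining) repeat copies:

```python
from g4scape import SimSpec, simulate_all, Interval, IntervalSet
from g4scape.region_enrichment import permutation_enrichment
from g4scape.feature_annotation import peak_repeat_profile

study = simulate_all(SimSpec(seed=3))
cons = study.repeat_truth[study.repeat_truth.conserved]
feature = IntervalSet(
    [Interval(r.chrom, int(r.start), int(r.end)) for r in cons.itertuples()],
    study.genome,
)
res = permutation_enrichment(study.peaks_a, feature, n_perm=1000, rng_seed=7)
print(f"observed={res.observed:.3f} null={res.null_mean:.4f} "
      f"z={res.z:.1f} p={res.p_emp:.5f}")
print(peak_repeat_profile(study.peaks_a, study.repeats, "class"))
```

prints

```
observed=0.915 null=0.0198 z=126.9 p=0.00100
LINE    0.9225
dtype: float64
```

91.5% of peaks sit on conserved repeat copies versus 2.0% expected for
randomly placed probes of the same widths — a Z-score of about 127 and the
smallest empirical p reachable with 1000 permutations (1/1001). The LINE
containment fraction (92%) recovers the planted peak-targeting rate (90%,
plus background peaks that land on repeats by chance).

The same operations are available from the shell:

```sh
g4scape simulate --seed 3 --out sim/
g4scape predict --fasta sim/genome.fa --preset canonical --out g4.bed
g4scape enrich --peaks sim/peaks_condition_a.bed --features g4.bed \
    --genome sim/genome.chrom.sizes --n-perm 1000 --seed 7 --out enrich.tsv
g4scape run --config config.yaml   # full pipeline -> report.json + TSVs
```

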
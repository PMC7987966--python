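# Methods

## Problem and scope

`g4scape` analyses the genomic landscape of G-quadruplexes (G4): four-stranded
DNA secondary structures formed by stacked guanine tetrads. Given a genome and
ChIP-seq peak sets obtained with a structure-specific antibody (e.g. 1H6), the
package answers five questions:

1. where canonical G4-forming motifs lie on the genome (sequence prediction);
2. how often peaks contain a predicted motif, and whether their colocalization
   with motifs, repeat families, or lamina-associated domains (LADs) exceeds a
   random-placement null (permutation enrichment);
3. how peaks partition across repeat families, LADs and genomic context
   (annotation);
4. how two peak sets (e.g. disease vs control neurons) relate (per-set
   shared/specific counts);
5. whether genes carrying intragenic peaks are biased toward up- or
   downregulation, and how peak classes relate to splicing-event calls
   (expression linkage).

Peak calling, read alignment, differential-expression estimation and image
segmentation are all upstream: the package consumes BED peak sets, a DE table,
splicing-call tables and extracted intensity vectors.

## Motif prediction

Canonical G4 motifs are found by a greedy regular-expression scan of the form
`(?:G{k,}\w{a,b}){r,}G{k,}` with k = minimum guanines per run, a..b = loop
length range and r = n_runs − 1. The canonical preset is k = 3, loops 1–12,
four runs; a strict preset (k = 5, loops 1–7) and two intermediate presets are
also named. Two consequences of regex semantics are deliberate:

- matches are leftmost and non-overlapping (scanning resumes at each match
  end), and
- the repetition is *at least* r, so a chain of five or more G-runs within
  loop distance is reported as one long motif, not several overlapping ones.

The minus strand is scanned on the reverse complement and mapped back to
forward coordinates. The test suite checks the scan against an independent
hand-written backtracking matcher on random sequences for all presets.

QGRS-style scoring is a separate, exhaustive enumeration: all placements of
four G-runs (length ≥ 2, loops 0–12) are scored with

    score = 20·(t − 2) + Σᵢ (loop_max − lᵢ) − (max l − min l)

where t is the minimum run length — rewarding more tetrads, shorter loops and
equal loops. The constants are this package's own; published QGRS Mapper
scores are produced by an unpublished implementation and are not expected to
match numerically. The enumeration is exhaustive and intended for motif-scale
sequences, not whole chromosomes.

## Peak annotation conventions

Coordinates are 0-based half-open throughout; an interval's length is
end − start and abutting intervals do not overlap. For G4 annotation, peaks
are first extended 50 bp on each side (clamped at chromosome ends) and then
intersected with the motif track; for repeat/LAD/context annotation no flank
is applied. Overlap means ≥ 1 shared base unless a larger `min_overlap` is
requested. Category membership is non-exclusive — a peak overlapping both an
L1 and an Alu counts in both LINE and SINE, so fractions can sum above 1 —
while "none of these"/"nonLAD" complements are computed on the union of
memberships and are exact. Strand is carried but ignored by overlap
arithmetic.

Peak-set comparison counts shared peaks per set: `shared_a` is the number of
a-peaks touching ≥ 1 b-peak, and can differ from `shared_b` when one very
large peak in one set contains several peaks of the other.

## Permutation null

Randomized probe sets preserve every peak's width; a chromosome is drawn with
probability proportional to its number of valid start positions
(length − width + 1) and the start is uniform. Probes may overlap each other
and no assembly-gap mask is applied (an exclusion list can be supplied). The
reported quantities are the permutation Z-score
(observed − null mean)/null sd and the empirical p-value with the +1
correction, p = (1 + #{null ≥ observed})/(n_perm + 1), one-sided for
enrichment by default. When the null is degenerate (sd = 0, e.g. a feature
covering the whole genome) the Z-score is reported as 0 with a `degenerate`
flag and the empirical p is 1 by the tie-counting rule. In
`multi_feature_enrichment` all features share the same randomized probe set
at each permutation index, so per-feature columns are directly comparable.

A note on calibration: with a coarse statistic (e.g. the overlapping-peak
fraction over few peaks) ties between observed and permuted values are
common and the empirical p is visibly conservative — this is a property of
the estimator, not an error. The calibration tests therefore use the
total-overlap-count statistic over fragmented feature sets, where the null
is fine-grained and the p-values are uniform to KS precision.

## Expression-direction test

For a gene set of interest, the number of direction-classified genes n and
the upregulated count k_up are compared against a genome-wide baseline
fraction (51% upregulated in the motivating contrast: 2006 up / 1924 down)
with exact binomial tails: p_down = P(X ≤ k_up) and p_up = P(X ≥ k_up) for
X ~ Binomial(n, baseline). Both one-sided tails are reported; their sum
exceeds 1 because they overlap at k_up. Direction comes from the sign of
log2 fold-change alone (genes at exactly 0 are excluded); no adjusted-p
filter is applied by default since the appropriate cutoff is caller-specific.

## Imaging statistics

Line-profile colocalization is plain Pearson correlation between two
channels. Per-cell grouping uses Lloyd's K-means (k = 2 or 3, 20 update
rounds with early exit on assignment convergence), with centers seeded as k
distinct data rows drawn by the seed using distance-weighted (k-means++)
sampling: uniform seeding of all k centers can stably place two centers in
one well-separated group, which defeats the intended use (splitting cell
populations by marker intensity). Box summaries report min, the 25th/75th
percentiles (linear interpolation) and max, with the center line at the
MEAN — an unusual convention retained on purpose to match the figures the
quantities feed.

## Synthetic study generator

The generator emulates the statistical structure of the real inputs so that
every pipeline stage has recoverable planted truth:

- **Genome**: i.i.d. bases, default 2 chromosomes × 2 Mb, GC 0.41
  (human-like). No repeats, isochores or gaps beyond what is planted.
- **Repeats**: 120 copies of a synthetic 1.2-kb L1-like consensus carrying
  exactly 3 canonical G4 motifs, placed without overlap. 40% of copies are
  "evolutionary conserved" (divergence 0, all motifs retained); the rest are
  degraded at a 20% per-base substitution rate — the scale of old L1
  elements — which destroys most embedded motifs. The consensus is a random
  backbone, not a RepBase/Dfam sequence.
- **Peaks**: 400 peaks (widths Normal(500, 150) truncated at 50 bp); each
  targets the center of a random conserved copy with probability 0.9, else
  uniform background. A second, 15% smaller control-like set is drawn from an
  independent stream over the same copies, so the two sets share peaks.
- **LADs**: the genome is tiled into 40-kb blocks and a random subset sized
  to 50% union coverage becomes LADs, split 60/40 into disjoint cLAD/fLAD.
- **Expression**: genes tile the genome; unflagged genes are upregulated with
  probability 0.51, flagged genes (those under condition-A-specific peaks,
  up to 50) with probability 0.2 — an 80% planted down-bias. Fold-change
  magnitudes are lognormal; p-values derive from a nominal SE with BH
  adjustment.
- **Intensities**: bivariate normal pairs at correlation 0.63, shifted and
  scaled to nonnegative arbitrary units.

All substreams fan out from one seed via fixed offsets, and every output is
byte-deterministic given the seed. What the generator does **not** emulate:
L1 indels and 5′ truncation gradients, GC isochores, assembly gaps,
read-level noise in peak calls, and correlated gene expression. Passing the
planted-truth tests therefore demonstrates the correctness of the
computations, not the biological effect sizes obtainable on real data.

## Problem sizes and numerical choices

Default analyses run on the 4-Mb synthetic genome with 1000 permutations —
seconds to a couple of minutes on one core; the calibration studies use 500
replicate tests at 200 permutations and the power study 100 replicate DE
tables, sizes chosen to give stable estimates at interactive run times.
Empirical p-values can never be exactly 0 by construction. K-means and all
generators take explicit integer seeds; ties in QGRS scoring break leftmost
then shortest; fractions are exact ratios of counts (no smoothing).

## Known limitations

- The motif scanner reproduces greedy regex semantics; tools that enumerate
  overlapping candidate quadruplexes will report more, shorter hits.
- The randomization null ignores GC composition and assembly gaps; on real
  genomes an exclusion BED should be supplied and GC-matched backgrounds are
  out of scope.
- QGRS scores are internally consistent but not comparable to QGRS Mapper
  output.
- Repeat "conservation" is taken from the annotation's divergence column if
  present (carried through, no default threshold), not inferred from
  alignment.
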
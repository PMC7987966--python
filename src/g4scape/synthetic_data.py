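"""Synthetic study generator: genomes with planted repeat copies, peak sets,
LAD maps, DE tables and paired intensities, with ground-truth sidecars.

Every generator is byte-deterministic given the SimSpec seed; one global seed
is fanned out to independent per-generator substreams via fixed offsets. The
default SimSpec is a desk-scale mirror of the study conditions: a 2 x 2 Mb
genome, 120 planted L1-like copies of which 40% are "evolutionary conserved"
(zero divergence, retaining their embedded canonical G4 motifs) and the rest
degraded, 400 peaks of which 90% target conserved copies, a LAD map covering
half the genome, 5000 genes with a 51% baseline upregulated fraction, and a
designated gene subset carrying a planted downregulation bias.

The repeat consensus shipped here is a synthetic stand-in for an L1
consensus: a random backbone with three canonical G4 motifs embedded, not a
real RepBase/Dfam sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm

from .coloc_stats import PairedIntensity
from .expression_link import SPLICING_CATEGORIES, DeRecord, SplicingCall
from .feature_annotation import GenomicContext, LadMap, RepeatRecord
from .genome_io import GenomeIndex, Interval, IntervalSet, write_bed, write_fasta
from .g4_predict import PRESETS, find_g4_motifs

# fixed substream offsets (one per generator)
_SUB_GENOME, _SUB_REPEATS, _SUB_PEAKS_A, _SUB_PEAKS_B = 1, 2, 3, 4
_SUB_LADS, _SUB_DE, _SUB_CONTEXT, _SUB_SPLICE, _SUB_INTENS = 5, 6, 7, 8, 9


@dataclass
class SimSpec:
    """Parameters of one synthetic study."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    gc_content: float = 0.41
    n_repeat_copies: int = 120
    conserved_fraction: float = 0.40
    divergence_rate: float = 0.20
    n_peaks: int = 400
    p_peak_on_conserved: float = 0.90
    peak_width: tuple[float, float] = (500.0, 150.0)  # (mean, sd) bp
    lad_coverage: float = 0.50
    n_genes: int = 5000
    frac_up: float = 0.51
    planted_down_bias: float = 0.80
    n_flagged_genes: int = 50
    seed: int = 0

    def __post_init__(self):
        for name, frac in (
            ("gc_content", self.gc_content),
            ("conserved_fraction", self.conserved_fraction),
            ("divergence_rate", self.divergence_rate),
            ("p_peak_on_conserved", self.p_peak_on_conserved),
            ("lad_coverage", self.lad_coverage),
            ("frac_up", self.frac_up),
            ("planted_down_bias", self.planted_down_bias),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, seed])


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def l1_like_consensus(
    length: int = 1200, n_motifs: int = 3, seed: int = 20_114
) -> str:
    """Synthetic L1-like consensus: random backbone with ``n_motifs`` embedded
    canonical G4 motifs, verified to contain exactly that many canonical-preset
    matches (both strands). Deterministic; not a real L1 consensus."""
    motif = "GGGTTAGGGTTAGGGTTAGGG"  # 4 G-runs of 3, loops of 2
    params = PRESETS["canonical"]
    rng = np.random.default_rng(seed)
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3]))
        positions = np.linspace(length // 8, length - length // 8 - len(motif),
                                n_motifs).astype(int)
        chars = list(seq)
        for pos in positions:
            chars[pos : pos + len(motif)] = motif
        candidate = "".join(chars)
        if len(find_g4_motifs(candidate, params, "both")) == n_motifs:
            return candidate
    raise RuntimeError("could not build a clean consensus (unexpected)")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_genome(spec: SimSpec) -> tuple[dict[str, str], GenomeIndex]:
    """I.i.d. random genome at the requested GC content."""
    rng = _rng(spec.seed, _SUB_GENOME)
    gc, at = spec.gc_content / 2, (1 - spec.gc_content) / 2
    seqs = {
        name: "".join(rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at]))
        for name, length in spec.chrom_lengths.items()
    }
    return seqs, GenomeIndex(spec.chrom_lengths)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.array(list("ACGT"), dtype="S1")
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def plant_repeats(
    seqs: dict[str, str],
    spec: SimSpec,
    consensus: str | None = None,
    max_tries_per_copy: int = 200,
) -> tuple[dict[str, str], list[RepeatRecord], pd.DataFrame]:
    """Plant non-overlapping consensus copies; mutate the degraded ones.

    Conserved copies are inserted verbatim (divergence 0); degraded copies
    are substituted per-base at ``divergence_rate``. Returns the mutated
    genome, rmsk-style records (milli_div = 1000 x divergence), and a truth
    table listing, per copy, which planted canonical motifs survived
    mutation (re-scanned with the canonical preset on the copy sequence).
    """
    consensus = consensus or l1_like_consensus()
    clen = len(consensus)
    genome = GenomeIndex({c: len(s) for c, s in seqs.items()})
    for chrom in genome:
        if clen >= genome[chrom]:
            raise ValueError("consensus longer than a chromosome")
    rng = _rng(spec.seed, _SUB_REPEATS)
    names = genome.names
    lengths = np.array([genome[c] for c in names], dtype=np.int64)
    slots = lengths - clen + 1
    probs = slots / slots.sum()

    n_cons = int(round(spec.n_repeat_copies * spec.conserved_fraction))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    records: list[RepeatRecord] = []
    truth_rows = []
    chars = {c: list(s) for c, s in seqs.items()}
    params = PRESETS["canonical"]
    for copy_i in range(spec.n_repeat_copies):
        conserved = copy_i < n_cons
        for _ in range(max_tries_per_copy):
            ci = rng.choice(len(names), p=probs)
            chrom = names[ci]
            start = int(rng.integers(0, lengths[ci] - clen + 1))
            end = start + clen
            if all(end <= s or start >= e for s, e in placed[chrom]):
                break
        else:
            raise RuntimeError("could not place all repeat copies without overlap")
        placed[chrom].append((start, end))
        copy_seq = consensus if conserved else _mutate(
            consensus, spec.divergence_rate, rng
        )
        chars[chrom][start:end] = copy_seq
        rep_name = "L1synA" if conserved else "L1synB"
        milli_div = 0 if conserved else int(round(spec.divergence_rate * 1000))
        records.append(
            RepeatRecord(
                Interval(chrom, start, end, name=rep_name),
                repeat_name=rep_name, repeat_class="LINE", repeat_family="L1",
                milli_div=milli_div,
            )
        )
        retained = find_g4_motifs(copy_seq, params, "both")
        truth_rows.append(
            {
                "copy_id": copy_i, "chrom": chrom, "start": start, "end": end,
                "conserved": conserved, "n_motifs_retained": len(retained),
                "motif_starts": [start + m.start for m in retained],
            }
        )
    mutated = {c: "".join(chars[c]) for c in names}
    return mutated, records, pd.DataFrame(truth_rows)


def simulate_peaks(
    repeats: list[RepeatRecord],
    truth: pd.DataFrame,
    spec: SimSpec,
    genome: GenomeIndex,
    substream: int = _SUB_PEAKS_A,
    n_peaks: int | None = None,
) -> tuple[IntervalSet, list[str]]:
    """Peaks targeting conserved repeat copies with probability
    ``p_peak_on_conserved``, else uniform background. Widths are normal,
    truncated at 50 bp. Returns the peaks and per-peak truth labels."""
    rng = _rng(spec.seed, substream)
    n_peaks = spec.n_peaks if n_peaks is None else n_peaks
    conserved = truth[truth.conserved]
    if spec.p_peak_on_conserved > 0 and len(conserved) == 0:
        raise ValueError("no conserved copies to target")
    names = genome.names
    lengths = np.array([genome[c] for c in names], dtype=np.int64)
    mean_w, sd_w = spec.peak_width
    intervals, labels = [], []
    for i in range(n_peaks):
        width = max(50, int(round(rng.normal(mean_w, sd_w))))
        if rng.random() < spec.p_peak_on_conserved:
            row = conserved.iloc[int(rng.integers(0, len(conserved)))]
            center = (int(row.start) + int(row.end)) // 2
            chrom, L = row.chrom, genome[row.chrom]
            label = "on_conserved"
        else:
            probs = np.maximum(lengths - width + 1, 0)
            probs = probs / probs.sum()
            ci = rng.choice(len(names), p=probs)
            chrom, L = names[ci], int(lengths[ci])
            center = int(rng.integers(width // 2, L - width + width // 2 + 1))
            label = "background"
        start = max(0, min(center - width // 2, L - width))
        intervals.append(Interval(chrom, start, start + width, name=f"peak_{i}"))
        labels.append(label)
    return IntervalSet(intervals, genome), labels


def simulate_lads(
    genome: GenomeIndex, spec: SimSpec, block_size: int = 40_000
) -> LadMap:
    """Block-based LAD map hitting the target union coverage.

    The genome is tiled into fixed-size blocks; a random subset sized to the
    target coverage becomes LADs, split 60/40 between cLADs and fLADs
    (disjoint by construction)."""
    if spec.lad_coverage >= 1:
        raise ValueError("lad_coverage must be < 1")
    rng = _rng(spec.seed, _SUB_LADS)
    blocks = []
    for chrom in genome:
        L = genome[chrom]
        for s in range(0, L, block_size):
            blocks.append(Interval(chrom, s, min(s + block_size, L)))
    n_lad = int(round(spec.lad_coverage * len(blocks)))
    chosen = rng.choice(len(blocks), size=n_lad, replace=False) if n_lad else []
    n_clad = int(round(0.6 * n_lad))
    clad = [blocks[i] for i in sorted(chosen[:n_clad])]
    flad = [blocks[i] for i in sorted(chosen[n_clad:])]
    return LadMap(IntervalSet(clad, genome), IntervalSet(flad, genome))


def tile_genes(genome: GenomeIndex, n_genes: int) -> IntervalSet:
    """Tile the genome with ``n_genes`` non-overlapping named gene bodies,
    apportioned to chromosomes by length."""
    total = genome.total_length
    counts = {c: max(1, int(round(n_genes * genome[c] / total))) for c in genome}
    intervals = []
    gi = 0
    for chrom in genome:
        w = genome[chrom] // counts[chrom]
        for i in range(counts[chrom]):
            gi += 1
            intervals.append(
                Interval(chrom, i * w, i * w + w, name=f"gene{gi:05d}")
            )
    return IntervalSet(intervals, genome)


def simulate_de_table(
    spec: SimSpec,
    flagged_genes: set[str] | None = None,
    genes: IntervalSet | None = None,
    genome: GenomeIndex | None = None,
) -> tuple[list[DeRecord], IntervalSet, set[str]]:
    """Differential-expression table over a tiled gene universe.

    Unflagged genes are upregulated with probability ``frac_up``; flagged
    genes with probability ``1 - planted_down_bias``. Fold-change magnitudes
    are lognormal; p-values follow from a nominal SE of 0.25 with BH
    adjustment."""
    rng = _rng(spec.seed, _SUB_DE)
    if genes is None:
        genome = genome or GenomeIndex(spec.chrom_lengths)
        genes = tile_genes(genome, spec.n_genes)
    gene_ids = [iv.name for iv in genes]
    if flagged_genes is None:
        flagged_genes = set(
            rng.choice(gene_ids, size=min(spec.n_flagged_genes, len(gene_ids)),
                       replace=False)
        )
    unknown = flagged_genes - set(gene_ids)
    if unknown:
        raise ValueError(f"flagged genes outside the gene universe: {sorted(unknown)[:3]}")
    records = []
    for gid in gene_ids:
        p_up = (1 - spec.planted_down_bias) if gid in flagged_genes else spec.frac_up
        sign = 1.0 if rng.random() < p_up else -1.0
        mag = float(rng.lognormal(mean=-0.7, sigma=0.6))
        lfc = sign * max(mag, 1e-6)
        pval = float(2 * norm.sf(abs(lfc) / 0.25))
        records.append(DeRecord(gid, lfc, pval, None))
    padj = false_discovery_control([r.pvalue for r in records])
    records = [
        DeRecord(r.gene_id, r.log2fc, r.pvalue, float(q))
        for r, q in zip(records, padj)
    ]
    return records, genes, flagged_genes


def simulate_context(
    genome: GenomeIndex, genes: IntervalSet, spec: SimSpec,
    n_enhancers: int = 150, n_cpg: int = 80,
) -> GenomicContext:
    """Gene bodies plus random enhancer (400 bp) and CpG-island (500 bp) sets."""
    rng = _rng(spec.seed, _SUB_CONTEXT)
    names = genome.names
    lengths = np.array([genome[c] for c in names], dtype=np.int64)

    def random_set(n, width):
        probs = (lengths - width + 1) / (lengths - width + 1).sum()
        out = []
        for _ in range(n):
            ci = rng.choice(len(names), p=probs)
            s = int(rng.integers(0, lengths[ci] - width + 1))
            out.append(Interval(names[ci], s, s + width))
        return IntervalSet(out, genome)

    return GenomicContext(genes, random_set(n_enhancers, 400), random_set(n_cpg, 500))


def simulate_splicing_calls(
    gene_ids, spec: SimSpec, p_call: float = 1.0
) -> list[SplicingCall]:
    """Assign each given gene a splicing-event call with probability
    ``p_call``; the category is drawn uniformly from the fixed vocabulary."""
    rng = _rng(spec.seed, _SUB_SPLICE)
    calls = []
    for gid in sorted(gene_ids):
        if rng.random() <= p_call:
            calls.append(SplicingCall(gid, str(rng.choice(SPLICING_CATEGORIES))))
    return calls


def simulate_paired_intensities(
    rho: float, n: int, seed: int = 0
) -> PairedIntensity:
    """Bivariate-normal paired intensity profile with correlation ``rho``,
    shifted/scaled to nonnegative arbitrary units."""
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("|rho| must be <= 1")
    rng = _rng(seed, _SUB_INTENS)
    cov = [[1.0, rho], [rho, 1.0]]
    # svd handles the singular |rho| = 1 boundary
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd")
    xy = np.clip(100.0 + 20.0 * xy, 0.0, None)
    return PairedIntensity(xy[:, 0], xy[:, 1], label=f"rho={rho}")


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    spec: SimSpec
    seqs: dict[str, str]
    genome: GenomeIndex
    repeats: list[RepeatRecord]
    repeat_truth: pd.DataFrame
    peaks_a: IntervalSet
    peaks_a_labels: list[str]
    peaks_b: IntervalSet
    peaks_b_labels: list[str]
    lads: LadMap
    genes: IntervalSet
    context: GenomicContext
    de: list[DeRecord]
    flagged_genes: set[str]
    splicing_calls: list[SplicingCall]
    intensities: PairedIntensity


def simulate_all(spec: SimSpec, outdir: str | Path | None = None) -> SimulatedStudy:
    """Generate one full synthetic study; optionally write all standard-format
    files (FASTA/BED/rmsk-TSV/DE-TSV) plus a JSON truth sidecar to ``outdir``.

    Condition A mirrors the disease-like peak set; condition B is a smaller
    control-like set drawn from an independent substream over the same
    conserved copies (so the two sets share peaks). Flagged (down-biased)
    genes are those hit by condition-A-specific peaks, capped at
    ``n_flagged_genes``.
    """
    from .expression_link import assign_peaks_to_genes
    from .feature_annotation import compare_peaksets
    from .genome_io import OverlapIndex

    seqs0, genome = make_genome(spec)
    seqs, repeats, truth = plant_repeats(seqs0, spec)
    peaks_a, labels_a = simulate_peaks(repeats, truth, spec, genome, _SUB_PEAKS_A)
    peaks_b, labels_b = simulate_peaks(
        repeats, truth, spec, genome, _SUB_PEAKS_B,
        n_peaks=max(1, int(round(0.85 * spec.n_peaks))),
    )
    lads = simulate_lads(genome, spec)
    genes = tile_genes(genome, spec.n_genes)

    # flagged genes = genes under condition-A-specific peaks
    b_index = OverlapIndex(peaks_b)
    a_specific = IntervalSet(
        [p for p in peaks_a if b_index.count(p) == 0], genome
    )
    flagged: set[str] = set()
    if len(a_specific):
        for gene_set in assign_peaks_to_genes(a_specific, genes):
            flagged.update(gene_set)
    flagged = set(sorted(flagged)[: spec.n_flagged_genes])
    de, genes, flagged = simulate_de_table(spec, flagged, genes=genes)
    context = simulate_context(genome, genes, spec)
    calls = simulate_splicing_calls(flagged, spec)
    intensities = simulate_paired_intensities(0.63, 300, seed=spec.seed)

    study = SimulatedStudy(
        spec, seqs, genome, repeats, truth, peaks_a, labels_a, peaks_b, labels_b,
        lads, genes, context, de, flagged, calls, intensities,
    )
    if outdir is not None:
        _write_study(study, Path(outdir))
    return study


def _write_study(study: SimulatedStudy, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.seqs, outdir / "genome.fa")
    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for chrom, length in study.genome.items():
            fh.write(f"{chrom}\t{length}\n")
    write_bed(study.peaks_a, outdir / "peaks_condition_a.bed")
    write_bed(study.peaks_b, outdir / "peaks_condition_b.bed")
    with open(outdir / "rmsk.tsv", "w") as fh:
        for r in study.repeats:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.repeat_name}\t{r.repeat_class}\t{r.repeat_family}\t"
                f"{r.milli_div if r.milli_div is not None else ''}\n"
            )
    write_bed(study.lads.clad, outdir / "clad.bed")
    write_bed(study.lads.flad, outdir / "flad.bed")
    write_bed(study.genes, outdir / "genes.bed")
    write_bed(study.context.enhancers, outdir / "enhancers.bed")
    write_bed(study.context.cpg_islands, outdir / "cpg_islands.bed")
    with open(outdir / "de_table.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tpadj\n")
        for r in study.de:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t{r.padj:.6g}\n")
    with open(outdir / "splicing_calls.tsv", "w") as fh:
        fh.write("gene_id\tcategory\n")
        for c in study.splicing_calls:
            fh.write(f"{c.gene_id}\t{c.category}\n")
    with open(outdir / "intensities.tsv", "w") as fh:
        fh.write("label\tposition\tchannel_a\tchannel_b\n")
        for i, (a, b) in enumerate(zip(study.intensities.a, study.intensities.b)):
            fh.write(f"{study.intensities.label}\t{i}\t{a:.4f}\t{b:.4f}\n")
    truth = {
        "seed": study.spec.seed,
        "repeat_copies": study.repeat_truth.to_dict(orient="records"),
        "peaks_a_labels": study.peaks_a_labels,
        "peaks_b_labels": study.peaks_b_labels,
        "flagged_genes": sorted(study.flagged_genes),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=int)
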
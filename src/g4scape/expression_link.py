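"""Link peak classes to genes, expression direction, and splicing events.

The direction test asks whether genes in a set are up- or downregulated more
often than the genome-wide baseline (e.g. 51% of genes upregulated in the
disease condition), using exact binomial tail probabilities. Direction is
taken from the sign of the log2 fold-change alone; genes with log2fc == 0 are
excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binom

from .genome_io import IntervalSet, OverlapIndex

SPLICING_CATEGORIES = ("minor_isoform_loss", "gap_junction", "cryptic_fusion")


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression contrast (condition vs control)."""

    gene_id: str
    log2fc: float
    pvalue: float | None = None
    padj: float | None = None

    def __post_init__(self):
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj {self.padj} outside [0, 1] for {self.gene_id}")

    @property
    def direction(self) -> str | None:
        """'up', 'down', or None when log2fc is exactly 0."""
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return None


@dataclass(frozen=True)
class PeakClass:
    """A named peak class (e.g. lost/common/gained) with its gene set."""

    label: str
    genes: frozenset[str]


@dataclass(frozen=True)
class SplicingCall:
    gene_id: str
    category: str

    def __post_init__(self):
        if self.category not in SPLICING_CATEGORIES:
            raise ValueError(
                f"unknown splicing category {self.category!r}; "
                f"expected one of {SPLICING_CATEGORIES}"
            )


def read_de_table(path) -> list[DeRecord]:
    """TSV with required header gene_id, log2fc, pvalue, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE table columns {sorted(missing)}")
    return [
        DeRecord(
            str(r.gene_id),
            float(r.log2fc),
            None if pd.isna(r.pvalue) else float(r.pvalue),
            None if pd.isna(r.padj) else float(r.padj),
        )
        for r in df.itertuples()
    ]


def read_splicing_calls(path) -> list[SplicingCall]:
    """TSV with header gene_id, category."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing splicing columns {sorted(missing)}")
    return [SplicingCall(str(r.gene_id), str(r.category)) for r in df.itertuples()]


def assign_peaks_to_genes(
    peaks: IntervalSet, genes: IntervalSet
) -> list[frozenset[str]]:
    """Per-peak set of gene names whose bodies the (unextended) peak overlaps.

    Gene intervals must be named; intergenic peaks get an empty set.
    """
    for iv in genes:
        if iv.name is None:
            raise ValueError(f"unnamed gene interval {iv.chrom}:{iv.start}-{iv.end}")
    index = OverlapIndex(genes)
    gene_names = [iv.name for iv in genes]
    return [
        frozenset(gene_names[i] for i in index.hits(peak)) for peak in peaks
    ]


def upregulated_fraction(de: Iterable[DeRecord]) -> float:
    """up / (up + down) over direction-classified genes (log2fc != 0)."""
    up = down = 0
    for rec in de:
        if rec.direction == "up":
            up += 1
        elif rec.direction == "down":
            down += 1
    if up + down == 0:
        raise ValueError("no direction-classified genes in DE table")
    return up / (up + down)


def direction_binomial_test(
    genes: Iterable[str], de: Iterable[DeRecord], baseline_up: float
) -> dict:
    """Exact binomial tails for expression-direction bias in a gene set.

    With n direction-classified genes in the set and k_up of them
    upregulated, against a genome-wide baseline probability ``baseline_up``:

        p_enriched_down = P(X <= k_up),   p_enriched_up = P(X >= k_up),
        X ~ Binomial(n, baseline_up).

    Both one-sided tails are reported (their sum is >= 1 since they overlap
    at k_up). Genes absent from the DE table or with log2fc == 0 are ignored.
    """
    if not (0.0 < baseline_up < 1.0):
        raise ValueError("baseline_up must be in (0, 1)")
    gene_set = set(genes)
    n = k_up = 0
    for rec in de:
        if rec.gene_id in gene_set and rec.direction is not None:
            n += 1
            if rec.direction == "up":
                k_up += 1
    if n == 0:
        raise ValueError("gene set has no direction-classified genes in DE table")
    return {
        "n": n,
        "k_up": k_up,
        "p_enriched_down": float(binom.cdf(k_up, n, baseline_up)),
        "p_enriched_up": float(binom.sf(k_up - 1, n, baseline_up)),
    }


def summarize_peak_splicing(
    classes: Iterable[PeakClass],
    calls: Iterable[SplicingCall],
    de: Iterable[DeRecord],
    baseline_up: float | None = None,
) -> pd.DataFrame:
    """Per-class summary of splicing-event burden and direction bias.

    For each peak class: number of genes, number with any splicing call,
    counts per category, and the binomial direction test restricted to genes
    with a splicing call. When the baseline is not given it is computed from
    the DE table itself. Classes whose splicing-call genes have no usable
    direction get NaN p-values and ``tested = False``.
    """
    de = list(de)
    if baseline_up is None:
        baseline_up = upregulated_fraction(de)
    calls_by_gene: dict[str, list[str]] = {}
    for call in calls:
        calls_by_gene.setdefault(call.gene_id, []).append(call.category)
    rows = []
    for cls in classes:
        spliced = sorted(g for g in cls.genes if g in calls_by_gene)
        row = {
            "class": cls.label,
            "n_genes": len(cls.genes),
            "n_with_splicing": len(spliced),
        }
        for cat in SPLICING_CATEGORIES:
            row[cat] = sum(
                cat in calls_by_gene[g] for g in spliced
            )
        try:
            test = direction_binomial_test(spliced, de, baseline_up) if spliced else None
        except ValueError:
            test = None
        if test is None:
            row.update(n_tested=0, k_up=0, p_enriched_down=float("nan"),
                       p_enriched_up=float("nan"), tested=False)
        else:
            row.update(
                n_tested=test["n"], k_up=test["k_up"],
                p_enriched_down=test["p_enriched_down"],
                p_enriched_up=test["p_enriched_up"], tested=True,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
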
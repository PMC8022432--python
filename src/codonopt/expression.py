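"""FPKM expression tables and the high/low/tissue-exclusive gene sets.

The study design measures expression in nine tissues (four paired
male/female tissues plus the male accessory glands), each with replicate
RNA-seq samples.  Organism-wide expression for a gene is the unweighted
mean of its nine tissue means (replicates averaged within tissue first, so
unequal replicate counts do not weight tissues).

Gene sets:

* ``select_extremes`` - top and bottom 5% of genes by a chosen expression
  basis, with every gene tied at the boundary value included on both tails.
* ``top5_one_tissue`` - genes in the top 5% of exactly one tissue and
  outside the top 5% of all other tissues; the nine sets are disjoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical nine tissue labels of the study design
TISSUES = (
    "female_gonad",
    "male_gonad",
    "female_somatic_repro",
    "male_somatic_repro",
    "female_brain",
    "male_brain",
    "female_nerve_cord",
    "male_nerve_cord",
    "male_accessory_glands",
)

#: paired male/female tissues for between-sex contrasts
SEX_PAIRED_TISSUES = ("gonad", "somatic_repro", "brain", "nerve_cord")


@dataclass
class ExpressionTable:
    """Genes x samples FPKM matrix with a sample -> tissue grouping."""

    fpkm: pd.DataFrame  # index gene_ids, columns sample_ids
    sample_to_tissue: dict

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("negative FPKM values are not allowed")
        unmapped = [s for s in self.fpkm.columns if s not in self.sample_to_tissue]
        if unmapped:
            raise ValueError(f"samples without tissue mapping: {unmapped}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.fpkm.columns:
            seen.setdefault(self.sample_to_tissue[s], None)
        return list(seen)

    def tissue_means(self) -> pd.DataFrame:
        """Per-gene mean FPKM within each tissue (replicates averaged)."""
        groups = pd.Series(
            {s: self.sample_to_tissue[s] for s in self.fpkm.columns}
        )
        return self.fpkm.T.groupby(groups).mean().T


@dataclass(frozen=True)
class GeneSetSelection:
    """High/low expression gene sets with the FPKM cutoffs that defined them."""

    high: frozenset
    low: frozenset
    cutoff_high: float
    cutoff_low: float
    basis: str

    def __post_init__(self) -> None:
        if self.high & self.low:
            raise ValueError("high and low gene sets overlap")


def load_expression(path, tissue_map: dict) -> ExpressionTable:
    """Load a tab-separated FPKM matrix (first column gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(fpkm=df, sample_to_tissue=dict(tissue_map))


def write_expression(table: ExpressionTable, path) -> None:
    table.fpkm.to_csv(path, sep="\t", index_label="gene_id")


def mean_expression(
    table: ExpressionTable,
    level: str = "organism",
    tissue: str | None = None,
    replicate_weighted: bool = False,
) -> pd.Series:
    """Per-gene mean FPKM at tissue or organism level.

    ``organism`` level averages the tissue means (two-stage mean) unless
    ``replicate_weighted`` asks for the flat mean over all samples.
    """
    if level == "tissue":
        if tissue is None:
            raise ValueError("tissue level requires a tissue label")
        tm = table.tissue_means()
        if tissue not in tm.columns:
            raise ValueError(f"unknown tissue label {tissue!r}")
        return tm[tissue]
    if level == "organism":
        if replicate_weighted:
            return table.fpkm.mean(axis=1)
        return table.tissue_means().mean(axis=1)
    raise ValueError(f"unknown level {level!r}")


def select_extremes(
    values, fraction: float = 0.05, include_ties: bool = True,
    basis: str = "organism_wide",
) -> GeneSetSelection:
    """Top/bottom ``fraction`` of genes by value, with boundary ties included."""
    if not (0.0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5)")
    series = pd.Series(values, dtype=float)
    n = series.size
    if n < 40:
        raise ValueError("need >= 40 genes to select expression extremes")
    k = math.ceil(fraction * n)
    order = series.sort_values(ascending=False, kind="mergesort")
    cutoff_high = float(order.iloc[k - 1])
    cutoff_low = float(order.iloc[n - k])
    if include_ties:
        high = frozenset(series.index[series >= cutoff_high])
        low = frozenset(series.index[series <= cutoff_low])
    else:
        high = frozenset(order.index[:k])
        low = frozenset(order.index[n - k:])
    if high & low:
        raise ValueError(
            "expression extremes overlap; the value distribution is too flat "
            "for the requested fraction"
        )
    return GeneSetSelection(
        high=high, low=low, cutoff_high=cutoff_high,
        cutoff_low=cutoff_low, basis=basis,
    )


def top_fraction(values, fraction: float = 0.05) -> frozenset:
    """Genes in the top ``fraction`` by value, boundary ties included."""
    series = pd.Series(values, dtype=float)
    k = math.ceil(fraction * series.size)
    order = series.sort_values(ascending=False, kind="mergesort")
    cutoff = float(order.iloc[k - 1])
    return frozenset(series.index[series >= cutoff])


def top5_one_tissue(
    table: ExpressionTable, tissue: str, fraction: float = 0.05
) -> frozenset:
    """Genes in the top fraction of ``tissue`` and of no other tissue."""
    tm = table.tissue_means()
    if tissue not in tm.columns:
        raise ValueError(f"unknown tissue label {tissue!r}")
    tops = {t: top_fraction(tm[t], fraction) for t in tm.columns}
    exclusive = set(tops[tissue])
    for other, members in tops.items():
        if other != tissue:
            exclusive -= members
    return frozenset(exclusive)


def write_gene_set(genes, path, basis: str, cutoffs=None) -> None:
    """One-column gene list with a header comment recording provenance."""
    with open(path, "w") as fh:
        fh.write(f"# basis: {basis}\n")
        if cutoffs is not None:
            fh.write(f"# cutoff_high: {cutoffs[0]!r}\tcutoff_low: {cutoffs[1]!r}\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")
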
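"""Intron composition as a mutational-bias control for codon selection.

Intron AT content (AT-I) tracks the background neutral pressures (mutation,
biased gene conversion) acting on a gene's neighbourhood.  If AT-ending
codon preference in highly expressed genes were purely mutational, genes
with the same AT-I should show the same AT3 regardless of expression.  The
control therefore bins highly and lowly expressed genes into narrow AT-I
bins (<=0.5, >0.5-0.6, >0.6-0.7, >0.7-0.8, >0.8) and contrasts AT3 between
expression groups within each bin (Mann-Whitney U), alongside the AT-I
contrast itself, which should be null within a bin.

The module also provides the expression-composition Spearman correlations
(AT-I or AT3 vs mean FPKM) and the longest-intron length contrast between
expression extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stat_core import TestResult, mann_whitney_u, spearman

DEFAULT_ATI_EDGES = (0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class GeneCompositionRecord:
    """Per-gene composition and expression summary for the control."""

    gene_id: str
    at_i: float
    at3: float
    at_cds: float
    expression_mean: float
    intron_raw_length: int


@dataclass(frozen=True)
class AtiBinComparison:
    bin_label: str
    n_high: int
    n_low: int
    median_at3_high: float
    median_at3_low: float
    mwu_p_at3: float
    median_ati_high: float
    median_ati_low: float
    mwu_p_ati: float
    tested: bool


def at_content(seq: str) -> float:
    """(A + T) / (A + C + G + T); N bases excluded from both sides."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["A"] + counts["T"]) / denom


def bin_labels(edges=DEFAULT_ATI_EDGES) -> list[str]:
    labels = [f"<={edges[0]}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f">{lo}-{hi}")
    labels.append(f">{edges[-1]}")
    return labels


def bin_by_ati(records, edges=DEFAULT_ATI_EDGES) -> dict:
    """Partition records into AT-I bins (first closed below, rest (lo, hi])."""
    edges = tuple(edges)
    if list(edges) != sorted(edges):
        raise ValueError("bin edges must be sorted ascending")
    labels = bin_labels(edges)
    bins: dict[str, list] = {lab: [] for lab in labels}
    for rec in records:
        ati = rec.at_i
        if np.isnan(ati):
            raise ValueError(f"gene {rec.gene_id} has undefined AT-I")
        idx = 0
        for i, edge in enumerate(edges):
            if ati > edge:
                idx = i + 1
        bins[labels[idx]].append(rec)
    return bins


def binned_at3_comparison(high, low, edges=DEFAULT_ATI_EDGES) -> list:
    """Per-bin MWU contrasts of AT3 (the signal) and AT-I (the control).

    Bins with fewer than two genes in either group are reported with their
    counts and medians but not tested (a one-gene bar carries no contrast).
    """
    bins_high = bin_by_ati(high, edges)
    bins_low = bin_by_ati(low, edges)
    out = []
    for label in bin_labels(edges):
        h = bins_high[label]
        l = bins_low[label]
        at3_h = np.array([r.at3 for r in h])
        at3_l = np.array([r.at3 for r in l])
        ati_h = np.array([r.at_i for r in h])
        ati_l = np.array([r.at_i for r in l])
        tested = len(h) >= 2 and len(l) >= 2
        if tested:
            p_at3 = mann_whitney_u(at3_h, at3_l).p_value
            p_ati = mann_whitney_u(ati_h, ati_l).p_value
        else:
            p_at3 = p_ati = float("nan")
        out.append(
            AtiBinComparison(
                bin_label=label, n_high=len(h), n_low=len(l),
                median_at3_high=float(np.median(at3_h)) if len(h) else float("nan"),
                median_at3_low=float(np.median(at3_l)) if len(l) else float("nan"),
                mwu_p_at3=p_at3,
                median_ati_high=float(np.median(ati_h)) if len(h) else float("nan"),
                median_ati_low=float(np.median(ati_l)) if len(l) else float("nan"),
                mwu_p_ati=p_ati,
                tested=tested,
            )
        )
    return out


def expression_composition_correlation(records, which: str = "at_i") -> TestResult:
    """Spearman of AT-I or AT3 against organism-wide mean expression."""
    if len(records) < 10:
        raise ValueError("need >= 10 records for a composition correlation")
    attr = {"at_i": "at_i", "at3": "at3"}[which]
    x = np.array([getattr(r, attr) for r in records])
    y = np.array([r.expression_mean for r in records])
    return spearman(x, y)


def intron_length_comparison(high, low, use_means: bool = False) -> tuple:
    """(low/high length ratio, two-sided MWU p) on raw longest-intron lengths."""
    if not high or not low:
        raise ValueError("both groups must be non-empty")
    lh = np.array([r.intron_raw_length for r in high], dtype=float)
    ll = np.array([r.intron_raw_length for r in low], dtype=float)
    center = np.mean if use_means else np.median
    fold = float(center(ll) / center(lh))
    p = mann_whitney_u(ll, lh).p_value
    return fold, p


def boxplot_data(records_by_group: dict) -> dict:
    """Quartile summaries (min/q1/median/q3/max) per group, JSON-ready."""
    out = {}
    for label, values in records_by_group.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[label] = {
            "n": int(v.size), "min": float(v.min()), "q1": float(q1),
            "median": float(med), "q3": float(q3), "max": float(v.max()),
        }
    return out
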
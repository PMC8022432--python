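"""Amino-acid usage versus biosynthetic cost, hydropathy, folding, tRNAs.

Per-gene amino-acid frequencies (percent of residues) are summarised as a
mean +- SE across a gene set and related to three per-residue properties:

* the Dufton size/complexity (S/C) score, a biosynthetic-cost proxy
  ranging from 1 (Gly) to 73 (Trp);
* Kyte-Doolittle hydropathy (positive = hydrophobic);
* a three-way secondary-structure propensity class (alpha-helix former,
  beta-sheet former, breaker).

Correlations "across the 20 amino acids" use the mean frequencies; a
gene-level mode that pools per-gene frequency/property pairs is provided
for the hydropathy analysis, whose published form is gene-based.  High- vs
low-expression contrasts are per-amino-acid Welch t-tests on per-gene
percent frequencies with Bonferroni correction over the 20 tests; percent
difference follows the (high - low) / high x 100 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import AA_THREE, STANDARD_CODE, GeneticCode
from .stat_core import TestResult, bonferroni, rank_anova, spearman, welch_t

#: Dufton S/C biosynthetic-cost scores (as used in the packaged usage table)
SC_SCORES = {
    "G": 1.00, "A": 4.76, "V": 12.28, "I": 16.04, "L": 16.04, "S": 17.86,
    "T": 21.62, "K": 30.14, "P": 31.80, "D": 32.72, "N": 33.72, "E": 36.48,
    "Q": 37.48, "F": 44.00, "R": 56.34, "Y": 57.00, "C": 57.16, "H": 58.70,
    "M": 64.68, "W": 73.00,
}

#: Kyte-Doolittle hydropathy index
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Chou-Fasman-style secondary-structure propensity classes
FOLDING_CLASS = {
    "A": "alpha", "E": "alpha", "Q": "alpha", "L": "alpha", "K": "alpha",
    "M": "alpha", "H": "alpha", "R": "alpha",
    "V": "beta", "I": "beta", "Y": "beta", "C": "beta", "W": "beta",
    "F": "beta", "T": "beta",
    "G": "breaker", "P": "breaker", "N": "breaker", "D": "breaker",
    "S": "breaker",
}


def amino_acid_properties(
    sc_scores: dict | None = None,
    hydropathy: dict | None = None,
    folding_class: dict | None = None,
) -> pd.DataFrame:
    """Per-amino-acid property table (20 rows), overridable for sensitivity."""
    sc = sc_scores or SC_SCORES
    hyd = hydropathy or HYDROPATHY
    fold = folding_class or FOLDING_CLASS
    aas = sorted(AA_THREE)
    if set(sc) != set(aas) or set(hyd) != set(aas) or set(fold) != set(aas):
        raise ValueError("property tables must cover exactly the 20 amino acids")
    return pd.DataFrame(
        {
            "sc_score": [sc[a] for a in aas],
            "hydropathy": [hyd[a] for a in aas],
            "folding_class": [fold[a] for a in aas],
        },
        index=pd.Index(aas, name="amino_acid"),
    )


@dataclass(frozen=True)
class AminoAcidUsageTable:
    """Mean +- SE percent usage per amino acid across a gene set."""

    mean_freq: pd.Series   # percent, indexed by one-letter amino acid
    se: pd.Series
    n_genes: int
    context: str


@dataclass(frozen=True)
class AaComparisonRecord:
    amino_acid: str
    freq_high: float
    freq_low: float
    percent_diff: float   # (high - low) / high * 100
    t_stat: float
    p_raw: float
    p_bonf: float


def per_gene_frequencies(
    genes, code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Percent residue frequencies, genes x 20 amino acids (rows sum to 100)."""
    if not genes:
        raise ValueError("empty gene list")
    aas = sorted(AA_THREE)
    aa_index = {a: i for i, a in enumerate(aas)}
    mat = np.zeros((len(genes), len(aas)))
    ids = []
    for gi, cds in enumerate(genes):
        ids.append(cds.gene_id)
        for codon in cds.codons:
            aa = code.codon_to_aa.get(codon)
            if aa is not None:
                mat[gi, aa_index[aa]] += 1
        total = mat[gi].sum()
        if total == 0:
            raise ValueError(f"gene {cds.gene_id} has no translatable codons")
        mat[gi] *= 100.0 / total
    return pd.DataFrame(mat, index=ids, columns=aas)


def aa_frequencies(
    genes, code: GeneticCode = STANDARD_CODE, context: str = "high"
) -> AminoAcidUsageTable:
    """Mean and standard error of per-gene percent frequencies."""
    freqs = per_gene_frequencies(genes, code)
    n = len(freqs)
    se = freqs.std(ddof=1) / np.sqrt(n) if n > 1 else freqs.iloc[0] * 0.0
    return AminoAcidUsageTable(
        mean_freq=freqs.mean(), se=se, n_genes=n, context=context
    )


def _aligned(usage: AminoAcidUsageTable, values: pd.Series) -> tuple:
    aas = sorted(AA_THREE)
    x = usage.mean_freq.reindex(aas).to_numpy()
    y = values.reindex(aas).to_numpy()
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("usage and property tables must cover all 20 amino acids")
    return x, y


def property_correlation(
    usage: AminoAcidUsageTable, props: pd.DataFrame, which: str = "sc"
) -> TestResult:
    """Spearman correlation of mean usage vs S/C score or hydropathy."""
    column = {"sc": "sc_score", "hydropathy": "hydropathy"}[which]
    x, y = _aligned(usage, props[column])
    return spearman(x, y)


def gene_level_property_correlation(
    freqs: pd.DataFrame, props: pd.DataFrame, which: str = "hydropathy"
) -> TestResult:
    """Gene-level mode: pool (frequency, property) pairs across all genes."""
    column = {"sc": "sc_score", "hydropathy": "hydropathy"}[which]
    values = props[column].reindex(freqs.columns).to_numpy()
    x = freqs.to_numpy().ravel()
    y = np.tile(values, len(freqs))
    return spearman(x, y)


def usage_trna_correlation(usage: AminoAcidUsageTable, trna_table) -> TestResult:
    """Spearman of mean amino-acid usage vs per-amino-acid tRNA gene totals."""
    totals = pd.Series({a: trna_table.per_aa_total(a) for a in sorted(AA_THREE)})
    x, y = _aligned(usage, totals)
    return spearman(x, y)


def trna_cost_correlation(trna_table, props: pd.DataFrame) -> TestResult:
    """Spearman of per-amino-acid tRNA totals vs S/C score."""
    aas = sorted(AA_THREE)
    totals = np.array([trna_table.per_aa_total(a) for a in aas], dtype=float)
    sc = props["sc_score"].reindex(aas).to_numpy()
    return spearman(totals, sc)


def folding_class_test(
    usage: AminoAcidUsageTable, props: pd.DataFrame, kruskal: bool = False
) -> TestResult:
    """Rank ANOVA of mean usage across the three folding classes."""
    groups = []
    for cls in ("alpha", "beta", "breaker"):
        members = props.index[props["folding_class"] == cls]
        vals = usage.mean_freq.reindex(members).to_numpy()
        if vals.size < 2:
            raise ValueError(f"folding class {cls!r} has < 2 members")
        groups.append(vals)
    return rank_anova(groups, kruskal=kruskal)


def high_low_aa_tests(
    high_freqs: pd.DataFrame, low_freqs: pd.DataFrame, alpha: float = 0.05
) -> list[AaComparisonRecord]:
    """Per-amino-acid Welch tests of percent usage, Bonferroni over 20."""
    if len(high_freqs) < 2 or len(low_freqs) < 2:
        raise ValueError("both groups need >= 2 genes")
    aas = sorted(AA_THREE)
    stats, raws = [], []
    for aa in aas:
        res = welch_t(high_freqs[aa].to_numpy(), low_freqs[aa].to_numpy())
        stats.append(res.statistic)
        raws.append(res.p_value)
    adj = bonferroni(raws)
    records = []
    for i, aa in enumerate(aas):
        fh = float(high_freqs[aa].mean())
        fl = float(low_freqs[aa].mean())
        pct = (fh - fl) / fh * 100.0 if fh != 0 else float("nan")
        records.append(
            AaComparisonRecord(
                amino_acid=aa, freq_high=fh, freq_low=fl, percent_diff=pct,
                t_stat=stats[i], p_raw=float(raws[i]), p_bonf=float(adj[i]),
            )
        )
    return records


def sex_tissue_comparison(freqs_by_tissue_sex: dict, alpha: float = 0.05) -> dict:
    """Female-vs-male usage contrasts per tissue.

    ``freqs_by_tissue_sex`` maps tissue -> {"female": DataFrame,
    "male": DataFrame} of per-gene frequencies.  Tissues where either sex
    has no genes are skipped.  Percent differences are female-relative.
    """
    results: dict[str, list[AaComparisonRecord]] = {}
    for tissue, sexes in freqs_by_tissue_sex.items():
        female = sexes.get("female")
        male = sexes.get("male")
        if female is None or male is None or len(female) < 2 or len(male) < 2:
            continue
        results[tissue] = high_low_aa_tests(female, male, alpha=alpha)
    return results


def usage_report(
    high: AminoAcidUsageTable,
    low: AminoAcidUsageTable,
    comparisons,
    props: pd.DataFrame,
    trna_table,
) -> pd.DataFrame:
    """Combined report table (one row per amino acid, publication layout)."""
    rows = []
    by_aa = {c.amino_acid: c for c in comparisons}
    for aa in sorted(AA_THREE):
        c = by_aa[aa]
        rows.append(
            {
                "amino_acid": AA_THREE[aa],
                "sc_score": props.loc[aa, "sc_score"],
                "mean_high": high.mean_freq[aa],
                "se_high": high.se[aa],
                "mean_low": low.mean_freq[aa],
                "se_low": low.se[aa],
                "percent_diff": c.percent_diff,
                "p_raw": c.p_raw,
                "p_bonf": c.p_bonf,
                "trna_total": trna_table.per_aa_total(aa),
            }
        )
    return pd.DataFrame(rows).set_index("amino_acid")
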
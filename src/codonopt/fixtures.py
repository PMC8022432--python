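"""Packaged reference tables for the cricket (G. bimaculatus) study.

Two small published tables are shipped as in-memory constants so that the
classification and correlation machinery can be exercised and validated
without the underlying genome and RNA-seq data:

* the organism-wide per-codon dRSCU table with significance marks, the
  predicted tRNA gene-copy numbers per codon, and the published codon
  statuses (59 synonymous codons plus Met and Trp; 1391 tRNA genes total);
* the per-amino-acid usage table for the top and bottom 5% expressed genes
  (mean percent +- SE over 777 genes per side), the Dufton size/complexity
  (S/C) biosynthetic-cost score, the printed percent differences with their
  significance marks, and the per-amino-acid tRNA totals.

Significance in the dRSCU table is encoded as published: starred contrasts
had P < 0.001 including after Bonferroni correction; unstarred rows were
non-significant.  Representative p-values (1e-4 / 0.5) stand in for the
unpublished exact values; they are on the correct side of every threshold
the analyses use.
"""

from __future__ import annotations

import pandas as pd

from .codon_metrics import DeltaRscuRecord
from .genetic_code import AA_ONE
from .trna_analysis import TrnaGeneTable, exact_decoding

#: (amino acid 3-letter, codon, dRSCU, significant, tRNA gene copies,
#:  published status or None, published wobble anticodon or None)
TABLE1_ROWS = [
    ("Ala", "GCT", +0.871, True, 35, "Opt_high_tRNA", None),
    ("Ala", "GCC", -0.344, True, 0, None, None),
    ("Ala", "GCA", +0.518, True, 18, None, None),
    ("Ala", "GCG", -1.039, True, 22, "Nonopt_high_tRNA", None),
    ("Arg", "CGT", +0.463, True, 40, None, None),
    ("Arg", "CGC", -1.053, True, 0, "Nonopt_low_tRNA", None),
    ("Arg", "CGA", +0.185, True, 39, None, None),
    ("Arg", "CGG", -0.548, True, 2, None, None),
    ("Arg", "AGA", +0.881, True, 18, "Opt_high_tRNA", None),
    ("Arg", "AGG", +0.047, False, 26, None, None),
    ("Asn", "AAT", +0.416, True, 0, "Opt_wobble", "GUU"),
    ("Asn", "AAC", -0.244, True, 37, "Nonopt_high_tRNA", None),
    ("Asp", "GAT", +0.520, True, 0, "Opt_wobble", "GUC"),
    ("Asp", "GAC", -0.482, True, 31, "Nonopt_high_tRNA", None),
    ("Cys", "TGT", +0.368, True, 0, "Opt_wobble", "GCA"),
    ("Cys", "TGC", -0.365, True, 38, "Nonopt_high_tRNA", None),
    ("Gln", "CAA", +0.254, True, 39, "Opt_high_tRNA", None),
    ("Gln", "CAG", -0.218, True, 37, "Nonopt_high_tRNA", None),
    ("Glu", "GAA", +0.496, True, 31, "Opt_high_tRNA", None),
    ("Glu", "GAG", -0.480, True, 18, "Nonopt_high_tRNA", None),
    ("Gly", "GGT", +0.610, True, 0, "Opt_wobble", "GCC"),
    ("Gly", "GGC", -0.709, True, 41, "Nonopt_high_tRNA", None),
    ("Gly", "GGA", +0.483, True, 19, None, None),
    ("Gly", "GGG", -0.383, True, 11, None, None),
    ("His", "CAT", +0.511, True, 0, "Opt_wobble", "GUG"),
    ("His", "CAC", -0.452, True, 37, "Nonopt_high_tRNA", None),
    ("Ile", "ATT", +0.603, True, 22, "Opt_high_tRNA", None),
    ("Ile", "ATC", -0.452, True, 0, "Nonopt_low_tRNA", None),
    ("Ile", "ATA", +0.045, False, 19, None, None),
    ("Leu", "TTA", +0.537, True, 28, "Opt_high_tRNA", None),
    ("Leu", "TTG", +0.383, True, 16, None, None),
    ("Leu", "CTT", +0.409, True, 39, None, None),
    ("Leu", "CTC", -0.629, True, 0, None, None),
    ("Leu", "CTA", +0.007, False, 28, None, None),
    ("Leu", "CTG", -0.692, True, 30, "Nonopt_high_tRNA", None),
    ("Lys", "AAA", +0.263, True, 20, "Opt_high_tRNA", None),
    ("Lys", "AAG", -0.160, True, 50, "Nonopt_high_tRNA", None),
    ("Phe", "TTT", +0.407, True, 0, "Opt_wobble", "GAA"),
    ("Phe", "TTC", -0.265, True, 48, "Nonopt_high_tRNA", None),
    ("Pro", "CCT", +0.749, True, 36, "Opt_high_tRNA", None),
    ("Pro", "CCC", -0.359, True, 0, None, None),
    ("Pro", "CCA", +0.483, True, 31, None, None),
    ("Pro", "CCG", -0.843, True, 36, "Nonopt_high_tRNA", None),
    ("Ser", "TCT", +0.731, True, 36, "Opt_high_tRNA", None),
    ("Ser", "TCC", -0.208, True, 0, None, None),
    ("Ser", "TCA", +0.493, True, 21, None, None),
    ("Ser", "TCG", -0.723, True, 15, "Nonopt_high_tRNA", None),
    ("Ser", "AGT", +0.325, True, 0, None, None),
    ("Ser", "AGC", -0.619, True, 60, None, None),
    ("Thr", "ACT", +0.644, True, 35, "Opt_high_tRNA", None),
    ("Thr", "ACC", -0.223, True, 0, None, None),
    ("Thr", "ACA", +0.493, True, 37, None, None),
    ("Thr", "ACG", -0.873, True, 31, "Nonopt_high_tRNA", None),
    ("Tyr", "TAT", +0.430, True, 0, "Opt_wobble", "GUA"),
    ("Tyr", "TAC", -0.186, True, 43, "Nonopt_high_tRNA", None),
    ("Val", "GTT", +0.600, True, 26, "Opt_high_tRNA", None),
    ("Val", "GTC", -0.394, True, 0, None, None),
    ("Val", "GTA", +0.314, True, 30, None, None),
    ("Val", "GTG", -0.484, True, 40, "Nonopt_high_tRNA", None),
]

#: single-codon amino acids (reported with tRNA counts, no dRSCU)
TABLE1_SINGLE_CODON = [("Met", "ATG", 43), ("Trp", "TGG", 32)]

#: sizes of the high/low expression sets behind the published dRSCU values
TABLE1_N_GENES = 777

#: (amino acid 3-letter, S/C score, mean % high, SE high, mean % low,
#:  SE low, printed percent difference, significance mark, tRNA total)
TABLE4_ROWS = [
    ("Gly", 1.00, 6.66, 0.21, 8.71, 0.13, -30.70, "**", 71),
    ("Ala", 4.76, 7.32, 0.24, 11.54, 0.14, -57.72, "**", 75),
    ("Val", 12.28, 6.73, 0.19, 6.27, 0.08, +6.80, "**", 96),
    ("Ile", 16.04, 5.70, 0.15, 2.91, 0.04, +49.01, "**", 41),
    ("Leu", 16.04, 9.07, 0.26, 8.13, 0.10, +10.31, "**", 141),
    ("Ser", 17.86, 6.75, 0.21, 7.63, 0.11, -12.94, "**", 132),
    ("Thr", 21.62, 5.16, 0.15, 5.08, 0.07, +1.69, "", 103),
    ("Lys", 30.14, 6.93, 0.18, 3.53, 0.06, +49.08, "**", 70),
    ("Pro", 31.80, 4.62, 0.15, 6.95, 0.11, -50.40, "**", 103),
    ("Asp", 32.72, 5.08, 0.16, 3.83, 0.06, +24.64, "**", 31),
    ("Asn", 33.72, 4.30, 0.13, 2.68, 0.04, +37.70, "**", 37),
    ("Glu", 36.48, 6.53, 0.22, 5.09, 0.07, +22.08, "**", 49),
    ("Gln", 37.48, 3.75, 0.15, 3.49, 0.05, +6.92, "*", 76),
    ("Phe", 44.00, 4.10, 0.10, 2.70, 0.04, +34.20, "**", 48),
    ("Arg", 56.34, 5.61, 0.15, 10.04, 0.12, -78.95, "**", 125),
    ("Tyr", 57.00, 3.10, 0.08, 1.87, 0.05, +39.53, "**", 43),
    ("Cys", 57.16, 2.08, 0.06, 2.51, 0.03, -20.75, "**", 38),
    ("His", 58.70, 2.24, 0.07, 2.53, 0.04, -12.99, "**", 37),
    ("Met", 64.68, 2.61, 0.06, 2.32, 0.02, +10.93, "**", 43),
    ("Trp", 73.00, 1.18, 0.03, 1.48, 0.02, -25.80, "**", 32),
]

_SIG_P = 1e-4   # representative p for starred contrasts (P < 0.001)
_NS_P = 0.5     # representative p for unstarred contrasts


def table1_fixture() -> tuple[list[DeltaRscuRecord], TrnaGeneTable]:
    """The published dRSCU table and its tRNA gene-copy table."""
    records = []
    counts: dict[str, int] = {}
    for aa3, codon, delta, sig, n_trna, _status, _wob in TABLE1_ROWS:
        p = _SIG_P if sig else _NS_P
        records.append(
            DeltaRscuRecord(
                codon=codon, amino_acid=AA_ONE[aa3], delta=delta,
                mean_high=float("nan"), mean_low=float("nan"),
                t_stat=float("nan"), p_raw=p, p_bonf=p,
                n_high=TABLE1_N_GENES, n_low=TABLE1_N_GENES,
            )
        )
        anticodon = exact_decoding(codon)
        counts[anticodon] = counts.get(anticodon, 0) + n_trna
    for _aa3, codon, n_trna in TABLE1_SINGLE_CODON:
        anticodon = exact_decoding(codon)
        counts[anticodon] = counts.get(anticodon, 0) + n_trna
    return records, TrnaGeneTable(counts=counts)


def table4_fixture() -> pd.DataFrame:
    """The published amino-acid usage table, indexed by one-letter code.

    Columns: sc_score, mean_high, se_high, mean_low, se_low,
    percent_diff_printed, significance, trna_total.
    """
    df = pd.DataFrame(
        TABLE4_ROWS,
        columns=[
            "aa3", "sc_score", "mean_high", "se_high", "mean_low", "se_low",
            "percent_diff_printed", "significance", "trna_total",
        ],
    )
    df.index = pd.Index([AA_ONE[a] for a in df["aa3"]], name="amino_acid")
    return df.drop(columns="aa3")
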
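"""Standard nuclear genetic code and codon-family bookkeeping.

The analyses in this package operate on synonymous codon families: the 61
sense codons of the standard code partitioned by amino acid, with family
size (degeneracy) k.  Met (ATG) and Trp (TGG) have k = 1 and are excluded
from every synonymous-choice statistic; the three stop codons are excluded
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: three-letter names keyed by one-letter code, ordering used in reports
AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA_ONE = {v: k for k, v in AA_THREE.items()}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """Codon → amino acid map plus synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        Map over the 61 sense codons to one-letter amino acids.
    families
        Amino acid → sorted list of synonymous codons.
    degeneracy
        Amino acid → family size k.
    """

    codon_to_aa: dict[str, str]
    families: dict[str, list[str]] = field(init=False)
    degeneracy: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fams.setdefault(aa, []).append(codon)
        for aa in fams:
            fams[aa].sort()
        object.__setattr__(self, "families", fams)
        object.__setattr__(
            self, "degeneracy", {aa: len(c) for aa, c in fams.items()}
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = unambiguous_dna_by_id[1]
        return cls(codon_to_aa=dict(table.forward_table))

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.codon_to_aa)

    @property
    def synonymous_codons(self) -> list[str]:
        """The 59 codons of amino acids with k >= 2 (excludes ATG, TGG)."""
        return [c for c in self.sense_codons if self.degeneracy[self.codon_to_aa[c]] > 1]

    @property
    def multi_codon_amino_acids(self) -> list[str]:
        """The 18 amino acids with synonymous codons."""
        return sorted(aa for aa, k in self.degeneracy.items() if k > 1)


STANDARD_CODE = GeneticCode.standard()
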
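"""tRNA gene-copy tables, wobble decoding, and codon-status classification.

The number of tRNA gene copies per anticodon in a genome is a standard
proxy for tRNA abundance.  Here the table is consumed from tRNAscan-SE v2
tabular output (or a simple two-column anticodon/count table), codons are
matched to their exact Watson-Crick anticodon, and codons with zero exact
matches are assigned a putative wobble decoder:

* a codon ending T can be read by the G34 anticodon of its synonymous
  NNC codon (G:U wobble);
* codons ending T, C or A can be read by an inosine-modified I34 anticodon,
  encoded genomically as A34 (the exact anticodon of the NNT codon).

Primary optimal and non-optimal codons are then classified into four
statuses by their exact tRNA gene counts: optimal codons with a high count
(>= 18 by default) are consistent with translational selection
(Opt_high_tRNA); optimal codons with zero exact matches obligately require
wobble decoding (Opt_wobble); non-optimal codons split into scarce-tRNA
(Nonopt_low_tRNA, count < 15) and abundant-tRNA (Nonopt_high_tRNA,
count >= 15) classes with distinct hypothesised translational roles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genetic_code import (
    STANDARD_CODE,
    STOP_CODONS,
    GeneticCode,
    dna_to_rna,
    reverse_complement,
    rna_to_dna,
)

logger = logging.getLogger(__name__)

#: tRNAscan-SE isotype labels excluded from anticodon counting
_EXCLUDED_ISOTYPES = {"Pseudo", "SeC", "Sec", "Sup", "Undet"}


@dataclass(frozen=True)
class TrnaGeneTable:
    """Gene-copy counts per anticodon with per-codon / per-AA views."""

    counts: dict  # anticodon (RNA, 5'->3') -> int
    code: GeneticCode = STANDARD_CODE

    def anticodon_count(self, anticodon: str) -> int:
        return self.counts.get(anticodon, 0)

    def per_codon_exact(self, codon: str) -> int:
        """Gene copies of the exact Watson-Crick anticodon for ``codon``."""
        return self.anticodon_count(exact_decoding(codon))

    def per_aa_total(self, amino_acid: str) -> int:
        """Total gene copies matching any synonymous codon of the amino acid."""
        return sum(
            self.per_codon_exact(c) for c in self.code.families[amino_acid]
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CodonStatusRecord:
    codon: str
    amino_acid: str
    role: str     # optimal | nonoptimal
    status: str   # Opt_high_tRNA | Opt_wobble | Nonopt_low_tRNA |
                  # Nonopt_high_tRNA | unclassified
    exact_trna_count: int
    wobble_anticodon: str | None = None


def exact_decoding(codon: str) -> str:
    """Watson-Crick anticodon of a sense codon, written 5'->3' in RNA."""
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    return dna_to_rna(reverse_complement(codon))


def anticodon_to_codon(anticodon: str) -> str:
    """Inverse of :func:`exact_decoding` (DNA codon from RNA anticodon)."""
    return reverse_complement(rna_to_dna(anticodon))


def wobble_anticodon(
    codon: str,
    table: TrnaGeneTable,
    allow_inosine: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> str | None:
    """Putative wobble decoder for a codon lacking exact-match tRNAs.

    For a codon ending T, the G34 anticodon of the synonymous NNC codon is
    returned when it has gene copies (G:U wobble).  As a fallback (for
    codons ending T, C or A) the genomically A34 anticodon is returned when
    present, on the premise of adenosine-to-inosine modification (I34 reads
    U, C and A).  None means no decoder exists in the table.
    """
    aa = code.codon_to_aa.get(codon)
    if aa is None:
        raise ValueError(f"{codon!r} is not a sense codon")
    family = set(code.families[aa])
    third = codon[2]
    if third == "T":
        partner = codon[:2] + "C"
        if partner in family:
            g34 = exact_decoding(partner)  # starts with G
            if table.anticodon_count(g34) > 0:
                return g34
    if allow_inosine and third in "TCA":
        partner = codon[:2] + "T"
        if partner in family:
            a34 = exact_decoding(partner)  # starts with A -> I34 candidate
            if a34 != exact_decoding(codon) and table.anticodon_count(a34) > 0:
                return a34
    return None


def classify_codon_status(
    optimal,
    table: TrnaGeneTable,
    opt_threshold: int = 18,
    nonopt_threshold: int = 15,
    code: GeneticCode = STANDARD_CODE,
) -> list[CodonStatusRecord]:
    """Four-way status of every primary optimal/non-optimal codon.

    Optimal codons with an exact count in (0, opt_threshold) fall outside
    both described optimal statuses and are reported as ``unclassified``
    rather than silently merged into either class.
    """
    records: list[CodonStatusRecord] = []
    for aa in sorted(optimal.primary_optimal):
        codon = optimal.primary_optimal[aa]
        count = table.per_codon_exact(codon)
        wob = None
        if count >= opt_threshold:
            status = "Opt_high_tRNA"
        elif count == 0:
            status = "Opt_wobble"
            wob = wobble_anticodon(codon, table, code=code)
            if wob is None:
                logger.warning("optimal codon %s has no wobble decoder", codon)
        else:
            status = "unclassified"
            logger.info(
                "optimal codon %s has %d exact tRNA copies (band 1-%d): "
                "unclassified", codon, count, opt_threshold - 1,
            )
        records.append(
            CodonStatusRecord(
                codon=codon, amino_acid=aa, role="optimal", status=status,
                exact_trna_count=count, wobble_anticodon=wob,
            )
        )
    for aa in sorted(optimal.primary_nonoptimal):
        codon = optimal.primary_nonoptimal[aa]
        count = table.per_codon_exact(codon)
        status = "Nonopt_high_tRNA" if count >= nonopt_threshold else "Nonopt_low_tRNA"
        records.append(
            CodonStatusRecord(
                codon=codon, amino_acid=aa, role="nonoptimal", status=status,
                exact_trna_count=count,
            )
        )
    return records


# ---------------------------------------------------------------------------
# parsers


def parse_trnascan(
    path, use_confidence_filter_column: bool = False
) -> TrnaGeneTable:
    """Parse tRNAscan-SE v2 tabular output into anticodon gene-copy counts.

    Pseudogenes, selenocysteine/suppressor tRNAs and rows with undetermined
    anticodons are excluded.  When the EukHighConfidenceFilter note column
    is present and the flag is on, only rows marked high-confidence count.
    """
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            # header block: name/border lines of the tabular format
            if line.startswith(("Sequence", "Name", "----")) or (
                "\t" not in line and lineno <= 3
            ):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: malformed tRNAscan row "
                    f"({len(fields)} columns)"
                )
            isotype = fields[4]
            anticodon = fields[5].upper().replace("T", "U")
            if isotype in _EXCLUDED_ISOTYPES:
                continue
            if len(fields) > 6 and fields[-1] == "pseudo":
                continue
            if not anticodon or anticodon in ("NNN", "???"):
                continue
            if any(b not in "ACGU" for b in anticodon) or len(anticodon) != 3:
                continue
            if use_confidence_filter_column:
                note = fields[-1] if fields else ""
                if "high confidence" not in note.lower():
                    continue
            counts[anticodon] = counts.get(anticodon, 0) + 1
    if not counts:
        raise ValueError(f"no usable tRNA rows in {path}")
    return TrnaGeneTable(counts=counts)


def read_anticodon_counts(path) -> TrnaGeneTable:
    """Simple two-column (anticodon, count) table, tab-separated."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith(
                "anticodon"
            ):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            anticodon = parts[0].upper().replace("T", "U")
            counts[anticodon] = counts.get(anticodon, 0) + int(parts[1])
    if not counts:
        raise ValueError(f"no anticodon counts in {path}")
    return TrnaGeneTable(counts=counts)


def write_status_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "codon\tamino_acid\trole\tstatus\texact_trna_count\twobble_anticodon\n"
        )
        for r in records:
            fh.write(
                f"{r.codon}\t{r.amino_acid}\t{r.role}\t{r.status}"
                f"\t{r.exact_trna_count}\t{r.wobble_anticodon or '-'}\n"
            )
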
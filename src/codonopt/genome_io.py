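"""Sequence and gene-model ingestion: FASTA, GFF3, CDS validation, introns.

CDS filtering follows the study design: keep the longest CDS per gene among
those that begin with ATG and are strictly longer than 150 nt; exclude the
terminal stop codon from the codon list; drop (with a warning) any trailing
1-2 nt that break the reading frame.  Records with an internal stop codon
are excluded and logged, never fatal.

Introns are the gaps between consecutive exons of one transcript, reported
on the sense strand of the gene.  For composition analyses each intron is
trimmed by 10 nt at both ends (putative splice-regulatory sequence) and
retained only if >= 50 nt remain; when requested, only the longest (by raw
length) intron per gene is kept.

Coordinates: GFF3 is 1-based inclusive on input; everything internal is
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    """One raw DNA sequence (genome contig or candidate CDS)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one transcript (1-based inclusive coordinates)."""

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple  # of (seq_id, start, end), sorted by start

    def __post_init__(self) -> None:
        prev_end = None
        for seq_id, start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"{self.transcript_id}: exon start {start} > end {end}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = end


@dataclass(frozen=True)
class CdsRecord:
    """A validated protein-coding sequence as an ordered codon list."""

    gene_id: str
    seq: str
    codons: tuple
    length_nt: int


@dataclass(frozen=True)
class IntronRecord:
    """One intron on the sense strand; trimmed_length set after trimming."""

    gene_id: str
    seq: str
    raw_length: int
    trimmed_length: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-FASTA file.

    Sequences are uppercased and U is mapped to T.  Duplicate ids and empty
    files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq).upper().replace("U", "T"))
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write SequenceRecords (or CdsRecords) as wrapped FASTA."""
    out = []
    for rec in records:
        rid = getattr(rec, "id", None) or rec.gene_id
        out.append(SeqRecord(Seq(rec.seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


# ---------------------------------------------------------------------------
# CDS selection


def _gene_id_from_record(record_id: str, delimiter: str | None) -> str:
    if delimiter and delimiter in record_id:
        return record_id.split(delimiter)[0]
    return record_id


def select_cds(
    records,
    min_len_nt: int = 150,
    require_start: bool = True,
    longest_per_gene: bool = True,
    gene_id_delimiter: str | None = None,
) -> list[CdsRecord]:
    """Validate candidate CDS sequences into codon records.

    Retains sequences strictly longer than ``min_len_nt`` that begin with
    ATG (when ``require_start``); keeps only the longest isoform per gene
    id; drops a trailing frame-breaking remainder with a warning; strips
    the terminal stop codon; excludes and logs records with internal stops.
    """
    candidates: dict[str, CdsRecord] = {}
    n_internal_stop = 0
    for rec in records:
        seq = rec.seq
        if len(seq) <= min_len_nt:
            continue
        if require_start and not seq.startswith("ATG"):
            continue
        remainder = len(seq) % 3
        if remainder:
            logger.warning(
                "CDS %s length %d not divisible by 3; dropping %d trailing nt",
                rec.id, len(seq), remainder,
            )
            seq = seq[: len(seq) - remainder]
        codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if any(c in STOP_CODONS for c in codons):
            n_internal_stop += 1
            logger.warning("CDS %s has an internal stop codon; excluded", rec.id)
            continue
        gene_id = _gene_id_from_record(rec.id, gene_id_delimiter)
        cds = CdsRecord(
            gene_id=gene_id, seq=seq, codons=tuple(codons), length_nt=len(seq)
        )
        prev = candidates.get(gene_id)
        if prev is None or not longest_per_gene:
            if prev is not None:
                # longest_per_gene off: keep every isoform under a suffixed id
                cds = CdsRecord(
                    gene_id=f"{gene_id}.{len(candidates)}", seq=seq,
                    codons=tuple(codons), length_nt=len(seq),
                )
            candidates[cds.gene_id] = cds
        elif cds.length_nt > prev.length_nt:
            candidates[gene_id] = cds
    if n_internal_stop:
        logger.info("excluded %d CDS with internal stop codons", n_internal_stop)
    return list(candidates.values())


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file into GeneModels."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = sorted(
            ((e.seqid, e.start, e.end) for e in db.children(mrna, featuretype="exon")),
            key=lambda t: t[1],
        )
        if not exons:
            continue
        models.append(
            GeneModel(
                gene_id=gene_id, transcript_id=mrna.id,
                strand=mrna.strand, exons=tuple(exons),
            )
        )
    return models


def extract_introns(models, genome) -> list[IntronRecord]:
    """Raw introns (untrimmed) between consecutive exons, sense strand.

    Minus-strand introns are reverse-complemented and ordered in the
    transcription direction.  Single-exon transcripts yield no introns.
    """
    contigs = {rec.id: rec.seq for rec in genome}
    introns: list[IntronRecord] = []
    for model in models:
        for seq_id, _start, end in model.exons:
            if seq_id not in contigs:
                raise ValueError(
                    f"{model.transcript_id}: contig {seq_id!r} not in genome"
                )
            if end > len(contigs[seq_id]):
                raise ValueError(
                    f"{model.transcript_id}: exon beyond end of contig "
                    f"{seq_id!r}"
                )
        gaps = []
        for (sid_a, _, end_a), (sid_b, start_b, _) in zip(
            model.exons, model.exons[1:]
        ):
            if sid_a != sid_b:
                raise ValueError(
                    f"{model.transcript_id}: exons span multiple contigs"
                )
            if sid_a not in contigs:
                raise ValueError(
                    f"{model.transcript_id}: contig {sid_a!r} not in genome"
                )
            contig = contigs[sid_a]
            if end_a > len(contig) or start_b - 1 > len(contig):
                raise ValueError(
                    f"{model.transcript_id}: exon beyond end of contig {sid_a!r}"
                )
            # gap between exons, converted to 0-based half-open
            lo, hi = end_a, start_b - 1
            if hi <= lo:
                continue
            gaps.append(contig[lo:hi])
        if model.strand == "-":
            gaps = [reverse_complement(g) for g in reversed(gaps)]
        for g in gaps:
            introns.append(
                IntronRecord(
                    gene_id=model.gene_id, seq=g,
                    raw_length=len(g), trimmed_length=len(g),
                )
            )
    return introns


def trim_and_filter_introns(
    introns,
    trim_each_end: int = 10,
    min_len_after: int = 50,
    longest_per_gene: bool = True,
) -> list[IntronRecord]:
    """Trim both intron ends and keep those with >= ``min_len_after`` nt left.

    With ``longest_per_gene`` only the intron with the greatest raw length
    survives per gene (selection happens before trimming so the choice is
    independent of the trim width).
    """
    if longest_per_gene:
        best: dict[str, IntronRecord] = {}
        for intr in introns:
            prev = best.get(intr.gene_id)
            if prev is None or intr.raw_length > prev.raw_length:
                best[intr.gene_id] = intr
        introns = list(best.values())
    kept: list[IntronRecord] = []
    n_dropped = 0
    for intr in introns:
        # trim relative to the sequence actually held, so re-running on
        # already-trimmed output with trim 0 is a no-op
        current = len(intr.seq)
        trimmed_len = current - 2 * trim_each_end
        if trimmed_len < min_len_after:
            n_dropped += 1
            continue
        seq = intr.seq[trim_each_end: current - trim_each_end]
        kept.append(
            IntronRecord(
                gene_id=intr.gene_id, seq=seq,
                raw_length=intr.raw_length, trimmed_length=trimmed_len,
            )
        )
    if n_dropped:
        logger.info("dropped %d introns below %d nt after trimming",
                    n_dropped, min_len_after)
    return kept


def write_intron_index(introns, at_i_values, path) -> None:
    """Tab-separated intron index: gene_id, raw_length, trimmed_length, AT_I."""
    with open(path, "w") as fh:
        fh.write("gene_id\traw_length\ttrimmed_length\tAT_I\n")
        for intr in introns:
            ati = at_i_values.get(intr.gene_id, float("nan"))
            fh.write(
                f"{intr.gene_id}\t{intr.raw_length}\t{intr.trimmed_length}"
                f"\t{ati:.6f}\n"
            )
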
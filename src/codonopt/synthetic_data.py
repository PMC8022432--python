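"""Synthetic genome / expression / tRNA fixture generator with known truth.

The generator emits a complete desk-scale dataset carrying the statistical
structure the analyses assume, so that every pipeline stage can be tested
against planted ground truth:

* nine-tissue FPKM expression with replicate samples, heavy-tailed
  (log-normal) across genes, with optional planted tissue-exclusive genes;
* per-gene codon usage whose preference for a planted "optimal" codon per
  amino acid strengthens logistically with standardized log expression
  (slope ``codon_bias_strength``), so AT-ending codon preference rises
  with expression when the planted set is the AT3 set;
* one intron per intron-bearing gene whose AT content follows a Beta
  distribution with mean linked to expression (slope
  ``ati_expression_slope``) and whose length shrinks with expression so
  that lowly expressed genes carry longer introns (planted fold);
* a tRNA gene-copy table consistent with the planted optimal set (wobble
  optimal codons have zero exact copies but well-stocked G34 partners).

Amino-acid composition per gene is Dirichlet-distributed around the
published high-expression usage means.  A per-amino-acid ``sex_effect``
shifts the composition of genes planted as exclusive to female tissues,
giving known female-vs-male contrasts.

A single integer seed drives one named pseudo-random stream per component
(expression, composition, sequence, introns), so enlarging one component
does not reshuffle the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import TISSUES, ExpressionTable, write_expression
from .fixtures import TABLE4_ROWS, table1_fixture
from .genetic_code import AA_ONE, STANDARD_CODE, reverse_complement
from .genome_io import SequenceRecord, write_fasta

#: planted primary optimal codon per amino acid: the published AT3 set
DEFAULT_PLANTED_OPTIMAL = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "TTA", "K": "AAA",
    "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "Y": "TAT", "V": "GTT",
}

#: amino-acid composition centre: published high-expression means (percent)
DEFAULT_AA_COMPOSITION = {AA_ONE[r[0]]: r[2] for r in TABLE4_ROWS}

#: mean of the top 5% of a standard normal (used to size the planted
#: intron-length fold between expression extremes)
_Z_TOP5_MEAN = 2.0627128


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one synthetic dataset."""

    n_genes: int = 600
    replicates_per_tissue: int = 2
    expression_mu: float = 1.5      # log-FPKM location
    expression_sigma: float = 2.0   # log-FPKM scale (heavy tail)
    tissue_noise_sigma: float = 0.6
    replicate_noise_sigma: float = 0.2
    planted_optimal: dict = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_OPTIMAL)
    )
    codon_bias_strength: float = 1.0   # logistic slope on standardized log expr
    aa_concentration: float = 120.0    # Dirichlet concentration of composition
    mean_protein_len: int = 300
    protein_len_sigma: float = 0.35    # log-space sd of protein length
    min_protein_len: int = 60
    fraction_with_introns: float = 0.905
    intron_length_log_mean: float = math.log(400.0)
    intron_length_log_sigma: float = 0.6
    intron_length_fold: float = 1.9    # planted low/high median length ratio
    min_intron_len: int = 90
    intron_at_base: float = 0.637
    ati_expression_slope: float = 0.015
    intron_at_concentration: float = 150.0
    tissue_exclusive_fraction: float = 0.0   # per tissue
    tissue_exclusive_boost: float = 6.0      # log-space expression boost
    sex_effect: dict = field(default_factory=dict)  # amino acid -> rel. shift
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0.0 <= self.fraction_with_introns <= 1.0):
            raise ValueError("fraction_with_introns must lie in [0, 1]")
        if self.tissue_exclusive_fraction * len(TISSUES) > 1.0:
            raise ValueError(
                "tissue_exclusive_fraction x 9 tissues exceeds the gene pool"
            )
        if not (0.0 < self.intron_at_base < 1.0):
            raise ValueError("intron_at_base must lie in (0, 1)")
        for aa, codon in self.planted_optimal.items():
            if STANDARD_CODE.codon_to_aa.get(codon) != aa:
                raise ValueError(f"planted codon {codon} does not encode {aa}")


@dataclass
class TruthRecord:
    """Planted ground truth mirrored by the emitted files."""

    seed: int
    planted_optimal: dict
    gene_base_expression: dict      # gene -> true log-normal mean FPKM
    gene_z: dict                    # gene -> standardized log expression
    tissue_exclusive: dict          # tissue -> sorted gene list
    intron_genes: list              # genes carrying an intron
    intron_raw_length: dict         # gene -> planted raw length
    intron_at_mean: dict            # gene -> planted Beta mean AT
    sex_shifted_amino_acids: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "planted_optimal": self.planted_optimal,
                "gene_base_expression": self.gene_base_expression,
                "gene_z": self.gene_z,
                "tissue_exclusive": self.tissue_exclusive,
                "intron_genes": self.intron_genes,
                "intron_raw_length": self.intron_raw_length,
                "intron_at_mean": self.intron_at_mean,
                "sex_shifted_amino_acids": self.sex_shifted_amino_acids,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SyntheticDataset:
    """In-memory dataset plus writers for the on-disk fixture formats."""

    config: SyntheticConfig
    cds: list                # SequenceRecord per gene (start..stop CDS)
    genome: list             # SequenceRecord per contig
    gff3: str
    expression: ExpressionTable
    trna_table: object
    truth: TruthRecord
    intron_seqs: dict        # gene -> planted intron sequence (sense strand)

    def write(self, outdir) -> dict:
        """Write FASTA/GFF3/TSV/JSON fixture files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cds": outdir / "cds.fasta",
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "expression": outdir / "expression.tsv",
            "trna": outdir / "trna_counts.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.genome, paths["genome"])
        paths["gff3"].write_text(self.gff3)
        write_expression(self.expression, paths["expression"])
        with open(paths["trna"], "w") as fh:
            fh.write("anticodon\tcount\n")
            for anticodon in sorted(self.trna_table.counts):
                fh.write(f"{anticodon}\t{self.trna_table.counts[anticodon]}\n")
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _stream(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([seed, component])


def _draw_codons(rng, aa: str, n: int, planted: str | None, z: float,
                 beta: float) -> list:
    """n codons for one amino acid; planted-codon odds logistic in beta*z."""
    family = STANDARD_CODE.families[aa]
    k = len(family)
    if k == 1 or planted is None or planted not in family:
        return list(rng.choice(family, size=n))
    logit = math.log(1.0 / (k - 1)) + beta * z
    p_opt = 1.0 / (1.0 + math.exp(-logit))
    probs = [
        p_opt if c == planted else (1.0 - p_opt) / (k - 1) for c in family
    ]
    counts = rng.multinomial(n, probs)
    codons: list[str] = []
    for codon, c in zip(family, counts):
        codons.extend([codon] * int(c))
    rng.shuffle(codons)
    return codons


def _intron_sequence(rng, length: int, at_fraction: float) -> str:
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2,
         at_fraction / 2]
    )
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one deterministic dataset from a validated config."""
    config.validate()
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    rng_expr = _stream(config.seed, 0)
    rng_comp = _stream(config.seed, 1)
    rng_seq = _stream(config.seed, 2)
    rng_intr = _stream(config.seed, 3)

    # --- tissue-exclusive assignment (deterministic counts per tissue)
    per_tissue = int(round(config.tissue_exclusive_fraction * n))
    tissue_exclusive: dict[str, list[str]] = {t: [] for t in TISSUES}
    exclusive_of: dict[str, str] = {}
    cursor = 0
    for tissue in TISSUES:
        for _ in range(per_tissue):
            exclusive_of[gene_ids[cursor]] = tissue
            tissue_exclusive[tissue].append(gene_ids[cursor])
            cursor += 1

    # --- expression matrix
    log_base = rng_expr.normal(config.expression_mu, config.expression_sigma, n)
    # planted exclusive genes start from the median so that the boost makes
    # them top-ranked in their tissue and mid-ranked everywhere else,
    # keeping the planted exclusivity consistent with the emitted matrix
    for gi, g in enumerate(gene_ids):
        if g in exclusive_of:
            log_base[gi] = config.expression_mu
    z = (log_base - config.expression_mu) / config.expression_sigma
    sample_ids = []
    sample_to_tissue = {}
    for tissue in TISSUES:
        for r in range(config.replicates_per_tissue):
            sid = f"{tissue}_rep{r + 1}"
            sample_ids.append(sid)
            sample_to_tissue[sid] = tissue
    fpkm = np.empty((n, len(sample_ids)))
    for ti, tissue in enumerate(TISSUES):
        t_noise = rng_expr.normal(0.0, config.tissue_noise_sigma, n)
        log_t = log_base + t_noise
        for gi, g in enumerate(gene_ids):
            if exclusive_of.get(g) == tissue:
                log_t[gi] += config.tissue_exclusive_boost
        for r in range(config.replicates_per_tissue):
            col = ti * config.replicates_per_tissue + r
            r_noise = rng_expr.normal(0.0, config.replicate_noise_sigma, n)
            fpkm[:, col] = np.exp(log_t + r_noise)
    expression = ExpressionTable(
        fpkm=pd.DataFrame(
            fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
        ).round(4),
        sample_to_tissue=sample_to_tissue,
    )

    # --- amino-acid composition centres
    aas = sorted(DEFAULT_AA_COMPOSITION)
    base_center = np.array([DEFAULT_AA_COMPOSITION[a] for a in aas])
    base_center = base_center / base_center.sum()
    shifted = list(config.sex_effect)
    female_center = base_center.copy()
    if shifted:
        for aa, shift in config.sex_effect.items():
            female_center[aas.index(aa)] *= 1.0 + shift
        female_center = female_center / female_center.sum()

    # --- CDS sequences
    beta = config.codon_bias_strength
    planted = config.planted_optimal
    cds_records: list[SequenceRecord] = []
    for gi, g in enumerate(gene_ids):
        length = int(
            round(
                math.exp(
                    rng_comp.normal(
                        math.log(config.mean_protein_len),
                        config.protein_len_sigma,
                    )
                )
            )
        )
        length = max(length, config.min_protein_len)
        excl = exclusive_of.get(g)
        center = (
            female_center
            if shifted and excl is not None and excl.startswith("female")
            else base_center
        )
        alpha = center * config.aa_concentration
        comp = rng_comp.dirichlet(alpha)
        aa_counts = rng_comp.multinomial(length, comp)
        codons: list[str] = []
        for aa, count in zip(aas, aa_counts):
            if count:
                codons.extend(
                    _draw_codons(rng_seq, aa, int(count), planted.get(aa),
                                 z[gi], beta)
                )
        rng_seq.shuffle(codons)
        seq = "ATG" + "".join(codons) + "TAA"
        cds_records.append(SequenceRecord(id=g, seq=seq))

    # --- introns, genome contigs and gene models
    n_with_introns = int(round(config.fraction_with_introns * n))
    intron_gene_idx = set(
        rng_intr.permutation(n)[:n_with_introns].tolist()
    )
    # length slope so that extreme expression strata differ by the planted fold
    lam = math.log(config.intron_length_fold) / (2.0 * _Z_TOP5_MEAN)
    flank = "ACGT" * 8  # 32 nt of neutral flanking sequence
    contigs: list[SequenceRecord] = []
    gff_lines = ["##gff-version 3"]
    intron_seqs: dict[str, str] = {}
    intron_len: dict[str, int] = {}
    intron_at: dict[str, float] = {}
    for gi, (g, cds) in enumerate(zip(gene_ids, cds_records)):
        strand = "+" if gi % 2 == 0 else "-"
        has_intron = gi in intron_gene_idx
        if has_intron:
            raw_len = int(
                round(
                    math.exp(
                        rng_intr.normal(
                            config.intron_length_log_mean - lam * z[gi],
                            config.intron_length_log_sigma,
                        )
                    )
                )
            )
            raw_len = max(raw_len, config.min_intron_len)
            at_mean = float(
                np.clip(
                    config.intron_at_base
                    + config.ati_expression_slope * z[gi],
                    0.05, 0.95,
                )
            )
            kappa = config.intron_at_concentration
            at_draw = float(
                rng_intr.beta(at_mean * kappa, (1.0 - at_mean) * kappa)
            )
            iseq = _intron_sequence(rng_intr, raw_len, at_draw)
            intron_seqs[g] = iseq
            intron_len[g] = raw_len
            intron_at[g] = at_mean
            half = (len(cds.seq) // 6) * 3  # codon-aligned split point
            exon1, exon2 = cds.seq[:half], cds.seq[half:]
            region = exon1 + iseq + exon2
            exon_spans = [
                (1, len(exon1)),
                (len(exon1) + len(iseq) + 1, len(region)),
            ]
        else:
            region = cds.seq
            exon_spans = [(1, len(region))]
        contig_id = f"contig_{g}"
        if strand == "+":
            contig_seq = flank + region + flank
            offset = len(flank)
            spans = [(offset + s, offset + e) for s, e in exon_spans]
        else:
            contig_seq = flank + reverse_complement(region) + flank
            offset = len(flank)
            L = len(region)
            # sense position p maps to contig position offset + L - p + 1
            spans = sorted(
                (offset + L - e + 1, offset + L - s + 1)
                for s, e in exon_spans
            )
        contigs.append(SequenceRecord(id=contig_id, seq=contig_seq))
        gene_start = min(s for s, _ in spans)
        gene_end = max(e for _, e in spans)
        gff_lines.append(
            f"{contig_id}\tsynth\tgene\t{gene_start}\t{gene_end}\t.\t{strand}"
            f"\t.\tID={g}"
        )
        gff_lines.append(
            f"{contig_id}\tsynth\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}"
            f"\t.\tID={g}.t1;Parent={g}"
        )
        for xi, (s, e) in enumerate(spans, start=1):
            gff_lines.append(
                f"{contig_id}\tsynth\texon\t{s}\t{e}\t.\t{strand}\t."
                f"\tID={g}.t1.exon{xi};Parent={g}.t1"
            )

    _, trna_table = table1_fixture()

    truth = TruthRecord(
        seed=config.seed,
        planted_optimal=dict(planted),
        gene_base_expression={
            g: float(np.exp(log_base[i])) for i, g in enumerate(gene_ids)
        },
        gene_z={g: float(z[i]) for i, g in enumerate(gene_ids)},
        tissue_exclusive={t: sorted(v) for t, v in tissue_exclusive.items()},
        intron_genes=sorted(intron_seqs),
        intron_raw_length=intron_len,
        intron_at_mean=intron_at,
        sex_shifted_amino_acids=sorted(config.sex_effect),
    )
    return SyntheticDataset(
        config=config,
        cds=cds_records,
        genome=contigs,
        gff3="\n".join(gff_lines) + "\n",
        expression=expression,
        trna_table=trna_table,
        truth=truth,
        intron_seqs=intron_seqs,
    )
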
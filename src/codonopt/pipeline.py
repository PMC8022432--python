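"""End-to-end orchestration: inputs -> gene sets -> codon/tRNA/intron/AA
analyses -> report tables.

``run_all`` sequences the analysis in its natural order and persists every
intermediate as a tab-separated or JSON file under the output directory.
Outputs are deterministic for a given config (a config hash is embedded in
the summary), so re-running with an identical config reproduces the report
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    amino_acid_analysis as aaa,
    codon_metrics as cm,
    expression as expr,
    genome_io as gio,
    intron_composition as ic,
    trna_analysis as ta,
)
from .fixtures import table1_fixture
from .genetic_code import AA_THREE, STANDARD_CODE
from .synthetic_data import SyntheticConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; every published threshold is a knob."""

    # inputs (either real paths or the synthetic switch)
    cds_fasta: str | None = None
    genome_fasta: str | None = None
    gff3: str | None = None
    expression_tsv: str | None = None
    trna_table: str | None = None
    trna_format: str = "anticodon_counts"  # or "trnascan"
    tissue_map: dict = field(default_factory=dict)
    synthetic: bool = False
    synthetic_n_genes: int = 600
    # thresholds
    fraction: float = 0.05
    alpha: float = 0.05
    use_bonferroni: bool = True
    rscu_elevated: float = 1.5
    opt_trna_threshold: int = 18
    nonopt_trna_threshold: int = 15
    min_cds_len: int = 150
    intron_trim: int = 10
    intron_min_len: int = 50
    ati_edges: tuple = ic.DEFAULT_ATI_EDGES
    # run control
    out_dir: str = "codonopt_out"
    seed: int = 7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.ati_edges, list):
            cfg.ati_edges = tuple(cfg.ati_edges)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """In-memory handles to every table the run produced."""

    config_hash: str
    optimal_codon_table: pd.DataFrame
    codon_status: list
    fop_by_tissue: pd.DataFrame
    ati_bins: pd.DataFrame | None
    amino_acid_table: pd.DataFrame
    correlations: dict
    elevated_use: dict
    gene_sets: dict


def _delta_table(records, optimal) -> pd.DataFrame:
    rows = []
    for r in records:
        role = ""
        if optimal.primary_optimal.get(r.amino_acid) == r.codon:
            role = "optimal"
        elif optimal.primary_nonoptimal.get(r.amino_acid) == r.codon:
            role = "nonoptimal"
        rows.append(
            {
                "amino_acid": AA_THREE[r.amino_acid],
                "codon": r.codon,
                "anticodon": ta.exact_decoding(r.codon),
                "delta_rscu": round(r.delta, 6),
                "p_raw": r.p_raw,
                "p_bonf": r.p_bonf,
                "n_high": r.n_high,
                "n_low": r.n_low,
                "role": role,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> AnalysisReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    # ---- stage: ingest -------------------------------------------------
    genome = None
    models = None
    if config.synthetic:
        syn = generate(
            SyntheticConfig(
                n_genes=config.synthetic_n_genes, seed=config.seed,
                tissue_exclusive_fraction=0.02,
            )
        )
        paths = syn.write(out / "inputs")
        cds_raw = syn.cds
        genome = syn.genome
        models = gio.read_gene_models(paths["gff3"])
        table = syn.expression
        trna_table = syn.trna_table
    else:
        if not (config.cds_fasta and config.expression_tsv):
            raise ValueError("non-synthetic runs need cds_fasta and expression_tsv")
        cds_raw = gio.read_fasta(config.cds_fasta)
        table = expr.load_expression(config.expression_tsv, config.tissue_map)
        if config.trna_table:
            if config.trna_format == "trnascan":
                trna_table = ta.parse_trnascan(config.trna_table)
            else:
                trna_table = ta.read_anticodon_counts(config.trna_table)
        else:
            logger.warning("no tRNA table supplied; using the packaged table")
            _, trna_table = table1_fixture()
        if config.genome_fasta and config.gff3:
            genome = gio.read_fasta(config.genome_fasta)
            models = gio.read_gene_models(config.gff3)

    cds_records = gio.select_cds(cds_raw, min_len_nt=config.min_cds_len)
    cds_by_gene = {c.gene_id: c for c in cds_records}
    logger.info("retained %d validated CDS", len(cds_records))

    # ---- stage: gene sets ----------------------------------------------
    organism_mean = expr.mean_expression(table, "organism")
    organism_mean = organism_mean[organism_mean.index.isin(cds_by_gene)]
    extremes = expr.select_extremes(
        organism_mean, fraction=config.fraction, basis="organism_wide"
    )
    logger.info(
        "organism-wide sets: %d high (cutoff %.3f FPKM), %d low (cutoff %.3f)",
        len(extremes.high), extremes.cutoff_high,
        len(extremes.low), extremes.cutoff_low,
    )
    one_tissue = {
        t: frozenset(
            g for g in expr.top5_one_tissue(table, t, config.fraction)
            if g in cds_by_gene
        )
        for t in table.tissues
    }
    gene_sets = {
        "high": sorted(extremes.high), "low": sorted(extremes.low),
        "cutoff_high": extremes.cutoff_high, "cutoff_low": extremes.cutoff_low,
        "top5_one_tissue": {t: sorted(s) for t, s in one_tissue.items()},
    }
    (out / "gene_sets.json").write_text(json.dumps(gene_sets, indent=1))

    # ---- stage: dRSCU and optimal calling ------------------------------
    profiles = {g: cm.rscu(c) for g, c in cds_by_gene.items()}
    high_profiles = [profiles[g] for g in sorted(extremes.high)]
    low_profiles = [profiles[g] for g in sorted(extremes.low)]
    records = cm.delta_rscu(high_profiles, low_profiles, alpha=config.alpha)
    optimal = cm.call_optimal_codons(
        records, alpha=config.alpha, use_bonferroni=config.use_bonferroni
    )
    delta_table = _delta_table(records, optimal)
    delta_table.to_csv(out / "delta_rscu.tsv", sep="\t", index=False)

    # ---- stage: Fop per tissue -----------------------------------------
    fop_rows = []
    if optimal.primary_optimal:
        for tissue, genes in one_tissue.items():
            vals = [
                cm.fop(cds_by_gene[g], optimal) for g in sorted(genes)
            ]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                fop_rows.append(
                    {
                        "tissue": tissue, "n_genes": len(vals),
                        "median_fop": float(np.median(vals)),
                        "mean_fop": float(np.mean(vals)),
                    }
                )
    fop_by_tissue = pd.DataFrame(fop_rows)
    fop_by_tissue.to_csv(out / "fop_by_tissue.tsv", sep="\t", index=False)

    # ---- stage: tRNA classification ------------------------------------
    status = ta.classify_codon_status(
        optimal, trna_table,
        opt_threshold=config.opt_trna_threshold,
        nonopt_threshold=config.nonopt_trna_threshold,
    )
    ta.write_status_table(status, out / "codon_status.tsv")

    # ---- stage: intron analyses ----------------------------------------
    ati_bins_df = None
    correlations: dict[str, dict] = {}
    if genome is not None and models is not None:
        raw_introns = gio.extract_introns(models, genome)
        kept = gio.trim_and_filter_introns(
            raw_introns, trim_each_end=config.intron_trim,
            min_len_after=config.intron_min_len,
        )
        comp_records = []
        for intr in kept:
            g = intr.gene_id
            if g not in cds_by_gene or g not in organism_mean.index:
                continue
            cds = cds_by_gene[g]
            comp_records.append(
                ic.GeneCompositionRecord(
                    gene_id=g,
                    at_i=ic.at_content(intr.seq),
                    at3=cm.at3(cds),
                    at_cds=ic.at_content(cds.seq),
                    expression_mean=float(organism_mean[g]),
                    intron_raw_length=intr.raw_length,
                )
            )
        by_gene = {r.gene_id: r for r in comp_records}
        high_comp = [by_gene[g] for g in sorted(extremes.high) if g in by_gene]
        low_comp = [by_gene[g] for g in sorted(extremes.low) if g in by_gene]
        if high_comp and low_comp:
            bins = ic.binned_at3_comparison(high_comp, low_comp, config.ati_edges)
            ati_bins_df = pd.DataFrame([asdict(b) for b in bins])
            ati_bins_df.to_csv(out / "ati_bins.tsv", sep="\t", index=False)
            fold, fold_p = ic.intron_length_comparison(high_comp, low_comp)
            correlations["intron_length_fold_low_over_high"] = {
                "value": fold, "mwu_p": fold_p,
            }
        if high_comp and low_comp:
            box = ic.boxplot_data(
                {
                    f"{grp}:{b}": [
                        r.at3 for r in ic.bin_by_ati(recs, config.ati_edges)[b]
                    ]
                    for grp, recs in (("high", high_comp), ("low", low_comp))
                    for b in ic.bin_labels(config.ati_edges)
                }
            )
            (out / "at3_by_ati_bin_boxplot.json").write_text(
                json.dumps(box, indent=1)
            )
        if len(comp_records) >= 10:
            for which in ("at_i", "at3"):
                res = ic.expression_composition_correlation(comp_records, which)
                correlations[f"expression_vs_{which}"] = res.as_dict()
        index_at = {r.gene_id: r.at_i for r in comp_records}
        gio.write_intron_index(kept, index_at, out / "intron_index.tsv")

    # ---- stage: amino-acid analyses ------------------------------------
    high_freqs = aaa.per_gene_frequencies(
        [cds_by_gene[g] for g in sorted(extremes.high)]
    )
    low_freqs = aaa.per_gene_frequencies(
        [cds_by_gene[g] for g in sorted(extremes.low)]
    )
    usage_high = aaa.aa_frequencies(
        [cds_by_gene[g] for g in sorted(extremes.high)], context="high"
    )
    usage_low = aaa.aa_frequencies(
        [cds_by_gene[g] for g in sorted(extremes.low)], context="low"
    )
    comparisons = aaa.high_low_aa_tests(high_freqs, low_freqs, alpha=config.alpha)
    props = aaa.amino_acid_properties()
    aa_table = aaa.usage_report(usage_high, usage_low, comparisons, props,
                                trna_table)
    aa_table.to_csv(out / "amino_acid_table.tsv", sep="\t")
    correlations["usage_high_vs_sc"] = aaa.property_correlation(
        usage_high, props, "sc").as_dict()
    correlations["usage_low_vs_sc"] = aaa.property_correlation(
        usage_low, props, "sc").as_dict()
    correlations["usage_high_vs_trna"] = aaa.usage_trna_correlation(
        usage_high, trna_table).as_dict()
    correlations["trna_vs_sc"] = aaa.trna_cost_correlation(
        trna_table, props).as_dict()
    correlations["folding_class_rank_anova"] = aaa.folding_class_test(
        usage_high, props).as_dict()

    # ---- stage: elevated-use gene lists (wobble + example codons) ------
    elevated: dict[str, list] = {}
    wobble_codons = [
        r.codon for r in status if r.status == "Opt_wobble"
    ]
    for codon in wobble_codons:
        members = cm.elevated_use_genes(
            extremes.high, profiles, codon, threshold=config.rscu_elevated
        )
        elevated[codon] = sorted(members)
    (out / "elevated_use.json").write_text(json.dumps(elevated, indent=1))

    # ---- report summary -------------------------------------------------
    summary = {
        "config_hash": chash,
        "n_cds": len(cds_records),
        "n_high": len(extremes.high),
        "n_low": len(extremes.low),
        "n_optimal": len(optimal.primary_optimal),
        "n_nonoptimal": len(optimal.primary_nonoptimal),
        "status_counts": {
            s: sum(1 for r in status if r.status == s)
            for s in sorted({r.status for r in status})
        },
        "correlations": correlations,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    return AnalysisReport(
        config_hash=chash,
        optimal_codon_table=delta_table,
        codon_status=status,
        fop_by_tissue=fop_by_tissue,
        ati_bins=ati_bins_df,
        amino_acid_table=aa_table,
        correlations=correlations,
        elevated_use=elevated,
        gene_sets=gene_sets,
    )
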
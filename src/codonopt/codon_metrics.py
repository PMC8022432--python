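"""Core codon-usage statistics: RSCU, dRSCU, optimal-codon calls, Fop, AT3.

RSCU for codon i of an amino-acid family of size k with per-gene counts
n_1..n_k is k * n_i / sum(n_j); 1 means equal synonymous use.  dRSCU for a
codon is mean RSCU over highly expressed genes minus mean RSCU over lowly
expressed genes, each mean taken over the genes where the codon's family is
present.  The primary optimal (non-optimal) codon per amino acid is the
codon with the largest positive (negative) and statistically significant
dRSCU; significance is a two-tailed Welch t-test of per-gene RSCU values
with Bonferroni correction over the 59 tested codons.

Fop (frequency of optimal codons) for a gene is the count of primary
optimal codons over the count of codons belonging to amino acids that have
a primary optimal codon (CodonW convention).  AT3 is the fraction of scored
codons whose third base is A or T, scoring only codons with a synonymous
choice (Met/Trp/stop excluded; an all-codons variant is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import STANDARD_CODE, GeneticCode
from .stat_core import bonferroni, student_t, welch_t

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RscuProfile:
    """Per-gene codon counts and RSCU values (undefined families absent)."""

    gene_id: str
    counts: dict  # codon -> int, all sense codons
    rscu: dict    # codon -> float, only codons of families with counts > 0


@dataclass(frozen=True)
class DeltaRscuRecord:
    codon: str
    amino_acid: str
    delta: float
    mean_high: float
    mean_low: float
    t_stat: float
    p_raw: float
    p_bonf: float
    n_high: int
    n_low: int
    flagged: bool = False  # defined in < 2 genes on either side


@dataclass(frozen=True)
class OptimalCodonSet:
    """Primary optimal / non-optimal codon per amino acid plus secondaries."""

    primary_optimal: dict      # amino acid -> codon
    primary_nonoptimal: dict   # amino acid -> codon
    secondary_optimal: dict    # amino acid -> list of codons
    alpha: float

    @property
    def optimal_codons(self) -> frozenset:
        return frozenset(self.primary_optimal.values())


@dataclass(frozen=True)
class GeneCodonSummary:
    gene_id: str
    fop: float
    at3: float
    n_codons_scored: int


def _contains_n(codon: str) -> bool:
    return any(b not in "ACGT" for b in codon)


def codon_counts(cds, code: GeneticCode = STANDARD_CODE) -> dict:
    """Sense-codon counts for one CDS; codons containing N are skipped."""
    counts = {c: 0 for c in code.sense_codons}
    for codon in cds.codons:
        if _contains_n(codon):
            continue
        if codon in counts:
            counts[codon] += 1
    return counts


def rscu(cds, code: GeneticCode = STANDARD_CODE) -> RscuProfile:
    """RSCU profile of one gene; families absent from the gene are undefined."""
    counts = codon_counts(cds, code)
    values: dict[str, float] = {}
    for aa, family in code.families.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            continue
        k = len(family)
        for c in family:
            values[c] = k * counts[c] / total
    return RscuProfile(gene_id=cds.gene_id, counts=counts, rscu=values)


def delta_rscu(
    high,
    low,
    alpha: float = 0.05,
    code: GeneticCode = STANDARD_CODE,
    pooled_t: bool = False,
) -> list[DeltaRscuRecord]:
    """Per-codon dRSCU between two RscuProfile lists with significance.

    Means are taken over the genes where the codon's family is defined.
    Welch (default) or pooled Student t per codon; Bonferroni over the 59
    synonymous codons.  Codons observed in fewer than two genes on either
    side carry NaN p-values and are flagged.
    """
    if not high or not low:
        raise ValueError("both gene sets must be non-empty")
    test = student_t if pooled_t else welch_t
    codons = code.synonymous_codons
    raw_p = np.full(len(codons), np.nan)
    partial: list[dict] = []
    for i, codon in enumerate(codons):
        aa = code.codon_to_aa[codon]
        vals_h = np.array([p.rscu[codon] for p in high if codon in p.rscu])
        vals_l = np.array([p.rscu[codon] for p in low if codon in p.rscu])
        flagged = vals_h.size < 2 or vals_l.size < 2
        mean_h = float(vals_h.mean()) if vals_h.size else float("nan")
        mean_l = float(vals_l.mean()) if vals_l.size else float("nan")
        if flagged:
            t_stat = float("nan")
        else:
            res = test(vals_h, vals_l)
            t_stat = res.statistic
            raw_p[i] = res.p_value
        partial.append(
            dict(
                codon=codon, amino_acid=aa, delta=mean_h - mean_l,
                mean_high=mean_h, mean_low=mean_l, t_stat=t_stat,
                n_high=int(vals_h.size), n_low=int(vals_l.size), flagged=flagged,
            )
        )
    # Bonferroni over the full tested family of 59 codons
    adj = np.minimum(raw_p * len(codons), 1.0)
    records = []
    for i, d in enumerate(partial):
        records.append(
            DeltaRscuRecord(p_raw=float(raw_p[i]), p_bonf=float(adj[i]), **d)
        )
    return records


def call_optimal_codons(
    records,
    alpha: float = 0.05,
    use_bonferroni: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> OptimalCodonSet:
    """Primary optimal / non-optimal codon per amino acid from dRSCU records.

    Primary optimal: significant positive dRSCU of largest magnitude;
    primary non-optimal: significant negative dRSCU of largest magnitude.
    Ties broken by smaller p, then alphabetical codon (logged).
    """
    by_aa: dict[str, list[DeltaRscuRecord]] = {}
    for rec in records:
        by_aa.setdefault(rec.amino_acid, []).append(rec)
    optimal: dict[str, str] = {}
    nonoptimal: dict[str, str] = {}
    secondary: dict[str, list[str]] = {}

    def pvalue(rec: DeltaRscuRecord) -> float:
        return rec.p_bonf if use_bonferroni else rec.p_raw

    for aa, recs in by_aa.items():
        sig = [r for r in recs if np.isfinite(pvalue(r)) and pvalue(r) < alpha]
        pos = [r for r in sig if r.delta > 0]
        neg = [r for r in sig if r.delta < 0]
        if pos:
            best = sorted(pos, key=lambda r: (-r.delta, pvalue(r), r.codon))
            if len(best) > 1 and best[0].delta == best[1].delta:
                logger.info("optimal-codon tie for %s broken by p then codon", aa)
            optimal[aa] = best[0].codon
            secondary[aa] = [r.codon for r in best[1:]]
        if neg:
            worst = sorted(neg, key=lambda r: (r.delta, pvalue(r), r.codon))
            if len(worst) > 1 and worst[0].delta == worst[1].delta:
                logger.info("non-optimal tie for %s broken by p then codon", aa)
            nonoptimal[aa] = worst[0].codon
    return OptimalCodonSet(
        primary_optimal=optimal, primary_nonoptimal=nonoptimal,
        secondary_optimal=secondary, alpha=alpha,
    )


def fop(
    cds,
    optimal: OptimalCodonSet,
    include_secondary: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Frequency of optimal codons for one gene; NaN when undefined.

    Denominator: codons of amino acids that have a primary optimal codon
    (Met/Trp and stops never contribute).  ``include_secondary`` also counts
    the positive-significant non-primary codons as optimal.
    """
    if not optimal.primary_optimal:
        raise ValueError("optimal set has no primary optimal codons")
    scored_aas = set(optimal.primary_optimal)
    counted = set(optimal.primary_optimal.values())
    if include_secondary:
        for aa, extras in optimal.secondary_optimal.items():
            counted.update(extras)
    num = 0
    denom = 0
    for codon in cds.codons:
        aa = code.codon_to_aa.get(codon)
        if aa is None or aa not in scored_aas or _contains_n(codon):
            continue
        denom += 1
        if codon in counted:
            num += 1
    if denom == 0:
        logger.warning("gene %s has no codons scorable for Fop", cds.gene_id)
        return float("nan")
    return num / denom


def at3(cds, code: GeneticCode = STANDARD_CODE, all_codons: bool = False) -> float:
    """Fraction of scored codons with A or T at the third position.

    Default scores only codons with a synonymous choice (excludes Met, Trp
    and stops, which never appear in a validated codon list); the
    ``all_codons`` variant scores every sense codon.
    """
    num = 0
    denom = 0
    for codon in cds.codons:
        aa = code.codon_to_aa.get(codon)
        if aa is None or _contains_n(codon):
            continue
        if not all_codons and len(code.families[aa]) == 1:
            continue
        denom += 1
        if codon[2] in "AT":
            num += 1
    if denom == 0:
        return float("nan")
    return num / denom


def gene_codon_summary(cds, optimal: OptimalCodonSet,
                       code: GeneticCode = STANDARD_CODE) -> GeneCodonSummary:
    scored = sum(
        1 for c in cds.codons
        if c in code.codon_to_aa and not _contains_n(c)
        and len(code.families[code.codon_to_aa[c]]) > 1
    )
    return GeneCodonSummary(
        gene_id=cds.gene_id,
        fop=fop(cds, optimal, code=code),
        at3=at3(cds, code=code),
        n_codons_scored=scored,
    )


def elevated_use_genes(
    genes, profiles, codon: str, threshold: float = 1.5,
    code: GeneticCode = STANDARD_CODE,
) -> frozenset:
    """Genes whose RSCU for ``codon`` is defined and >= ``threshold``."""
    aa = code.codon_to_aa.get(codon)
    if aa is None or len(code.families[aa]) < 2:
        raise ValueError(f"{codon!r} is not a synonymous-family codon")
    selected = set()
    for g in genes:
        prof = profiles.get(g)
        if prof is not None and prof.rscu.get(codon, float("-inf")) >= threshold:
            selected.add(g)
    return frozenset(selected)
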
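# Methods

## Model and procedure

The package treats optimal-codon identification as a contrast between
expression extremes. Gene-level expression is an FPKM matrix over nine
tissues (four paired male/female tissues plus male accessory glands) with
replicate samples; the organism-wide expression of a gene is the unweighted
mean of its nine tissue means, with replicates averaged within tissue
first. Averaging in two stages prevents tissues with more replicates from
dominating the organism-wide mean; a flat per-sample mean is available via
`replicate_weighted=True`.

High and low gene sets are the top and bottom 5% of genes by the chosen
expression basis. Ties at the boundary value are included on both tails
(the source analyses state tie inclusion for the low tail; we apply it
symmetrically, since dropping an arbitrary subset of tied genes would make
the selection order-dependent). Genes with zero FPKM are eligible for the
low set. The tissue-exclusive sets ("top 5% in exactly one tissue") are
computed against per-tissue means with the same tie rule and are pairwise
disjoint by construction.

RSCU is computed per gene and per synonymous family (`k · n_i / Σ n_j`);
families absent from a gene are undefined rather than zero, and genes where
a family is absent are excluded from that family's codon means — the
convention of the CAICAL lineage of tools. ΔRSCU per codon is the
difference of those means, tested with a two-tailed Welch t-test on the
per-gene RSCU values and Bonferroni-corrected across the 59 synonymous
codons. Welch rather than pooled Student is the default because the
high/low groups routinely have unequal RSCU variances (the published
summary statistics show heterogeneous SEs); a pooled variant is available
by flag. Primary optimal / non-optimal calls take the largest significant
positive / negative ΔRSCU per amino acid; exact ties break by smaller
p-value and then alphabetical codon so outputs are deterministic.

Fop divides a gene's primary-optimal-codon count by the count of codons
belonging to amino acids that have a primary optimal codon (CodonW
convention; Met, Trp and stops never enter). AT3 scores only codons with a
synonymous choice, again excluding Met/Trp/stop, so the statistic reflects
synonymous-site choice rather than amino-acid composition; an all-codons
variant exists for comparison with GC3-style measures.

tRNA gene-copy counts are aggregated per anticodon from tRNAscan-SE v2
tabular output (pseudogenes, selenocysteine, suppressor and
undetermined-anticodon rows excluded; initiator and elongator Met both
count toward CAU). A codon's exact decoder is its Watson–Crick reverse
complement written 5'→3' in RNA. For codons with zero exact matches, the
wobble decoder is the G34 anticodon of the synonymous NNC codon for
U(T)-ending codons (G:U wobble), with a genomically-A34 (inosine I34)
fallback for U/C/A-ending codons. Status thresholds are ≥ 18 exact copies
for the high-tRNA optimal class and ≥ 15 for the high-tRNA non-optimal
class, both exposed as knobs; optimal codons with 1–17 copies fall into an
explicit `unclassified` band rather than being silently merged (the band is
empty on the packaged reference table, and keeping it explicit preserves
the two described optimal statuses faithfully).

The intron control trims 10 nt from each intron end (putative
splice-regulatory sequence), keeps introns with ≥ 50 nt remaining, and uses
the longest intron per gene (selected by raw length before trimming, so the
choice is independent of the trim width). The ≥ 50 reading of the length
filter is used (the source describes it both as "> 50" and "≥ 50"; the
boundary is a config knob). AT-I bins are right-closed
(≤ 0.5, > 0.5–0.6, …, > 0.8); per-bin contrasts use two-sided Mann–Whitney
U tests, exact when the pooled tie-free sample is ≤ 12, otherwise the
normal approximation with tie and continuity correction. The intron-length
contrast reports the ratio of group medians (means by flag).

Amino-acid analyses use per-gene percent residue frequencies (rows sum to
100). Cost is the Dufton size/complexity score transcribed from the
published usage table (Gly = 1 … Trp = 73). Hydropathy is the
Kyte–Doolittle index and the three folding classes (alpha former, beta
former, breaker) follow Chou–Fasman-style propensities; both are packaged
constants overridable through `amino_acid_properties(...)` for sensitivity
analysis. Correlations "across the 20 amino acids" use mean frequencies,
which reproduces the published rank correlations; a gene-level mode that
pools per-gene (frequency, property) pairs is provided for the hydropathy
analysis, whose published form is gene-based. Percent difference is
(high − low)/high × 100 — the only convention consistent with the
published signs and magnitudes (verified on Gly, Ile and Lys). Spearman
p-values use the exact permutation distribution for n ≤ 9 and the
t-approximation otherwise; p-values are floored at the smallest positive
double and never reported as exactly zero.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analyses assume, not
an evolutionary mechanism. Expression is log-normal (location 1.5, scale
2.0 in log-FPKM — a heavy-tailed profile with a realistic dynamic range),
with per-tissue log-noise 0.6 and per-replicate log-noise 0.2. Codon choice
per amino-acid site is a family-level multinomial whose planted-codon
probability is logistic in β·z (z = standardized log mean expression,
β = 1.0 by default), so planted-codon RSCU rises smoothly with expression;
the planted set defaults to the published AT3 optimal set, making AT3 the
emergent signature. Amino-acid composition is Dirichlet (concentration 120)
around the published high-expression means; protein lengths are log-normal
around 300 codons. 90.5% of genes carry one intron (the published fraction
of genes with usable introns); intron AT is Beta-distributed
(concentration 150) with mean 0.637 (the published genome-wide median)
plus an expression slope of 0.015, and intron length is log-normal with an
expression slope calibrated so the bottom/top 5% strata differ by the
planted fold (1.9 by default). Planted tissue-exclusive genes start from
the median base expression so that their tissue boost makes them
top-ranked in exactly one tissue. The tRNA table defaults to the packaged
per-anticodon reference counts, which are consistent with the planted
statuses (wobble-optimal codons have zero exact copies and well-stocked
G34 partners). One named RNG stream per component (expression,
composition, sequence, introns) hangs off the single seed, so enlarging
one component does not reshuffle the others.

Passing tests on this generator demonstrate that the pipeline recovers
planted structure of the published shape and calibration; they do not
demonstrate robustness to features of real data the generator omits —
isoform structure, multi-intron genes, GC-heterogeneous contigs,
expression correlated with gene length, mapping noise in FPKM, or
tRNA-count error.

## Numerical choices and degenerate inputs

CDS validation drops a trailing 1–2 nt frame remainder with a warning,
strips the terminal stop, and excludes (non-fatally) records with internal
stops; the start-codon filter runs before longest-isoform selection.
Codons containing N are excluded from all codon counts; N bases are
excluded from both numerator and denominator of AT content. Coordinates
are GFF3 1-based inclusive on input and 0-based half-open internally.
Codons observed in fewer than two genes on either side of a ΔRSCU contrast
carry NaN p-values and are flagged; empty families are undefined, not
zero. A Welch test with zero variance in both groups returns p = 1 at
equal means and the floored minimum p otherwise, flagged either way.
Constant vectors leave Spearman undefined (NaN, flagged). Bins with fewer
than two genes in either expression group are reported but not tested.

## Problem sizes

The test suite runs the generator at 300–2000 genes: recovery of the
planted optimal set uses 2000 genes (one seed), the no-bias null
calibration uses 100 seeds at 300 genes, and the binned AT3 control uses
12 seeds at 1200 genes. These sizes give the recovery and calibration
checks comfortable statistical margins while keeping the whole suite
around half a minute on one CPU.

## Known limitations

The wobble rules cover G:U and inosine 34 pairing only; modified-base
decoding beyond inosine (e.g. U34 superwobble for G-ending codons) is not
modelled, which is sufficient for the packaged reference table since every
zero-tRNA codon there ends in U/T. The pipeline consumes FPKM as given and
performs no cross-library normalisation. Biased gene conversion is not
modelled; the AT-I binning controls for it only to the extent that it acts
equally on a gene's introns and synonymous sites. The Bonferroni family is
fixed at one ΔRSCU analysis (59 codons) or one usage contrast (20 amino
acids); cross-analysis multiplicity is left to the reader.
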
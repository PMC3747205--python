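# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of the `translatome` package.

## Polysome-content quantification

A polysome profile is a vector of non-negative RNA signal over ordered,
equal-volume gradient fractions (low index = top of gradient). Polysome
content is the percentage of total net signal in the designated polysomal
fractions, with plain sums over fractions (no trapezoidal weighting, since
fractions are equal-volume aliquots). Two baseline conventions are exposed:

* `constant-min` (default): subtract the minimum fraction signal. This is
  the conservative, parameter-free reading of "gradient baseline"; it
  removes any constant offset exactly.
* `linear-endpoints`: subtract the straight line through the first and
  last fractions, for sloped baselines. Net values are clamped at zero.

Fractions outside both the NP (default 1–8) and P (default 11–16) sets —
the monosome/disome shoulder — count in the denominator but not the
numerator, matching the definition of PC as polysomal share of *total*
signal. PC is scale invariant and strictly monotone in polysomal mass.

The per-replicate PC normalization factor is PC_stress/PC_control. Because
equal RNA amounts are processed per sample, the stress-PB measurements sit
on an inflated scale; shifting them by log2(factor) restores the absolute
polysome-loading scale. Only stress-PB samples are adjusted (control PB is
the reference), pairing factors to samples by replicate index.

qPCR support: relative quantities of stress-PB samples are multiplied by
the same factor, and per-fraction transcript distributions are derived from
Ct values as weight_f = E^(−Ct_f) normalized to 100%, with amplification
efficiency E = 2 unless a standard-curve value is supplied. The minimum Ct
is subtracted before exponentiation for numerical stability; the
normalization cancels the shift exactly, so the distribution is invariant
to adding a constant to all Ct values.

## Differential statistics

Contrasts are two-group comparisons (stress vs control) within one RNA
population, with pooled within-group variance on n₁ + n₂ − 2 df. The
empirical-Bayes prior (d₀, s₀²) is fitted by moment matching of
log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of
var(e) over the mean sampling variance ψ′(d_g/2) identifies ψ′(d₀/2),
solved by Newton iteration on the trigamma inverse to |Δ| < 1e-8
(the same algorithm as the Bioconductor reference implementation, against
which the fit and the t-statistics are cross-checked in the test suite to
1e-6 / 1e-8). If the observed dispersion does not exceed its sampling
minimum, d₀ = ∞ (complete shrinkage) and s₀² = exp(mean e), i.e. the
log-scale-bias-corrected common variance. p-values use d₀ + d_g df; d₀ = 0
reproduces the ordinary pooled t exactly, and d₀ = ∞ uses a normal
reference.

Degenerate input: with exactly replicated values (zero pooled variance for
every gene, as in noise-free simulations) the moderated t is undefined; the
implementation returns the noise-free limit — any nonzero log2FC has p = 0
(t = ±∞), zero change has p = 1 — so downstream stages still run.

BH adjustment is the standard step-up (via statsmodels), ties broken by
stable rank order; calls require |log2FC| ≥ log2(2) (inclusive) and
FDR < 0.05 (strict), exactly as the calling rule is stated. Venn
partitioning of the TOT- and PB-significant sets is plain set arithmetic,
separately for up- and down-regulation.

## Translation-efficiency classes

TE and relative TE are computed from replicate means on the log2 scale and
exponentiated; relative TE equals TE_stress/TE_control algebraically. The
class partition uses the arithmetic mean of the *linear* relative-TE
distribution as anchor (a geometric-mean alternative sits behind
`scale="log"`), with a symmetric fold window: Class I ≤ mean/1.5,
Class III ≥ mean·1.5, boundaries belonging to the flanking classes. The
symmetric reading is deliberate: a literal "≤ 1.5 × mean" lower class
would swallow most of the distribution, whereas the symmetric window
reproduces small flanking classes around a large average class. Genes with
missing values are excluded before averaging, mirroring a
complete-information analysis universe. Labels are scale invariant.

## Sequence features

Gene models are one representative model per gene, either as per-region
FASTA records (`GENE.5utr/.cds/.3utr`) or genome FASTA + GFF3 (1-based
inclusive; strand resolved at load so all downstream code sees mRNA
orientation; multi-segment regions are concatenated in genomic order before
reverse complementing). Genes missing any of the three regions are dropped
and counted. Only A/C/G/T/N are accepted; other ambiguity codes raise.

G+C percentages exclude N from numerator and denominator. The first-10-nt
5′UTR G+C falls back to the full UTR when shorter than 10 nt and flags the
record. uAUG counting is permissive: every ATG occurrence in the 5′UTR, all
frames, overlapping, without requiring a downstream stop — a putative-uAUG
count. cDNA length bins are [1,1000) / [1000,2000] / (2000,∞): the middle
bin is written inclusively and the flanks strictly, so the boundary values
1000 and 2000 belong to the middle bin. Folding energies are never computed
internally; a per-gene ΔG table (kcal/mol) may be joined by gene ID, and
ΔG comparisons are simply absent without it.

## Association statistics

Two-sample KS tests compute D = sup|F̂₁ − F̂₂| over the pooled sample. For
n₁·n₂ ≤ 100 the p-value is the exact permutation tail, enumerated over all
C(n₁+n₂, n₁) splits of the pooled sample (ties handled by the
right-continuous ECDF convention); otherwise the Kolmogorov statistic's
distribution is evaluated at the rounded effective size n₁n₂/(n₁+n₂) —
the standard two-sample asymptotic, matching scipy's. The threshold between
modes is exposed (`exact_limit`). Tests are two-sided.

The class-feature summary reports per-class medians for every numeric
feature, the percentage of genes with ≥ k uAUGs (k = 1..4), and KS tests of
Classes I and III against the reference Class II. A feature is starred when
both flanking p-values fall below 0.001 **and** the three class medians are
strictly monotone — the operationalization of "significant with a
correlation to relative TE"; monotone medians stand in for a correlation
the source rule does not formalize. Classes with fewer than 3 genes are
summarized but not tested (warning). Genome-subset comparisons (e.g. a
class's length distribution against the whole universe) use the universe
as reference, with the subset included in it.

Note a deliberately small planted effect: with the per-class 5′UTR G+C
means 42.33/37.61/36.07% and a realistic ~7.5 pp within-class spread, the
resistant-vs-average flank differs by only 1.5 pp, so at the simulated
class sizes that flank does not reach p < 0.001 and the G+C feature earns
no asterisk under the default conditions; the sensitive flank (4.7 pp) is
detected at far below 0.001. The length features, whose planted effects are
large, are starred.

## Enrichment

Singular mode: upper-tail hypergeometric per term for the overlap between a
class and the term within the analysis universe, BH across terms. Ranked
mode: the universe ordered by decreasing relative TE is cut at the
n_partitions − 1 internal equal-count boundaries (default 30 partitions,
exposed); at each cut both one-sided hypergeometric tails (enrichment above
= "top", below = "bottom") are evaluated and the smaller kept with its
direction; BH runs jointly across all term × cut tests (conservative by
design). One-sided tails were chosen over a two-sided Fisher so that when a
term occupies a rank prefix isolated by a cut, the ranked p equals the
singular p for the same set exactly; reversing the ranking flips every
direction and leaves p-values unchanged. Annotations are flat term → gene
sets (two-column TSV or GAF); GO DAG propagation is the caller's
responsibility.

## The synthetic-data model

Per gene, a class label is drawn with proportions 696/16098, 14946/16098,
456/16098 (the exact fractions; their rounded three-decimal forms do not
sum to 1). The planted linear relative TE is the global loading factor
(default 0.564) times the class multiplier (1/2.5, 1, 2.5) — multipliers
sit well beyond the 1.5× window so that replicate noise, not overlap,
controls recovery difficulty. An optional log2-scale within-class scatter
(`te_scatter_sd`, default 0) spreads the planted values. Heat-induced
total-mRNA changes are N(0, 0.8²) on log2 (no magnitude is reported for
real data; 0.8 gives a realistic mix of called and uncalled transcriptional
changes), baseline abundance N(8, 1.5²) log2, baseline control TE scatter
N(0, 0.4²) log2, and i.i.d. replicate noise N(0, 0.15²) log2 per cell — a
typical well-replicated array dispersion; the magnitude is a package
choice, flagged in the config.

The expression matrices are built as
TOT22 = base, TOT38 = base + Δtot, PB22 = base + te₀,
PB38 = base + Δtot + te₀ + log2(relTE), plus noise; each PB38 replicate is
then **sum-rescaled** (linear scale) to carry the same total signal as its
paired PB22 replicate. This erases the global loading reduction from the
matrix — a naive analysis sees mean relative TE ≈ 1 — and the erased linear
factor is emitted as that replicate's planted PC ratio
(PC_stress = 20% × factor, control PC 20%). PC adjustment with these
factors restores the planted scale exactly, which is why the noise-free
round trip recovers the planted relative TE to better than 1e-9 on the
log2 scale: the correction adds back the very constant the rescaling
removed.

Simulated gradient profiles are constructed to reproduce a requested PC
exactly: a random non-negative shape (monosome peak plus polysome bump) is
shifted to zero minimum, the polysomal and non-polysomal blocks are scaled
to sum to PC and 100 − PC, and an optional constant baseline is added —
which constant-min subtraction removes exactly, so PC computed from the
written profile equals the planted value to float precision (the 0.5-point
contract is met with large margin).

Features are drawn per class — log-normal lengths (cDNA medians
1204/1641/2323 nt, σ_log 0.45; UTR lengths around their class medians),
Beta-distributed G+C (class means as above, concentration 40 ≈ 7.5 pp sd),
Poisson uAUG counts with rates matched to the uAUG ≥ 1 prevalences — and
CDS length is the cDNA remainder (floored at 75 nt, *not* rounded to codon
multiples: the class medians are not all divisible by 3, and the gene-model
contract tolerates and flags out-of-frame CDSs). The coupling is
generative, not causal: features do not determine TE in the simulator.
Sequence realization draws i.i.d. nucleotides at each gene's planted G+C,
scrubs accidental ATGs from the 5′UTR by A→T substitution (G+C preserving)
and plants exactly `n_uaug` non-overlapping ATGs; realized feature tables
are recomputed from the final sequences.

### What the simulator does not emulate

Probe-level effects, array spatial artifacts, intensity-dependent variance,
correlated noise between populations, multi-isoform genes, qPCR chemistry
beyond ideal efficiency, and any causal feature→TE mechanism. Passing
recovery tests therefore demonstrates the pipeline's correctness under its
own model assumptions, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Trigamma inverse: Newton iteration from 0.5 + 1/y, tolerance 1e-8,
  closed-form limits for extreme arguments.
* KS p-values clipped to (0, 1]; exact-mode ties compared with a 1e-12
  slack.
* BH via the standard cumulative-minimum step-up, order invariant.
* Zero replicate variance: see the noise-free limit above. Zero total
  gradient signal, empty samples/classes below size 3, factor ≤ 0,
  p-values outside [0,1], duplicate gene IDs or rankings all raise with
  explicit messages.
* All pipeline randomness flows from the single config seed through named
  substreams (`default_rng([seed, stream])`); reruns are byte-identical,
  TSVs written with a fixed float format.

## Problem sizes used in the checks

The default verification runs use the full 20000-gene universe for class
and feature recovery (seconds on one CPU), 2000-gene runs for pipeline
integration, and a 20000-replicate Monte Carlo for the KS null calibration
— at n₁ = n₂ = 50 the statistic is discrete and the exact test level at
nominal 0.05 is 0.0392 (computed independently by lattice-path counting),
so enough replicates are used for the estimate to resolve that level
within ±0.015 of 0.05.

## Known limitations

* The moderated t assumes a shared two-group design per population;
  multi-factor designs are out of scope.
* The asterisk rule (monotone medians + both flanks at p < 0.001) is one
  reasonable formalization among several.
* Ranked enrichment's joint BH over term × cut is conservative; per-term
  best-cut selection is not corrected for adaptivity beyond that.
* Real annotation inputs must already be one representative model per
  gene; no model selection is performed.
* ΔG values are consumed, never computed.
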
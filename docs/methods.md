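# Methods

## The model

`adasnv` calls single-nucleotide variants from coordinate-sorted
alignments with a *data-adaptive* score rather than a genotype
likelihood.  The observed mismatch rate at reference position *i*,

    δᵢ = |M̄ᵢ| / |Cᵢ|,

decomposes as δ = β + ε: biological allele fraction β plus the compound
technical error ε of library preparation, sequencing and alignment.
Because the overwhelming majority of sites carry no variant, the data
themselves estimate the error process: the caller samples sites with
`0 < δ < 0.5` and tabulates how matches and mismatches distribute over
four per-base characteristics —

* **Q**, the probability the base call is correct (`1 − 10^(−phred/10)`),
* **P**, the relative read position `k/m` within the aligned portion,
* **R**, the read's alignment edit distance (`NM` tag),
* **H**, the read's alignment multiplicity (`NH` tag).

Each site with at least one mismatch receives

    S = Δ_Q + Δ_P + Δ_R + Δ_H + log q(δ),

where each Δ averages, over the mismatch bases only and normalised by
the full coverage |C|, an empirical log-odds: `log[Q/(1−Q)]` for
qualities, `log[Pr(M|x)/(1−Pr(M|x))]` for P/R/H (with the position
component additionally shifted by `log(P_M̄/P_M)`, the ratio of the
maximal mismatch and match probabilities over position bins), and
`q(δ)` is the inclusive empirical quantile of the site's mismatch rate
across all tabulated sites.  All logarithms are natural.  Mismatches
that look like good sequence — high quality, central position, clean,
uniquely mapping reads, unusually high δ — push S up; technical errors
do not.  Sites with no mismatch enter no component of the model and are
never scored, sampled or called.

The positive scores typically form a mixture of a noise bump near zero
and a variant component to its right.  The marginal density of `S > 0`
is estimated by Lindsey's method: the histogram counts are modelled as
Poisson with a log-mean that is a natural cubic spline in the bin
midpoint.  The decision threshold S\* is the midpoint of the leftmost
strict interior local minimum of the fitted density; every site with
`S > S*` (strict by default; `--ge` switches to `>=`) is declared
variant.  When no such minimum exists, the upper 95% quantile of the
positive scores is used instead and the caller warns that the score
model does not suffice for a reliable cutoff — calling is then
conservative by construction.

The score assumes independence of the four characteristics, in the
spirit of naive-Bayes classifiers; correlations between them (e.g.
between quality and read position) are ignored.  No assumption is made
about ploidy, heterozygosity or an allele-frequency prior, which is why
the same machinery applies to haploid, diploid, pooled or tumour data.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sample_size` | 100 000 | background sites (0 < δ < 0.5) sampled by a single-pass reservoir; raise it for low-frequency designs where few sites populate the positive score range |
| `p_bins` | 50 | equal-width bins for P over (0, 1] |
| `r_max`, `h_max` | 20, 50 | identity bins for R (0…r_max) and H (1…h_max), each with an overflow bin |
| `pseudocount` | 0.5 | additive (Jeffreys) smoothing of every table cell, keeping all log-odds finite |
| `n_bins` | 100 | histogram bins over (0, max S] for the density fit |
| `df` | 7 | natural-spline degrees of freedom, the customary choice for Lindsey/Efron-style density fits |
| `min_scores` | 200 | positive scores required before a density fit is attempted |
| `fallback_quantile` | 0.95 | fallback cutoff, taken over the positive scores (the population the histogram describes) |
| `min_base_quality` | 0 (phred) | pileup filter; phred-0 bases and `N` calls are always dropped |

Base qualities are clamped into [0.001, 0.9999] before the log-odds so
that a phred-40+ or phred-0 call cannot produce an infinity.  The δ
ECDF is tabulated over **all** emitted sites including δ = 0 (so any
mismatch already lands above the bulk); `include_zero=False` restricts
it to mismatch sites.  Below the smallest tabulated δ the quantile is
floored at 1/(n_sites+1).

## Numerical choices

* The spline basis is the cubic-regression basis (`patsy` `cr`), which
  spans the constant; no separate intercept is added.
* Long interior zero runs in the histogram (the gap between the two
  score populations) make plain IRLS diverge through quasi-separation;
  the Poisson log-likelihood is concave, so it is maximised with L-BFGS
  from a log-linear least-squares start.  A failed fit signals the
  fallback path.
* "Strict local minimum" means strictly below both neighbours; plateaus
  and boundary bins never qualify.  In addition, at least 5 observed
  scores must lie to the right of a candidate minimum: a natural spline
  on the log scale will chase a single extreme score into a spike at
  the histogram boundary, and a dip in front of isolated outliers is
  not a population boundary.  Five is deliberately negligible against
  any real variant component.
* Multi-allelic mismatch sets are scored jointly (the component sums
  run over all of M̄); the reported ALT is the modal mismatch
  nucleotide, ties broken alphabetically.
* Reservoir sampling makes the background draw single-pass and exactly
  reproducible for a given seed and input order.
* The VCF QUAL column carries `max(S − S*, 0)`; the raw score, its five
  components, δ, coverage and mismatch count travel in INFO
  (HZS/HZQ/HZP/HZR/HZH/HZLQ/DELTA/DP/NMM).

## The synthetic-data generator

`adasnv.simulate` emulates a single-end, ungapped resequencing
experiment: an i.i.d. random reference, uniformly placed fixed-length
reads (default 100 bp), per-site variants whose alternative allele is
carried by each overlapping read independently with probability β, and
technical errors applied per base with probability
`ε × profile(k) × w`, where the position profile is flat or a linear
ramp (0.5→1.5, emulating end-of-read degradation) and the weight *w*
derives from a discrete phred-class distribution normalised to mean 1,
so errors concentrate on low-quality bases.  With `calibrated=True`
(default) written phred values equal the true per-base error
probability on the phred scale; with `calibrated=False` qualities are
drawn independently and carry no information, which isolates the Δ_Q
contribution in experiments.  Reads are written at their true
placements with `NM` equal to the realised mismatch count (optionally
inflated for a configurable read fraction, standing in for alignment
error) and `NH = 1` except for a configurable multi-mapper fraction.

`standard_fixtures()` exposes the desk-scale study grid on a 1 Mbp toy
genome with 1000 variants and ε = 0.01: coverages
{10, 20, 30, 50, 100, 200} crossed with allele fractions {0.2, 0.5},
plus a low-frequency grid (β ∈ {0.05, 0.1}) that carries a larger
recommended background sample (300 000).

What the generator does **not** emulate: mapper behaviour (reads are
never mis-placed, so R and H carry less signal than in real
alignments), indels, paired ends, GC or context-dependent error
structure, systematic (recurrent) sequencer errors, and real quality
miscalibration.  Passing tests therefore demonstrate the correctness
and the adaptive behaviour of the algorithm under a controlled error
model, not calling performance on real libraries.

## Behaviour across the study grid

On the separated cell (coverage 50, β = 0.5, ε = 0.01, 1 Mbp, 1000
variants) the fitted density shows a deep interior minimum and the
adaptive threshold recovers essentially all variants with essentially
no false calls (sensitivity and PPV ≈ 1, see
`scripts/acceptance.py`).  On pure noise the density decays
monotonically, no qualifying minimum exists and the 95%-quantile
fallback engages.

The low-coverage/low-frequency corner (coverage 10, β = 0.05) is a
documented limitation.  With the score formulas above, every mismatch
site scores positive at low coverage (the conditional match
probabilities exceed ½ in every bin, so each mismatch contributes
positive log-odds while `log q(δ)` is negligible when nearly all
mismatch sites share one δ value).  The positive population is then
dominated by technical-error sites, whose 2-mismatch subpopulation
forms a weak but resolvable shoulder at near-uniform coverage: the
threshold lands there, recall is very low (most β = 0.05 sites show 0-1
alternative reads at 10×) and precision is poor under either rule.  At
this fixture scale the detectable variants are outnumbered by
positive-score noise sites roughly twentyfold, which bounds the
achievable PPV well below 1 regardless of the cutoff.

## Problem sizes

The default test and acceptance runs use a 1 Mbp toy genome (about
5 × 10⁷ aligned bases at 50×), which the pure-Python/NumPy pileup
processes in about half a minute per pass; unit tests use 20-60 kb
genomes.  These sizes are the package's desk-scale study conditions;
all parameters scale to larger inputs unchanged.
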
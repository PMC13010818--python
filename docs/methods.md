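# Methods

## Design and data model

The unit of analysis is a gene-level count matrix over a replicated
experimental-evolution design: two biogeographic histories (PT, NL), two
thermal selection regimes (Control at a constant temperature; Warming with
mean and amplitude increasing every generation), three replicate ancestral
populations (APs) per history, and two assay generations (G9, G23) — 24
samples in total. Each AP founds both a control lineage and a warming
lineage, so AP is a blocking factor shared across regimes, and samples from
the same AP are positively correlated. All expression contrasts are
warming-vs-control at the same generation, which cancels between-generation
batch and environmental effects.

## Normalization and filtering

Size factors follow the median-of-ratios construction: the pseudo-reference
for gene *g* is its geometric mean across the samples of the analysis
subset; a sample's factor is the median over reference genes of the
count/reference ratio. Reference genes must have strictly positive counts in
every sample of the subset. Two deliberate choices:

* **Anchoring.** Raw median-of-ratios factors are identified only up to a
  dataset-wide constant (only depth *ratios* matter). We anchor the factors
  at geometric mean 1, which makes normalization idempotent — renormalizing
  a normalized matrix returns unit factors — and leaves every downstream
  ratio and model term except the intercept unchanged. Factors from the
  unanchored convention differ by exactly that constant.
* **Per-subset protocols.** Filtering (non-zero counts in ≥ 3 samples,
  "data" meaning a non-zero count) and size factors are recomputed
  independently for every analysis subset (all samples, per generation, per
  history × generation, per history), because each analysis involves a
  different sample set. Filtering uses the raw matrix; normalization
  preserves zeros, so the order does not change membership.

## Per-gene models

Expression is modelled with a log link; the response is the normalized count
(fractional values admissible — see below). Fixed-effect designs:

| id | fixed terms                              | fitted on             |
|----|------------------------------------------|-----------------------|
| M1 | Generation × Selection × History         | all 24 samples        |
| M2 | Selection × History                      | each generation (12)  |
| M3 | Selection                                | each history × generation (6) |
| M4 | Generation × Selection                   | each history (12)     |

Every model carries a random AP intercept (nested in History where both
histories are present; AP labels are unique across histories, so plain AP
grouping encodes the nesting). All factors are two-level; each term
contributes one coefficient.

**Families.** Negative binomial with variance μ + φμ² (per-gene φ, no
shrinkage across genes) and Poisson as the φ → 0 limit. Likelihoods are
evaluated with gamma-function generalizations of the factorial terms
(Γ(y+1) for y! and Γ(y+r)/Γ(r) for the NB coefficient), so the fractional
responses produced by normalization enter the likelihood directly instead of
being rounded. This makes the "likelihood" a continuous extension rather
than a probability mass function; it coincides with the usual one at integer
y and is the same device glmmTMB applies to non-integer responses.

**Random-intercept integration.** The marginal likelihood integrates the AP
intercepts by a per-group Laplace approximation: for each AP level, a 1-D
damped Newton iteration finds the posterior mode of the intercept (the
penalized per-group log-likelihood is strictly concave in it), and the
marginal contribution is the mode value minus ½·log(1 + σ²W) with W the
observed information at the mode. The outer optimization runs L-BFGS-B over
(β, log φ, log σ) with bounds φ ∈ [10⁻⁸, 10³], σ ∈ [10⁻⁴, 10], a relative
function tolerance of 10⁻¹², and a cap of 500 iterations; a stalled line
search triggers one restart from the terminal point, which either confirms
stationarity or escapes the stall. Starting values come from a least-squares
fit on log(y + 0.5) and a method-of-moments dispersion. If the variance
estimate collapses to its lower bound or the mixed fit fails, the gene is
refitted without the random term and flagged (`fallback_used`); the
better-likelihood fit is kept. A numba-compiled evaluation of the same
objective (asserted equal to the numpy reference to ~10⁻¹¹ in the tests)
keeps per-gene fits near a millisecond.

**AIC and family selection.** AIC = 2k − 2·logL with k counting fixed
coefficients, the NB dispersion, and the random-intercept variance — also
for fallback fits, so AICs stay comparable across genes. The family used for
all genes is chosen by a per-gene vote: each gene votes for its lowest-AIC
candidate (ties toward fewer parameters), the majority wins. On
overdispersed data (φ = 0.5) NB wins ~93% of votes; on Poisson data the
extra dispersion parameter costs NB the vote (~98% Poisson).

**Term tests.** Per-term p-values are likelihood-ratio tests: the reduced
model removes the term's single column under sum-to-zero contrasts while
retaining all other terms, so a main effect is tested as the average effect
across the levels of interacting factors; the statistic is referred to
χ²(1). The maximized full-model likelihood is coding-invariant, so the
treatment-coded fit (whose coefficients are directly interpretable — the M3
Selection coefficient is ln of the warming/control mean ratio) is reused.

**Candidate calling.** Genes with p below α/H<sub>n</sub>, α = 0.01 and
H<sub>n</sub> = Σ<sub>i=1..n</sub> 1/i for the n genes actually tested in
the analysis. This is a single fixed cutoff (the harmonic-series correction
that makes Benjamini–Hochberg valid under arbitrary dependence), not a
ranked step-up procedure; at n ≈ 12,800 it is ≈ 0.001. Non-converged fits
are excluded from calling and logged.

### Known limitation: small-sample behaviour of the LRT

The χ²-referenced LRT with a per-gene ML dispersion is anti-conservative at
this design's sample sizes. Under a null M3 simulation (6 samples, φ = 0.1)
the empirical size at nominal 0.05 is ≈ 0.17–0.20, falling to ≈ 0.11 at 12
samples (M4) and ≈ 0.14 for M1's Selection test at 24 samples. This is a
property of the test construction, not of this implementation: glmmTMB
produces the same size on identical data, with per-gene log-likelihoods
matching ours to ~10⁻⁹ and coefficients to 10⁻³. Effect *estimates* are
essentially unbiased (mean Selection estimate within 0.3% of a planted ln 2
at baseline 200, φ = 0.05). The stringent harmonic-series cutoff offsets the
liberality in practice, but nominal error rates at loose thresholds should
not be taken at face value; a parametric bootstrap or Bartlett correction
would be the upgrade path.

## Trajectory classification

For one history, x is the ratio of mean normalized expression (warming over
control, averaging the three replicate populations per regime) at G9 and y
the same at G23; each generation's ratio uses that generation's
independently normalized subset. Ratios stay on the natural scale (not log)
because the plateau rule's 0.05 threshold is stated on the ratio scale. If
either mean is zero, a pseudocount of 0.5 is added to both means and the
gene is logged. A per-replicate-pair alternative (mean of W<sub>i</sub>/C<sub>i</sub>)
is not implemented; pooling replicates matches the ratio definition used
throughout.

With the neutral point (1, 1): Q1 (x>1, y>1) splits at the diagonal into
pink_up (y > x, amplifying upregulation) and blue_up (y < x, slowing); Q3
symmetric for downregulation (pink_down y < x, blue_down y > x); all of Q4
is green_up_down and all of Q2 green_down_up (sign reversals). "Magnitude of
change" is distance from 1 on the ratio scale; within Q1/Q3 this reduces to
comparing y against x. Points within a relative tolerance (default 10⁻⁹) of
ratio 1 on either axis are labelled boundary, and points on the diagonal are
labelled diagonal; both get dedicated labels rather than arbitrary
assignment, are excluded from percentage denominators, and are reported
separately. Reversal percentage = green/total; slowing-plus-reversal =
(blue + green)/total; both rounded to the nearest integer.

**Plateau rule.** A gene plateaus iff it is a candidate at both G9 and G23
(model 3 at each generation), its Generation × Selection interaction (model
4) is *not* significant at the same harmonic-series cutoff, and
|y − x| < 0.05.

**Four gene sets.** Summaries are produced for G9 candidates, G23
candidates, both-generation candidates, and interaction candidates —
candidacy at G9/G23 from model 3's Selection term per history per
generation, interaction candidacy from model 4's Generation × Selection
term.

One bookkeeping note: the published per-zone counts for the NL G9 candidate
set sum to 1,144 while the candidate total is reported as 1,145 elsewhere;
summaries here always report the zone-count sum. Similarly, the published
counts imply a 17% consistent fraction for PT G9 candidates (59/343), and it
is the counts that this package reproduces.

## Synthetic data

The generator draws, per gene: a baseline log-mean uniform on
[ln 20, ln 2000] (spanning moderately to highly expressed genes), an NB
dispersion uniform on [0.01, 0.3] (the range typical of replicate bulk
RNA-seq), a Generation main effect ~ N(0, 0.2²) applied to *all* samples of
G23 (emulating the large between-generation batch signal real assays show),
and AP intercepts ~ N(0, 0.1²) drawn once per gene × AP and shared by the
control population and its warming descendant at both generations — the
paired lineage structure the GLMM's random term targets. The warming effect
at each generation is the gene's archetype log2 fold-change (converted to
natural log), applied only to warming samples:

| archetype        | log2FC at G9 | at G23 |
|------------------|--------------|--------|
| null             | 0            | 0      |
| progressive_up   | +0.5         | +1.0   |
| slowing_up       | +1.0         | +0.5   |
| reversal_up_down | +1.0         | −1.0   |
| plateau          | +1.0         | +1.0   |

(down-variants mirrored). A |log2FC| of 1 is a clear but biologically
plausible selective response; the progressive/slowing pairs put a factor √2
between generations. Counts are NB draws (Poisson when φ = 0) with optional
per-sample depth multipliers (default 1; the normalization stage is
exercised separately). Randomness is split into per-gene substreams keyed by
(seed, gene index), so draws are independent of evaluation order and fully
reproducible; the default mix is 80% null with the planted archetypes
sharing the remainder.

**What the generator does not emulate:** mean–dispersion trends and
dispersion shrinkage targets, gene–gene correlation, compositional effects,
GC/length biases, or generation-specific library artefacts beyond the
shared Generation shift. Passing recovery tests therefore demonstrates that
the pipeline's inference and classification machinery is correct under its
own model assumptions, not that real thermal-selection data meet those
assumptions.

## Problem sizes and numerical conventions

Simulation-based checks run at 200 replicate genes for effect recovery,
1,000 genes for null calibration, 500 genes per family-vote condition, and
2,000 genes (24 samples, 10% planted reversals, 5% plateaus) for end-to-end
recovery — sizes at which the Monte-Carlo error of the reported rates is
well below the margins asserted, while a full run stays in the minutes
range on one core. Linear predictors are clipped at ±30 to keep exp() in
range; dispersion and variance parameters are optimized on the log scale;
LRT statistics are clipped at 0 (optimizer noise can make the reduced fit
marginally better); percentage summaries are recomputed from counts, never
stored. On degenerate input (a gene with identical values everywhere) the
Selection coefficient is ~0, the dispersion and random-intercept SD collapse
to their bounds, and the LRT p-value is ≈ 1 — the optimizer tolerance leaves
the statistic a hair above zero, so "≈ 1" rather than exactly 1.
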
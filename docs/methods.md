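# Methods

This note documents the statistical models implemented in `enuscreen`,
the generative model behind the synthetic screens, the numerical
choices, and the known limitations.

## Scoring and classification

The composite health score sums five ordinal parameters (0/1/2 each)
and a body-weight score. The printed weight anchors (0 if <29 g, 1 if
30–34 g, 2 if >35 g) leave the half-open gram intervals [29, 30) and
(34, 35] unassigned; the implementation rounds weight half-up to the
nearest gram and scores ≤29 → 0, 30–34 → 1, ≥35 → 2, which preserves
the integer anchors exactly and partitions (0, ∞) without gaps or
overlaps. Improvement thresholds are strict for the score (<8 at 8 wk)
and inclusive for longevity (≥98 d screen 1, ≥70 d screen 2). Screen 2's
"improved scores" requirement is operationalized as the same <8
threshold used for founders — the only quantitative improvement
criterion defined anywhere in the screen design. An animal censored
(sacrificed healthy) at or after the longevity threshold counts as
improved, matching colony practice of sacrificing healthy animals at
12–14 wk for sperm cryopreservation; screen-1 classification uses
longevity only, since no score criterion is defined for it. Screens
that recorded only four subjective parameters are scored through the
same five-parameter path with missing parameters entered as 0 and
flagged (`imputed_parameters`), preserving provenance in one code path.

## The Mendelian segregation test

For one N2 family with *n* assessed Mecp2/Y N3 offspring, the null
distribution of the improved count *K* is the hierarchical Bernoulli
mixture

P(K = k) = (1 − p_c)·1{k = 0} + p_c·C(n, k)·p_t^k·(1 − p_t)^(n − k),

with carrier probability p_c = 0.5 and per-offspring transmission
probability p_t = 0.5 (expected improved fraction p_c·p_t = 0.25).
Families are independent and the test conditions on the observed family
sizes. *Extremeness* is probability ordering: the p-value is the total
null probability of all per-family count configurations whose null
probability does not exceed the observed configuration's. This is the
standard construction for exact multinomial-style tests: two-sided,
parameter-free, and equal on the single-offspring case to the intuitive
answer (observing the 0.25-probability outcome gives p = 0.25).

Implementation notes:

- Exact enumeration builds the outer product of per-family pmf tables;
  the configuration count Π(nᵢ + 1) is capped (default 10⁷, ~80 MB of
  doubles) and larger structures fall back to Monte Carlo.
- Configurations tied with the observed probability up to a relative
  tolerance of 10⁻⁹ count as "as extreme", so float rounding cannot
  silently drop the observed configuration itself.
- The Monte-Carlo version simulates whole lines from the null and uses
  the add-one (permutation-style) correction
  p = (1 + #{prob ≤ prob_obs}) / (reps + 1), which keeps p > 0 and
  valid; it is seeded and reproducible.
- For calibration studies, `exact_pvalues_for_sizes` enumerates one
  family structure once and maps many observed count vectors through a
  sorted cumulative sum.

Being discrete, the test is conservative: under the null,
P(p ≤ α) ≤ α, verified by simulation at 10⁴ lines.

**Power caveat.** Probability ordering has essentially no power against
*deficient* improvement (e.g. two loci both required, improved fraction
1/16): the all-zero configuration is the null's own mode (each family
has P(k = 0) ≈ ½), so such lines receive large p-values. This mirrors
screen practice — lines with very few improved N3s cannot be resolved
by segregation counts alone. The test does detect *excess* improvement
(e.g. two loci, either sufficient: improved fraction 7/16), with power
≈ 0.33 at four families of eight and α = 0.05 versus size ≈ 0.05.

## Variant pipeline

Filtering removes a variant if its (chrom, pos, ref, alt) site occurs
in the parental-strain panel, in the known-variant catalogue, or in at
least `sharing_threshold` *other* founder lines, or if its tolerance
prediction is "tolerated". The cross-founder default is 2: a site seen
in exactly one other founder may be a genuine recurrent ENU hit (real
screens observe multi-allele genes), whereas broader sharing indicates
a strain polymorphism or systematic artifact. The stages are pure set
subtractions — order-independent and idempotent. Tolerance predictions
are consumed as an input column; re-implementing a trained tolerance
predictor is out of scope.

Consequence calls use a minimal transcript model (ordered 1-based CDS
exon intervals plus the spliced coding sequence, validated for frame,
start, and stop). SNVs in the CDS are called codon-by-codon through the
standard genetic code, strand-aware; intronic positions within ±2 bp of
an exon boundary are splice (canonical donor/acceptor dinucleotides —
the minimal defensible rule); length-changing indels are frameshift
unless the length change is a multiple of 3 (reported as missense at
the protein level); everything outside the span is noncoding. A
mismatch between the variant's reference allele and the model's coding
sequence raises a validation error rather than a silent call.

Spectrum summaries report integer-rounded percentages per consequence
class, counts over the 12 *as-sequenced* substitution classes (A→G and
T→C are distinct; no strand collapsing), and a per-gene allele tally
counting distinct (gene, line) lesions. Genome equivalents divide
gametes screened by 655, the gametes-per-genome-equivalent for the
standard 3 × 100 mg/kg ENU dose.

## Association models

- **Ordinal traits** (composite score and each parameter) use the
  cumulative-logit proportional-odds model
  P(Y ≤ j | x) = logistic(θ_j − xβ), fitted by maximum likelihood
  (statsmodels `OrderedModel`, BFGS, monotone-threshold
  parameterization). The logit link is the conventional default for
  ordinal screens and gives β a log-odds-ratio interpretation. Traits
  are fitted on their observed levels; unobserved categories are
  collapsed. Separation or non-convergence is reported through an
  explicit `converged` flag, never silently.
- **Body weight** uses OLS with classical t-tests; rank-deficient
  designs fail with the aliased column named.
- **Longevity** uses accelerated-failure-time likelihoods with right
  censoring across four families — exponential, Weibull, log-normal,
  log-logistic (lifelines AFT fitters; the exponential via its exact
  Poisson-regression equivalence, with the censored-data log-likelihood
  evaluated directly). The AFT (log-time linear predictor) form is used
  because it has an unambiguous likelihood across all four families.
  Model selection minimizes AIC = 2k − 2ℓ; ties break toward fewer
  parameters, then the fixed family order above.
- **Scans** fit one marginal model per locus per trait and one
  interaction model per locus pair (both main effects plus the product
  term; the reported effect/p belong to the product term). Loci with
  fewer than two carriers or two non-carriers are skipped with a
  recorded reason; locus pairs with no observed double carriers are
  omitted from the interaction table. Fixed effects only: family
  random effects showed negligible variance in practice, and the
  fixed-effects models are the primary specification. Raw p-values are
  primary; Benjamini–Hochberg q-values are available behind a flag.
- **Utilities**: Kaplan–Meier medians (first time S(t) ≤ 0.5, undefined
  if never reached), the Mantel-Cox log-rank test, 2^−ΔΔCt fold
  changes, and the pooled-variance two-sample t-test.

## The synthetic-data generator

The generator emulates the screen's study conditions so that every
analysis stage can be validated against known truth.

**Pedigree.** An N1 founder carries all declared suppressor loci; each
locus passes to each N2 with probability ½ and from carrier N2s to each
N3 with probability ½, independently across loci unless a pairwise
recombination fraction r declares linkage (a cis double-heterozygous
parent transmits both with probability (1 − r)/2, neither with
(1 − r)/2, each alone with r/2). Default scale: 10 N2 families of 10
assessed Mecp2/Y N3 each, plus 2 wild-type littermates per family.

**Ordinal phenotypes.** Each animal-week draws a shared Gaussian
frailty (sd 0.5) added to a latent severity location = disease baseline
(4.0) + Σ carrier latent effects (+ pairwise interaction terms); each
of the five parameters then adds independent standard-logistic noise
and is thresholded at parameter-specific cutpoints. A *strictly* shared
latent would make the five parameters deterministic functions of each
other; the frailty-plus-noise form keeps the cross-trait correlation a
composite score relies on while each parameter remains marginally
(approximately) proportional-odds — the mild logistic-normal
attenuation of recovered effects (<5% at frailty sd 0.5) is well inside
the 3-SE recovery bands used in testing. Wild-type littermates receive
a −8 latent offset, placing them at score ≈ 0, the wild-type anchor of
the scale.

**Defaults.** The baseline (4.0) and the default suppressor latent
effect (−2.5) were chosen so that unsuppressed Mecp2/Y animals
typically score ≥8 at 8 wk (not improved) while single-suppressor
carriers usually score <8 — the qualitative contrast the screen is
built on. Weight is Gaussian (Mecp2/Y mean 32 g, sd 3 g; wild-type
25 g) with a 1 g-per-latent-unit genotype shift.

**Survival.** Weibull AFT: baseline shape 4 and scale set so the median
is 77 d (the unsuppressed Mecp2/Y median); carrying loci multiplies the
scale — hence every quantile — by exp(Σ log-accelerations), with the
default single-locus acceleration log(112/77) moving the median to
112 d. Censoring is administrative only, at the sacrifice age (default
98 d); survival-focused analyses that need observable medians above
98 d use an aged-cohort configuration with later censoring. No random
loss to follow-up is modeled.

**Founder variants.** Poisson-many lesions per founder (mean 50), with
consequence probabilities 0.92/0.04/0.03/0.01 (missense / nonsense /
splice / frameshift-and-stop-loss) and a 12-class substitution spectrum
dominated by A→G (22%) and T→C (18%) transitions, T→A (16%) and A→T
(11%) transversions, C→G and G→C at 0.5% each, and the remaining mass
spread evenly over the other six classes. Genes are drawn proportional
to length from a small synthetic catalogue (the giant *Ttn* soaks up
recurrent alleles, as in every real ENU screen); coordinates are
invented and serve only as plausible positions.

**What the generator does not emulate:** litter and maternal effects,
family-level clustering beyond genotype, age-dependent score
trajectories (weeks are exchangeable given genotype), genotyping error,
incomplete penetrance/phenocopies beyond what the thresholded-latent
model induces, and non-administrative censoring. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to these real-data features.

## Problem sizes and numerical choices

Test simulations use sizes chosen to make each property sharp but
cheap: exact-vs-Monte-Carlo agreement on fully enumerable family
structures (3·√(p(1−p)/reps) tolerance plus a discreteness allowance);
null calibration at 10⁴ lines of four families of eight; parameter
recovery at n = 2000 (3-SE bands); AIC family selection at the per-line
scale n = 50 as a scaled-down plurality check; transmission fractions
at ≥10⁴ N3 (3-sigma binomial bounds). Seeds are fixed throughout;
`same seed ⇒ byte-identical output` is a tested contract of the
generator and the pipeline reports.

## Limitations

- The segregation test's blind spot for deficient improvement is
  intrinsic to probability-ordering extremeness (see above).
- The exponential AFT reports Wald p-values from the Poisson-GLM
  equivalence; the other families use the fitters' observed-information
  standard errors. Likelihood-ratio tests are not exposed.
- Consequence annotation handles SNVs and simple indels against
  single-transcript models only — no multi-transcript resolution, UTRs,
  or splice-region (beyond ±2 bp) calls.
- The interaction scan requires observed double carriers; in small
  families a pair can be untestable, and the scan omits rather than
  imputes such cells.
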
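# Methods

## Model overview

`apoe4risk` implements a forward, hierarchical Bayesian estimator of the
APOE ε4 genotype (states +/+, +/-, -/-, always in that order) from family
history of Alzheimer's disease, followed by a Gompertz cumulative-risk model
weighted by the genotype probabilities and scaled by population-normalized
hazard ratios.

### Onset likelihood

Age of AD onset given genotype g is modelled as Gaussian with means
(68, 76, 84) years and a common SD of 8.2 years. The posterior for an
individual with onset t is the normalized product of their prior and the
three Gaussian densities. Onsets are accepted in [45, 95] by default —
outside that window late-onset AD is either implausible or the model's
Gaussian tails are not trusted — and out-of-range values raise an error
rather than being clamped. The range is a parameter (`onset_range`) so that
simulation experiments can widen or disable it; the file-format schema
always enforces [45, 95].

An individual with **no AD history keeps their prior unchanged**. This is a
deliberate simplification: being AD-free at, say, age 90 is genuinely
informative (survival-style censoring would down-weight ε4 carriers), but
the estimator does not use current age at all. The `age` field is carried
in the data model purely for record keeping.

A configuration flag (`lifetime_risk_weighting`) additionally multiplies
each genotype's likelihood by its asymptotic lifetime risk (the Gompertz
A column), reflecting that an observed onset is also evidence of ever
converting. It is off by default: the plain Gaussian likelihood already
reproduces the package's worked example, and the weighting double-counts
conversion risk unless AD-free relatives are censored symmetrically.

### Pedigree propagation

The pedigree is fixed at three generations: subject, parents, four
grandparents (great-grandparents add little and are rarely known;
siblings and half-relatives are out of scope and rejected by the schema).
Estimation is **forward-only**: grandparents → parents → subject. Each
parent's prior is the Mendelian combination of the two grandparental
posteriors; because transmission is independent per parent, the combination
reduces to the product of ε4-transmission probabilities
t = P(+/+) + ½·P(+/-). This is an approximation, not an exact pedigree
likelihood: evidence never flows child → parent (no Elston–Stewart
peeling), so an affected subject does not update a parent's estimate. The
simulation module exists to quantify the cost of this approximation rather
than hide it.

**Missing relatives** are assigned the population prior and the combination
rule is applied uniformly — the same treatment as an AD-free relative, so
replacing an AD-free ancestor with a missing one never changes downstream
estimates. One consequence worth stating explicitly: the published genotype
frequencies (0.045, 0.09, 0.865) are *not* at Hardy–Weinberg equilibrium
(the implied allele frequency 0.09 would give genotype frequencies
0.0081, 0.1638, 0.8281), so the no-information prior for a subject with
unknown parents is the combined distribution (0.0081, 0.1638, 0.8281), not
the raw population prior — a 7.4-point difference on the heterozygote
state. We keep the combination rule uniform rather than special-casing
fully-unknown branches, because the alternative makes estimates
discontinuous between "two AD-free grandparents" and "two unknown
grandparents", which are epistemically identical inputs here.

### Gompertz risk curves

Cumulative risk per genotype is A·exp(−exp(−k·(age − x₀))) with the
published per-genotype fits (A the lifetime risk, k the rate per year, x₀
the location, roughly the mean onset age; risk equals A/e at x₀). The
parameters are treated as constants — the cumulative-incidence data behind
the fits is not available to refit. The rising sign convention is used
throughout: risk increases with age towards A.

A subject's genetic curve averages the **parameters** (ΣA·P, Σk·P, Σx₀·P),
not the curves. Parameter averaging is the primary definition; pointwise
curve mixing ΣP·curve_g is available behind the `mix_curves` flag for
sensitivity analysis. The two differ materially for diffuse genotype
distributions, and parameter averaging does not guarantee the averaged
curve lies between the pure-genotype curves — tests therefore assert
continuity in the genotype distribution rather than an envelope property.

### Hazard-ratio adjustment

Published hazard ratios for race, type-2 diabetes, traumatic brain injury,
education, physical exercise and diet come from studies with different
reference categories, so each factor is rescaled to make its
prevalence-weighted mean ratio exactly 1: HR_adj = HR / Σ(HR·prevalence).
The registry stores **only raw ratios and North-American prevalences**;
adjusted values are always recomputed at full precision. This surfaces
several inconsistencies in the published adjusted column rather than baking
them in: diabetes recomputes to 1.395 (published 1.41), education to
1.424/0.800 (published 1.522/0.855), severe TBI to 4.39 (published 4.5).
Two data-entry choices:

* The diet rows' prevalences are label-corrected by default (Mediterranean
  26.9%, other 73.1%): that reading reproduces the published adjusted
  values (1.12 for non-Mediterranean, 0.67 for Mediterranean) and the
  worked example's non-Mediterranean ratio. `strict_printed_hazards`
  restores the values exactly as published.
* TBI prevalences published as "<1%" are encoded as 0.005 each, with
  No/Mild at 0.99.

Selected adjusted ratios combine **additively**, m = Σ(HR_adj − 1) + 1.
Real risk factors confound rather than add; the additive rule can exceed
the multiplicative combination and can push risk past probability 1, in
which case the factored curve is clipped at 1 with a logged warning. A
multiplicative combiner is available behind a non-default flag. For the
worked example's six factors the full-precision multiplier is 1.1015;
combining the *display-rounded* per-factor ratios instead gives 1.23 —
the difference is entirely rounding in the published per-factor column
(0.973 → 1.0 for white race, 0.800 → 0.86 for post-secondary education),
worth knowing when comparing against published totals.

### Display rounding

Genotype distributions are displayed as whole percents using
largest-remainder rounding, so the three percentages always sum to 100
(e.g. 4.5/9.0/86.5 displays as 4/9/87). CSV output keeps full precision.

## Simulator

`simulate.SimConfig` defines a generative model: the four founders are
drawn from configurable genotype frequencies (default: the population
priors), parents and subject inherit ε4 alleles by Mendelian transmission,
each person develops AD with a per-genotype lifetime probability (default:
the Gompertz A column, 0.9377/0.4962/0.225), and affected individuals draw
an onset from their genotype's Gaussian, truncated by resampling to
[45, 95] so the estimator can consume it. Everything is deterministic given
the seed.

What the simulator does *not* emulate: mortality and ascertainment (an
85-year-old's grandparents' histories are better known than a 45-year-old's),
competing dementias and misdiagnosis, assortative mating, and any link
between hazard factors and onset (no published generative model exists for
the latter, so hazard code is tested analytically instead). Passing
calibration under this simulator therefore shows internal consistency of
the estimator with its own assumptions, not field validity.

### Calibration experiment

For each simulated subject the estimator is run on phenotypes only, the
predicted P(+/+), P(+/-), P(-/-) are binned into deciles (quantile bins;
duplicate edges collapse), and each occupied bin reports mean predicted
probability vs empirical true-genotype frequency. `matched_singleton_config`
builds the configuration under which the estimator is *exactly* the Bayes
posterior of the generating model, so its calibration gap is pure
Monte-Carlo noise: lifetime risk equalized across genotypes at 0.5 (AD
status then carries no genotype information, matching the estimator's
treatment of AD-free subjects), untruncated Gaussian onsets (the
estimator's exact likelihood), and subject-only observation of a fully
simulated three-generation pedigree (so the subject's true marginal equals
the estimator's no-information prior). At n = 10,000 subjects every
occupied decile's absolute gap is below 0.03 (the binomial noise floor for
~1,000-subject bins is ≈0.015 at worst). Under the default (mismatched)
configuration — genotype-dependent lifetime risk and truncated onsets —
the experiment reports the resulting gaps without a fixed threshold; the
AD-status selection effect is the dominant contribution.

### Recovery experiment

Argmax-genotype accuracy against simulation truth, stratified by the number
of AD-affected relatives, plus an overall row and an early-onset row
(subject onset before 65). Each stratum reports the majority-class baseline
(the best constant classifier for that stratum) and heterozygote recall.
With zero-information phenotypes the argmax is constant, so accuracy equals
the majority-class frequency exactly (≈0.83, the -/- share of the combined
marginal). Family history mainly adds value for heterozygote detection
among early-onset subjects, where recall rises from the baseline's zero to
well above it.

## Problem sizes and numerics

Default experiment sizes are 10,000 pedigrees for calibration (seconds on a
laptop) and a few thousand for recovery; the test suite uses 200–10,000.
All probability arithmetic is in linear space — the Gaussian densities and
three-state products involved are far from underflow; Gompertz evaluation
guards the one benign overflow (ages far below the location, where risk
underflows to 0). Distributions validate to a 1e-9 sum tolerance;
equality-style tests use 1e-12 against independent scalar oracles.

## Known limitations

* Forward-only propagation understates certainty relative to exact pedigree
  inference and ignores child → parent evidence.
* AD-free survival to an old age is not used as evidence (no censoring).
* Early-onset autosomal-dominant AD (APP/PSEN1/PSEN2) is out of scope; the
  model is meaningless for onsets before 45.
* Additive hazard combination is a heuristic; combined multipliers can
  exceed 1/A and trigger clipping.
* The constants (priors, onset means, Gompertz fits, hazard ratios and
  prevalences) are literature values for a North-American population and
  are not re-estimated from data.
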
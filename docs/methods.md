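# Methods

## The statistical model

The design treats each (agent arm, tumor type) cohort as a basket with its
own true 16-week clinical-benefit rate `p_j`, compared against a published
historical response rate `p0_j` for that tumor type under standard care.
All inference targets the exceedance probability `P(p_j > p0_j | data)`.

**Effect parameterization.** The cohort effect is
`δ_j = logit(p_j) − logit(p0_j)`. This choice makes "the response rate
exceeds the historical rate" exactly `δ_j > 0`, and — because each cohort
is measured relative to its own comparator — lets cohorts with different
historical rates share a cluster and a hierarchical prior meaningfully.

**Clustering prior.** Cohorts are partitioned by a Dirichlet-process
mixture on `x_j = logit(p0_j)`: cluster centers `θ_c ~ N(m0, v0)`,
observations `x_j | θ_c ~ N(θ_c, κ²)`, CRP partition prior with
concentration `α`. The partition posterior is proportional to
`α^K · Π_c (|c|−1)! · Π_c m(x_c)` with `m(·)` the Normal–Normal marginal
likelihood. Defaults: `α = 1`, `m0 = logit(0.15)`, `v0 = 4`, `κ = 0.25`.
The base measure is centered on a typical late-line oncology response rate
and is diffuse on the logit scale; `κ = 0.25` separates historical rates
that differ by more than roughly ten percentage points, which is the
granularity at which published response rates are meaningfully different.
Clustering is *prospective* by default — it uses only historical rates,
fixed before outcomes accrue. An outcome-adaptive variant (re-cluster on
posterior mean rates at each interim) is possible by refitting the
clusterer on posterior means; it is exposed only through composition and
should be treated as experimental, since re-clustering on outcomes changes
the design's operating characteristics.

**Within-cluster hierarchy.** `δ_j ~ N(μ_c, τ_c²)` with `μ_c ~ N(0, s0²)`
and `τ_c ~ Half-Normal(t0)`; no parameter is shared across clusters, so
borrowing never crosses cluster boundaries. Defaults `s0 = 2`, `t0 = 1`:
on the log-odds scale `s0 = 2` spans odds ratios from roughly 1/50 to 50
(weakly informative, admits both skepticism and strong signals), and
`t0 = 1` lets the between-cohort spread range from near-pooling to
near-independence, which is what "dynamic" borrowing requires. The amount
of shrinkage is then driven by the concordance of the data.

**Decision rules.** Futility: strictly fewer than 10% posterior
probability of exceeding the historical rate, assessed only at ≥ 10
evaluable patients. Success: at least 95% probability, assessed only at
15–30 evaluable patients, inclusive thresholds read literally. Success is
checked before futility (they cannot both fire at these thresholds).
Beyond 30 evaluable without an early stop the cohort continues to final
analysis; the 15–30 window bounds *early success*, it is not a cap.
Look schedule: event-driven by default — a look fires whenever an open
cohort's evaluable count reaches a new integer ≥ 10 — with an optional
fixed calendar (`look_weeks`) and an optional restricted set of look
sizes (`look_at_n`) for single-look designs. Whether the historical
program's looks were event- or calendar-driven is not documented; both are
provided and neither is asserted as fact.

## Samplers and numerical choices

- **CRP collapsed Gibbs.** One sweep resamples each cohort's assignment in
  fixed cohort order from the conjugate predictive full conditional.
  Partitions are canonicalized (labels in order of first appearance) so
  samples are comparable; canonical labeling is idempotent. The point
  estimate from samples is Dahl's least-squares partition against the
  pairwise co-clustering matrix, with lexicographic tie-breaking; from the
  exact enumeration table it is the posterior mode. Enumeration is limited
  to 10 cohorts (Bell(10) = 115 975).
- **Hierarchical sampler.** Adaptive random-walk Metropolis within Gibbs:
  per-cohort `δ_j` updates and per-cluster log-`τ_c` updates adapt their
  proposal scales in batches of 50 toward 0.44 acceptance during burn-in
  (adaptation frozen afterwards, preserving the correct stationary law);
  `μ_c` is a conjugate Gibbs draw. Because `μ_c` and its `δ`s become
  perfectly coupled as `τ_c → 0`, each cluster also gets a joint
  translation move that shifts `μ_c` and all its `δ_j` together; without
  it the near-pooling regime mixes pathologically slowly. `τ` may be fixed
  (`tau_fixed`) to switch borrowing off (large) or force pooling (small).
  Chains are seeded from spawned `SeedSequence` children, so runs are
  exactly reproducible and chains independent. Split-R̂ and bulk ESS come
  from arviz; `R̂ > 1.1` sets a non-silent `converged=False` flag.
- **Closed-form engine.** The `independent_conjugate` mode evaluates
  `P(p > p0) = 1 − I_{p0}(a+r, b+n−r)` via the regularized incomplete beta
  function. It is both a fast analysis engine for simulation and the
  validation target for the MCMC in its no-borrowing limit.
- **Test oracles.** The quadrature oracles used in the test suite
  integrate on a dense fixed grid (400 001 points over ±40 prior sd)
  rather than adaptive quadrature: the posteriors involved can be orders
  of magnitude narrower than the prior support, and adaptive rules
  demonstrably miss the peak.
- **Rounding.** Printed percentages round half-up to one decimal
  (`11/80 → 13.8`), matching the convention of the program's tables;
  banker's rounding would disagree on exact `.x5` cells.
- **Degenerate inputs.** Empty cohorts (`n = 0`) are retained and get their
  cluster's prior predictive (interims may query cohorts before accrual);
  a zero denominator rate is an error, not 0; missing 16-week outcomes
  parse as not-evaluable, never as failure.

## The simulator

Patient identification is a homogeneous Poisson process (the source
program documents no arrival model; the rate is a scenario knob). Each
identified patient either enrolls at an already-open site (probability
`site_reuse_prob`, default 0.5) or triggers a new opening whose start-up
delay is log-normal per site type. The defaults calibrate the log-normal
to each site type's observed median with log-sd
`σ = sqrt(2 ln(mean/median))` — the identity that makes a log-normal
reproduce both printed summaries simultaneously (all-sites: median 3.6,
mean 5.9 weeks → σ ≈ 0.994). Outcomes are Bernoulli in the cohort's true
rate, revealed 16 weeks after dosing; cohorts form at ≥ 4 enrolled and
close to accrual when stopped. Randomness flows from one seed through
named substreams (accrual, sites, outcomes), so common-random-number
couplings across scenarios are valid — raising one cohort's true rate
with matched seeds cannot reduce its success fraction via accrual noise.
A screening-funnel pre-filter (checklists → actionable → consented →
treated) is available in the generator but is not part of the default
simulation path.

## The synthetic-data generator

The generator emulates the source program: 8 agent arms with treated
sizes (146, 80, 110, 12, 10, 84, 47, 106); per-arm 16-week benefit counts
(22, 11, 25, 3, 0, 12, 9, 19) over evaluable denominators
(146, 80, 110, 12, 10, 82, 47, 106); site-type treated totals
(166, 196, 233) with protocol openings (118, 197, 81) across 192 distinct
sites; the published tumor-type counts (colorectal 55 … penile 2, the
remainder pooled as "other"); alteration counts PIK3CA 93, RAS 80
(sub-labels KRAS 67 / NRAS 14 / HRAS 3 with overlap, so patients may be
counted in more than one RAS category), CDKN2A 78, PTEN 60; and the
screening funnel 1674 → 1568 → 988 → 595.

**Exact mode guarantees marginals only.** The program never published
patient-level joint distributions, so the joint structure — which
alteration sits in which tumor type at which site — is a deterministic
seeded round-robin chosen for feasibility, not an estimate. Three
deliberate reconstructions: (i) the arm with 84 treated but 82 evaluable
gets exactly two non-evaluable patients, making both denominators (595
treated, 593 evaluable) correct at once; (ii) each arm's observed
tumor-type cohorts are seeded with 4 patients so the cohort-formation
rule reproduces them; (iii) per-site-type *distinct site* counts
(57, 96, 39) are not published individually — only their 192 total is —
and are apportioned proportionally to openings. Because 197 community
openings exceed 196 community-treated patients, openings cannot be
recovered from the treated roster; the generator therefore emits a
separate site-registry table, and `summarize_program` takes it as an
optional input for the openings count. The funnel's itemized drop reasons
(116, 57, 99) are reported out of 414 exactly as published even though
the consented-to-treated gap is 393; the discrepancy is a reporting quirk
of the source tables and is carried, not resolved.

Consequently, tests passing on these rosters demonstrate that the
pipeline reproduces the program's *marginal* structure and that the
statistical machinery is correct against independent oracles; they say
nothing about covariate correlations, per-cohort outcome clustering, or
any real patient's data.

## Problem sizes

The test suite and `scripts/acceptance.py` use: exact partition
enumeration on 3–4 cohorts vs 18 000 retained Gibbs sweeps
(total-variation < 0.05); hierarchical fits of 2 chains × 5 000 iterations
(1 500 burn-in) against grid oracles (agreement within 0.02 absolute);
10 000 simulator replicates for the null futility scenario
(true rate = p0 = 0.30, single look at n = 10, closed-form engine;
exact stop probability 0.7¹⁰ ≈ 0.0282); and 100 000 draws for start-up
calibration (within 2% of median 3.6 / mean 5.9 weeks). These sizes give
Monte-Carlo error comfortably inside each stated tolerance.

## Known limitations

- The source program's prior families and hyperparameters were never
  published; every default above is this package's own choice, labeled as
  such, and configurable.
- The realized historical clusters, per-cohort closures, and responder
  listings of the source program are not reproducible without its
  non-public patient data; nothing here claims to recover them.
- The sampler is a random-walk scheme tuned for the small cohort counts
  (≲ 30) typical of basket trials; for hundreds of cohorts a gradient
  sampler would be preferable.
- No EXNEX-style mixture weights or commensurate priors: the design is a
  single hierarchical family per cluster by construction.
- Operating characteristics are frequentist summaries of a Bayesian rule
  set; they depend on every scenario knob (accrual rate, prevalence,
  look schedule), and no universal type-I-error calibration is implied.
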
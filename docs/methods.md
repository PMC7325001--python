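# Methods

This note records the statistical model the package implements, the
conventions and defaults it adopts where the method leaves choices open,
what the synthetic-data generator does and does not emulate, and the known
limitations. It documents *how* quantities are computed; every number it
mentions is recomputed by the test suite or by `scripts/acceptance.py`.

## The estimator

The service multiplier method combines a service count and a survey
proportion. For one site:

- **M** — distinct clients with at least one eligible visit inside the
  reference window. The window is the half-open interval
  `[survey_date − window_months, survey_date)` (default 6 months): a visit
  on the survey date itself is outside the recall period. Eligibility is
  per visit: a visit counts if its recorded age is ≥ 18 (matching the
  survey's own eligibility cut), and a client counts if *any* of her
  in-window visits is eligible. Visits with an empty client identifier are
  dropped and counted rather than treated as fatal, since real logs violate
  the "identifier never missing" rule. Clients are site-scoped; linking the
  same person across sites is out of scope.
- **var(M) = M** — visits are modelled as arriving at a constant rate, so
  the unique-client count is treated as Poisson and `SE(M) = √M`.
- **P̂** — the RDS-II (Volz–Heckathorn) inverse-degree weighted proportion
  of respondents reporting service use in the window,
  `P̂ = (Σ_{y_i=1} 1/d_i) / (Σ 1/d_i)`. Seeds are included (standard
  RDS-II practice). Respondents with missing or zero degree are retained
  in the recruitment forest but excluded from weighted estimation with a
  logged count — the inverse-degree weight is undefined and imputation
  would silently bias P̂. Respondents missing the trait are excluded from
  that estimate only.
- **N̂ = M/P̂**, with first-order (delta-method) variance
  `var(N̂) = var(M)/P̂² + M²·var(P̂)/P̂⁴` and a symmetric normal CI
  truncated below at zero. The symmetric-normal construction matches the
  shape of published results tables for this method; log-scale or
  percentile intervals are plausible alternatives and would be asymmetric.
  N̂ below the RDS sample size is logically impossible and triggers a
  warning rather than an error.

### Variance of P̂: chain bootstrap

Field RDS data are one realization of a dependent chain-referral process,
so an iid bootstrap understates uncertainty. The package uses a tree
bootstrap: resample the seeds with replacement, then regrow each chain by
resampling every node's recruits with replacement (keeping each node's
observed brood size). `SE(P̂)` is the standard deviation of the estimate
over replicates (default 1000), with a percentile 95% CI. An explicit RNG
seed is required on the command line; results are bit-reproducible given
it.

Two numerical details. Regrowing can change the replicate's size (a
duplicated recruit carries its own subtree), so replicates are capped at
4× the observed sample to bound pathological growth. And the scheme is
deliberately conservative: at the seeds-only boundary it reduces exactly to
the iid bootstrap (SE → `√(p(1−p)/n)` for equal degrees), but for deeper
trees the within-chain regrowth adds variance on top of the seed-level
component — a factor of about 4/3 in variance at one wave of branching-two
recruitment, growing with depth. This conservatism is intended: it reflects
the dependence structure of chain data, and it shows up downstream as CI
coverage at or above nominal in the recovery experiments.

### Validity range of the delta method

The first-order delta formula is accurate while the proportion's
coefficient of variation is small. Against a simulation oracle (M* normal
with variance M, P* truncated normal on (0, 1], SD of M*/P* over 10⁶
draws) the relative error of the delta SE is under 1% at CV(P̂) = 0.05,
about 3% at 0.10, about 5% at 0.12, and degrades to 8–14% by CV 0.15–0.18
— the ratio's skewness is a second-order effect the linearization ignores.
The acceptance grid therefore probes CV ∈ {0.05, 0.10}; for survey
proportions with CV above ~0.12 the reported SE should be read as a lower
bound.

## Diagnostics

- **Convergence series**: cumulative RDS-II estimate in interview order
  (ties broken lexicographically by respondent id — interview order is how
  these plots are always drawn, but tie rules are never stated).  A prefix
  with no usable respondent yields NaN.  Besides the plot data, a numeric
  stability flag is reported: every cumulative estimate over the last 25%
  of the sample within 0.02 of the final value. The 0.02 band is a
  package convention — the field assessment of convergence is visual and
  defines no threshold — and is exposed as a parameter.
- **Bottleneck series**: the same computation restricted to each seed's
  recruitment tree; requires ≥ 2 seeds. Non-converging per-seed tracks
  indicate network segmentation or a chain stuck in a subgroup.
- **Recruitment homophily**: observed recruiter–recruit trait matches over
  matches expected under random recruitment. Expected matches use the
  recruit-side marginal prevalence q: a recruiter with the trait matches by
  chance with probability q, one without it with probability 1−q. This is
  the convention of standard RDS software's recruitment-homophily
  statistic; alternatives (network homophily, recruiter-side marginals)
  exist, so the components (observed, expected, pair count) are reported
  for comparison. The statistic is invariant to complementing the trait.

## Cross-source comparisons

Both comparisons pool sites, weighting each survey respondent by her
inverse degree normalized to **mean 1 within site** so no site dominates
through its degree scale.

- **Programme knowledge**: Pearson chi-square on the weighted contingency
  table of trait × ever-heard-of-programme. With uniform weights this is
  exactly the classical Pearson statistic. No design-effect correction is
  applied — the p-values are anti-conservative under recruitment
  clustering and outputs say so.
- **Source comparison**: survey respondents reporting attendance (weighted)
  are stacked against deduplicated programme clients (weight 1); a
  binomial GLM regresses the source indicator on the trait plus fixed site
  terms (frequency weights, IRLS). The trait p-value is a joint Wald test
  of the trait contrasts; trait×site interaction is tested by likelihood
  ratio between the models with and without interaction terms. Programme
  clients' traits come from the most recent in-window visit — demographics
  drift between visits, and the latest record is the one closest in time
  to the survey. Possible complete separation is flagged on the result
  rather than raised.

## The synthetic-data generator

`rdsmm.simulate` emulates the statistical structure the estimator assumes —
and its violations — not any particular place:

- **Network**: negative-binomial degrees (mean 10, dispersion 3; degrees
  clamped to ≥ 1) wired by a configuration model with self-loops and
  parallel edges removed. Heavy-tailed degrees are the realistic choice for
  personal networks; the dispersion default keeps a visible tail without
  fragmenting the graph.
- **Attendance trait**: Bernoulli(p_true), independent of degree.
- **Homophily dial**: with `trait_homophily = h`, a fraction `h/(1+h)` of
  cross-group edges are rewired pairwise into within-group edges,
  preserving every degree. h = 0 leaves mixing proportionate; the measured
  recruitment homophily rises monotonically in h.
- **Recruitment**: seeds drawn uniformly or attender-biased (each seed an
  attender with probability 5/6 by default, mirroring the seed composition
  typical of the field studies this design emulates); each respondent
  offers 2 coupons to uniformly chosen *unsampled* neighbours, each
  returned with probability 0.9; breadth-first by wave, stopping at the
  target sample (200) or the wave cap (5 after the seeds — the field
  design). Sampling is without replacement, deliberately violating the
  estimator's with-replacement assumption exactly as real surveys do.
  Reported degree is the true network degree (degree-faithful reporting).
- **Visit log**: each attender makes a zero-truncated Poisson(2) number of
  visits (a service user attends about twice per six-month window) at
  uniform dates, under a stable client id; `underage_frac` injects extra
  under-18 clients that the eligibility filter must remove.

All randomness flows from a single `rng_seed` (sub-streams for population,
recruitment and visit log), and every simulated site can write a sidecar
JSON echoing the configuration and realized truth.

### Experimental regimes

- **Ideal regime** (recovery experiments): homophily 0, uniform seeds, wave
  cap lifted (max_waves = 100), n_true = 500, p_true = 0.3, target 200.
  Over 200 replicates with 300 bootstrap replicates each, the median N̂
  falls within a few percent of truth and the delta-method CI covers truth
  at ≥ nominal rate; the homophily statistic averages ≈ 1.
- **Violation regime** (bias direction): attender-biased seeds *and*
  trait_homophily = 1.0, wave cap 5. The homophily is essential to the
  mechanism: on a trait-independent network, neighbours are a random draw
  with respect to attendance, so biased seeds shift the estimate only
  O(n_seeds/n). Bias propagates when attender seeds sit in attender-rich
  neighbourhoods — service users recruiting service users — which is
  precisely the dependence the assortative network encodes. Under this
  regime the mean P̂ exceeds p_true and the mean N̂ falls below n_true:
  the multiplier *underestimates* when the two sources are positively
  dependent through the recruitment chains.

Problem sizes in the test suite and acceptance script (200 replicates, 300
bootstrap replicates inside the recovery loop, 10⁶ oracle draws) were
chosen to pin Monte-Carlo error well below the effect sizes being checked.

### What the generator does not emulate

Degree misreporting beyond the faithful-report default, mobility in and out
of the population, recall error in the service-use question, duplicate
identifiers in the visit log, and within-person trait change. Passing the
recovery tests therefore shows the estimation chain is correct *given* the
assumed data-generating process; it does not certify field estimates where
those additional error sources operate.

## Known limitations

- The delta SE understates uncertainty when CV(P̂) ≳ 0.12 (above).
- Weighted chi-square and logistic p-values carry no design-effect
  correction; under recruitment clustering they are anti-conservative.
- The published nine-site table bundled in `rdsmm.sites` can only be
  reproduced to rounding: the printed proportions are themselves rounded,
  so re-derived estimates can differ by ±1–2 persons from printed values in
  a few sites, and printed CIs (computed from unrounded internals) differ
  slightly from ±1.96·SE on printed inputs. One printed SE (site 1's 7.4
  for M = 57) is inconsistent with the √M rule the method states; the
  package always computes √M.
- Pooling sites for the cross-source comparisons violates the
  single-connected-network assumption of RDS weighting; it is done (as in
  practice) to escape small per-site samples, and the outputs are
  descriptive.
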
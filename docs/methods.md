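# Methods

This note documents the models and procedures implemented in `coopnet`,
the numerical choices behind them, and what the synthetic-data
experiments do and do not establish.

## The model

`coopnet` models the evolution of a directed binary support network
x between two observation waves as a continuous-time stochastic
actor-oriented process. Each actor i receives change opportunities at a
common rate λ (per unit of the inter-wave interval). At an opportunity,
the actor chooses among n options: toggle the outgoing tie to any one of
the other n−1 actors, or keep the status quo. Option y is chosen with
multinomial-logit probability

    P(y | x, i) ∝ exp( Σ_k β_k Δ_k,ij(x, y) ),

where Δ_k,ij = s_k,i(y) − s_k,i(x) is the *change statistic* of effect k
(the status quo has gain 0). Effects are per-actor summaries of local
structure — out-degree, reciprocity (Σ_j x_ij x_ji), transitive triplets
(Σ_jh x_ij x_ih x_hj), three-cycles (Σ_jh x_ij x_jh x_hi), in-degree
popularity (Σ_j x_ij x_+j), out-degree activity (x_i+²), in-degree
activity (x_+i · x_i+) — or covariate terms: alter, ego, same-category,
absolute-difference and dyadic forms. Degree effects use the plain
(non-square-root) functional forms; the registry is a single dispatch
table, so square-root variants can be added as new kinds without touching
the simulator.

Gender enters through the woman ego effect (change statistic = ego's
woman flag) and through interaction effects whose change statistic is the
woman flag times the parent effect's change statistic. Because the woman
ego effect *is* the gender × out-degree interaction under this
convention, the fully interacted specification adds the woman ego effect
plus interactions with every other baseline effect (a separate
woman × out-degree term would be exactly collinear).

All change statistics are computed in closed form; the test suite checks
them against toggle-and-recount on all 64 three-actor digraphs (exactly,
for the counting effects) and on random ten-actor instances. The closed
forms are valid for both tie addition and deletion evaluated on the
current network, which is what makes an O(n) per-option kernel possible.

### Composition change

Actors may enter or leave between waves. Entry/exit times are fractions
of the inter-wave interval; an actor outside its presence window neither
receives opportunities nor is available as an alter. Joiners start with
no ties; leavers' ties are frozen at exit. These are conventional
treatments; nothing downstream depends on them when turnover is zero.

### A note on the stationary distribution

The multinomial-logit ministep chain is **not** reversible with respect
to exp(Σ β·s): the one-toggle neighbourhood of a state depends on the
state, so the familiar logistic form e^β/(1+e^β) is *not* the long-run
tie probability even in the pure out-degree model. (At β = −1 and n = 3
the exact stationary tie probability, obtained by enumerating the
64-state chain, is 0.2267 against the logistic 0.2689.) The simulator is
therefore validated against the exactly enumerated chain rather than a
logistic closed form.

## Estimation

Parameters (λ, β) are estimated by the method of moments. Targets: the
observed inter-wave Hamming distance (identifying λ) and, for each
effect, the statistic total Σ_i s_k,i at wave 2, with every simulated
chain started from the observed wave 1. The solver is three-phase
stochastic approximation:

1. **Derivative.** D = ∂E[S]/∂θ estimated as Cov(S, score) over a batch
   of simulations (likelihood-ratio/score method; the path score w.r.t.
   each β is accumulated ministep by ministep, and w.r.t. log λ it is
   m − λT). Diagonal entries are floored at 5% of the mean diagonal to
   guard against near-singular estimates.
2. **Robbins–Monro.** Sub-phases of single-simulation updates
   θ ← θ − a·D⁻¹(S_sim − S_obs) with the gain a halved per sub-phase
   (default initial 0.3, 4 sub-phases × 40 iterations), per-component
   step clipping (0.75), and iterate averaging within each sub-phase.
   Before inversion, D is blended half-and-half with its diagonal
   (`diag_mix = 0.5`): the score-method estimate of a large derivative
   matrix is noisy, and inverting it raw sends updates in wildly wrong
   directions for specifications with tens of effects, while the
   diagonally dominated blend remains a valid Robbins–Monro gain matrix
   and leaves the solution (moment matching) unchanged.
   β components are boxed to ±8 and log λ to ±3 around its moment-based
   start: a moment target on the boundary of its support (e.g. an
   observed triplet count of zero) has no finite solution, and the box
   converts such runaways into flagged boundary estimates. If the
   convergence check fails, estimation restarts from the initial point
   with the gain halved (up to `max_retries` times) and the best attempt
   by convergence ratio is reported.
3. **Covariance.** A large batch at the solution gives convergence
   t-ratios (simulated mean − target, over simulated SD), the statistic
   covariance Σ_S, a fresh derivative D, and the parameter covariance
   D⁻¹ Σ_S D⁻ᵀ (pseudo-inverse). Convergence requires the median |t|
   below 0.1 and the maximum below 0.25; strongly collinear moment pairs
   (e.g. kinship and log-distance, because kin co-reside) can leave one
   slowly-mixing direction above the median criterion at small n.

The rate is estimated on the log scale (positivity for free); its SE is
delta-method transformed back. Initial values: β = 0 except the
out-degree coefficient at the logit of the wave-2 density, and
λ = 1.5 × Hamming/n (some toggles cancel, hence the factor).

**Wald tests.** Nested specifications are compared with
χ² = β̂_Aᵀ (Σ̂_AA)⁻¹ β̂_A on the added subvector A, df = |A|, p from the
upper χ² tail. Calibration is verified by simulation: under a
gender-neutral data-generating process the gender-interaction test
rejects at its nominal level within binomial error.

## Hypothesis scoring

Each cooperative-mechanism hypothesis is scored as a linear combination
a'β̂ of Model-3 estimates, where the weights a are the change statistics
implied by adding one hypothetical tie x_ij to an artificial status-quo
network: 1 for out-degree, 2d+1 for out-degree activity at ego
out-degree d, the fixed ego in-degree (6) for in-degree activity, q+1
for in-degree popularity at alter in-degree q, the scenario's focal
values (reciprocity 1; kinship 1; friendship 1; transitive closure = the
median out-bound two-path count 12; cyclic closure = the median in-bound
two-path count 5; one SD of reputation difference; same-gender 1), and
for the gender terms the ego's woman flag times the parent weight.
Standard error: sqrt(a'Σ̂a); z = value/SE; two-tailed normal p with a
significance flag at 0.001. The default grid spans ego out-degree 0–32 ×
alter in-degree 0–64 (2145 cells per gender, 4290 per panel). Scenarios
H1–H6 fix Same Gender = 0 (a cross-gender "typical" dyad, identically
aged, different caste, ~e^5.7 ≈ 298.86 m apart); H7 sets Same Gender = 1
to isolate gender homophily. The woman-minus-man difference at any cell
reduces algebraically to the summed gender-term contributions — the
constitutive terms cancel — and the tests assert this to machine
precision. The combinations live on the log-odds scale; they are never
converted to tie probabilities.

## Goodness of fit and ego-networks

Fit is assessed by the joint Mahalanobis distance of an observed
auxiliary-statistic vector from the cloud simulated under the fitted
model: dimensions constant across the ensemble are dropped, the ensemble
covariance is Moore–Penrose pseudo-inverted (rank truncation at 1e−8),
MHD is the square root of the quadratic form (so an identity-covariance
cloud reduces it to a Euclidean distance), and GOFp is the share of
ensemble members at least as distant (weak inequality: the p-value is 1
when the observed vector sits at the mean, and never 0). Auxiliary
statistics: cumulative in-degree (support 0–64) and out-degree (0–32)
distributions, directed geodesic distances 1–13 with an "unreachable"
bucket, the Holland–Leinhardt 16-class triad census, and the
concatenated women-minus-men differences of eight ego-network statistics
(out-degree, reciprocal out-degree, supportive friends, supportive kin,
same-gender patrons, transitive triads, three-cycles, and the
reputation-gap sum Σ_j x_ij |z_i − z_j| on the z-score of the square
root of nomination counts). The ensemble mean and covariance are
estimated *including* the ensemble members but excluding the observed
vector, which biases GOFp slightly downward by order dim/m; the
calibration experiment therefore uses ensembles large relative to the
statistic dimension (m = 300) and confirms approximate uniformity.

The gender-split ego-network comparison reports, per statistic, the
observed women-minus-men difference in means next to the median,
quartiles and whiskers of that difference across simulated networks.

## Synthetic data

The field data the design emulates (a two-wave sociometric census of two
adjacent South Indian villages) are access-restricted, so all
experiments run on a generator that reproduces their *structure*:

- two villages of equal size; gendered actors; households of 1–5 adults
  placed uniformly in a 900 m square per village, villages 2 km apart;
- covariates drawn at the published summary moments — age 44.01 (SD
  14.70) years truncated to 18+, log household wealth 12.62 (0.94)
  shared within household, reputation nominations negative-binomial with
  mean 2.28 and SD 1.97, pairwise log-distance affinely calibrated to
  5.69 (1.36) log-metres (iterated because clipping at zero perturbs the
  moments); education 5.5 (4.5) years and 75% married are plausible
  values for the setting, not published moments;
- kinship = co-residence plus inter-household links (probability 0.03
  per household pair); patrilocality is emulated by flagging a fraction
  (0.35) of married women as village immigrants; friendship is sparse
  (2%), caste-assortative and partially reciprocated;
- wave 1 is produced by a long burn-in (40 opportunities per actor) of
  the ministep process at the true parameters starting from the empty
  network, so that estimation on (t1, t2) is internally consistent;
  wave 2 follows by one simulated period at rate 3. Default true
  parameters give a sparse network (density ≈ 0.04) with reciprocity,
  mild transitive closure, kin/friend bias, homophily, distance decay
  and a small gender asymmetry.

What passing tests on these data show: the estimator recovers the
parameters of its own data-generating process without bias detectable at
Monte Carlo precision; the Wald and GOF machinery is calibrated under
the null. What they do not show: robustness to measurement artefacts of
real sociometric data (differing question wording between waves,
name-generator truncation, reporting asymmetries), to genealogical kin
structure beyond a binary indicator, or to rate heterogeneity across
actors — none of which the generator emulates. Real tie counts and
between-wave similarity of the emulated study are deliberately not
matched.

## Problem sizes

The validation experiments run at deliberately small scale so the whole
suite completes on one CPU in minutes: parameter recovery uses 20
replicates of 50 actors at β = (out-degree −2.0, reciprocity 1.5,
transitive triplets 0.25); Wald calibration 200 replicates of 30 actors;
GOF calibration 100 replicates of 20 actors with 300-member ensembles;
the demonstration study in `analysis/` uses 200 actors and 500-member
ensembles (the full design contemplates 10 000). Ensemble and replicate
counts scale Monte Carlo precision only; no point definition depends on
them.

## Known limitations

- Method-of-moments only; no maximum-likelihood or Bayesian estimation,
  no score-type tests, no endowment (creation vs maintenance) split, no
  behaviour co-evolution, no multiplex networks.
- A single rate parameter per period; no rate covariates.
- Boundary moment targets (zero observed counts for an included effect)
  yield boxed boundary estimates rather than finite solutions — by
  construction, such effects should be dropped from the specification.
- The Wald covariance comes from simulation; with very small phase-3
  batches the test can be anticonservative. Defaults are sized so the
  null calibration experiment passes its binomial band.
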
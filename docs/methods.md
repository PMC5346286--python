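# Methods

This note records the statistical model, the synthetic-data design, the
numerical conventions, and the open design choices behind `odacta`.

## Effect metrics

All effect estimates derive from a 2×2 table (predictor-positive /
negative × effect / no effect, cells `a, b, c, d`):
sensitivity `100·a/(a+c)`, specificity `100·d/(b+d)`,
PPV `100·a/(a+b)`, NPV `100·d/(c+d)`, attributable risk
`a/(a+b) − c/(c+d)`, NNH `1/attributable risk`, risk ratio
`[a/(a+b)]/[c/(c+d)]`, and ESS `sensitivity + specificity − 100`.
ESS is the two-class form of a chance- and maximum-corrected accuracy:
0 at chance (predictor-positive rate equal in cases and controls), 100
at perfect discrimination, −100 at perfect anti-discrimination.  A
metric with an empty denominator is `None` ("undefined"); a ratio with
zero divisor but well-defined limit is `inf`; NaN never escapes.
Internal arithmetic is full precision; presentation rounds half-up
(`round_half_up`), matching how such tables are conventionally printed.
Published screens sometimes imply the `d` cell rather than print it;
`complete_counts` reconstructs it from either the unexposed-group total
(naive analysis rows, `d = N_unexposed − c`) or the cohort total
(within-cohort predictor rows, `d = N − a − b − c`).

## Univariable ODA

For an ordered attribute the model space is every cutpoint at a midpoint
between adjacent distinct observed values, in both directions (effect
positive above or at-most the cutpoint); the fitted model maximizes ESS
over that space — which is why fitted cutpoints take half-integer values
such as 90.5 or 208.5 when observations are integers.  Ties in ESS are
broken deterministically: larger sensitivity on the smaller outcome
class, then the smaller cutpoint, then direction `>` over `<=`.  Missing
attribute values are excluded pairwise and logged (`n_used`,
`n_missing`), so screened predictors may have different effective n.

**Inference.**  Significance is the permutation probability of the
*maximized* statistic: outcome labels are permuted, the cutpoint is
re-optimized (both directions) for each relabeling, and p is the
fraction of relabelings whose maximal ESS reaches the observed one.
This max-ESS null is the conservative choice consistent with exact ODA;
a fixed-cutpoint null is available (`null="fixed_cut"`) but is not the
default, and no claim is made about which variant produced any
particular published p-value.  Enumeration is exact over all
`C(n, n_cases)` labelings when that count is ≤ 200,000 (a practical
vectorized-enumeration bound; configurable); beyond it, Monte-Carlo
permutation with the small-sample correction `p = (1 + hits)/(n_mc + 1)`
guarantees validity.  For a fixed binary attribute the null is
hypergeometric in the `a` cell and the two-direction p-value is computed
exactly in closed form; it agrees with full enumeration (tested).

**Multiplicity.**  Where k hypotheses are screened, the Šidák criterion
`1 − (1 − α)^(1/k)` controls the experimentwise rate; the generalized
mode keeps per-comparison `p ≤ α` instead.  The two-direction cutpoint
search counts as *one* comparison per attribute — direction is part of
the optimization, not a separate test.  k is the number of screened
predictors; the alternative (counting per outcome family) is not used.

## CTA

Trees chain ODA splits: at each node the candidate set is every
predictor's ODA-optimal cutpoint *re-optimized for that node's
subjects*, restricted to cuts leaving at least `min_leaf_frac` (default
10%) of the root cohort on each side, and gated by the Šidák criterion
over the node's predictor pool (Monte-Carlo permutation p for ordered
predictors, exact hypergeometric for binary ones).  Endpoint classes are
assigned after the structure is fixed: model ESS decomposes over
endpoints (`sens = Σ_pos a_i/P`, `spec = Σ_neg b_i/N`), so the globally
optimal assignment is per-endpoint — positive iff `a_i/P > b_i/N`, ties
negative.  Routing is half-open: a value exactly at a cutpoint follows
the `<=` branch.  Predictors may repeat along a path (two duration
cutpoints on one branch are legal); the endpoint-size minimum applies to
terminals (children of any split already satisfy it by construction).

Two search modes.  *Greedy* recursion takes the best significant
node-local split (by node ESS).  *Exhaustive* enumerates every tree
assemblable from the candidate splits up to `max_depth` and returns the
one maximizing model ESS — guaranteed optimal **within that enumerated
family**, with ties resolved by fewer endpoints, then shallower depth,
then lexicographic structure.  No optimality claim is made outside the
family (the candidate set is one ODA-optimal split per predictor per
node); exceeding the complexity budget raises an explicit capacity
error rather than silently degrading.  Default `max_depth` is 4, the
scale of the models this method produces in practice.

Holdout validation scores the frozen tree on a temporally later cohort
(`temporal_holdout`: subjects with no detected dysfunction in the main
interval, evaluated over the following 6 months) without refitting.

## Cohort construction

Exposure duration is the length of the union of half-open supply
intervals `[start, start + days_supply)`, intersected with
`[first_start, truncation_point)`; exact duplicate prescriptions count
once and gaps count zero.  The algorithm is interval-merge over sorted
starts and is tested against a day-by-day scan oracle on random
instances.  "Stopping" is the end of the last supply interval — supply,
not issuance, defines exposure.  Drugs approved after January 1992
(dutasteride 2001, sildenafil 1998) begin exposure assessment at their
approval date.  Truncation for cases is at event onset; for non-cases
duration runs to the last supply end (the record's "last appearance" is
taken as the last encounter for reference-date purposes; this is
configurable in spirit but fixed here).

Case definitions are trigger-tool style.  New ED = earliest ED
diagnosis strictly after first 5α-RI exposure, in 1998 or later (when
the first PDE5 inhibitor became available), within ±90 days of a PDE5I
prescription (the "contemporaneous antidote"; the window is a package
choice — no canonical value exists — and is configurable), with no
ED/low-libido/PDE5I history before first exposure.  New low libido
drops the antidote and calendar requirements.  PED requires *positive
documentation of persistence*: the latest ED-supporting diagnosis must
fall ≥90 days after stopping, and any resolution record must also be
≥90 days after stopping; mere absence of a resolution note with no late
documentation does not qualify.  Persistence days run from stopping to
resolution (if recorded) else to the last ED documentation.  These
rules replace manual chart review with a deterministic procedure over
structured records; resolution is encoded as a dedicated code
(`607.84R`) in the toy dictionary rather than narrative text.

The analysis table evaluates time-varying predictors (age, exposure
days, encounter counts) at event onset for cases and at the last
encounter for non-cases; binary comorbidity/drug predictors use
presence anywhere in the record, except prostate surgery, which for
cases ignores procedures after onset.  Because cases and non-cases are
referenced at different times, `age_years` carries a genuine
differential-follow-up signal (non-cases have aged further by their
last encounter); the table therefore also carries
`age_at_first_exposure`, which is evaluation-time-free.  Analyses that
want age as a pure subject attribute should prefer it; the planted-model
recovery experiment does.

The young-men subcohort keeps subjects aged 16–42 at first finasteride
prescription (the source description is ambiguous between "16–42" and
"<42"; the inclusive bound is used and the limit is a parameter),
exposed only to finasteride ≤1.25 mg/day, with no dutasteride, no
prostate disease/surgery/cancer, and clean pre-exposure history.

## Synthetic cohorts and the planted model

The generator emulates the structure of a large single-center EMR
cohort of men aged 16–89:

- **Attribute prevalences** per exposure stratum default to the
  emulated cohort's baseline table (e.g. prescription NSAID 26.8%
  unexposed / 55.8% exposed; prostate disease 3.7% / 36.3%).
  Comorbidities are drawn independently — the source reports no joint
  structure, so none is imposed (configurable prevalences allow a user
  to stress correlated designs by stratified generation).
- **Ages** are log-normal fitted to each stratum's median/IQR
  (unexposed 38.9 [28.7–53.6], exposed 51.0 [30.8–66.3] years),
  truncated to 16–89 by inverse-CDF sampling since the described
  population is itself age-restricted.
- **Exposure durations** target a log-normal with median 168 days and
  log-SD 1.1, chosen so that roughly 45–48% of exposed men exceed the
  ~180-day univariable cutpoint, the proportion the emulated screen
  implies.  Prescription episodes realize that target as 30- or 90-day
  supplies on a 15-day refill grid with exponential gaps (mean 22.5 d),
  a 15% chance of an overlapping early refill and a 5% chance of an
  exact duplicate script — exercising the union/deduplication logic.
  The grid mimics real refill cadence and makes observed durations
  cluster on multiples of 15 days, so "one inter-observation gap" is a
  meaningful recovery tolerance.
- **The planted tree** is a decision list over resolvable attributes,
  default: prostate disease (exit), exposure days > 208.5 (continue),
  NSAID (continue), with ED leaf risks 7.8% / 2.0% / 3.0% / 6.7% —
  scaled to the emulated cohort's new-ED rates (≈4.5–5% overall; the
  high-risk leaf's published 2.1% PED rate divided by P(PED|ED)=0.315).
  PED is drawn given ED at 0.315 with log-normal persistence (median
  1,348 days, log-SD 0.965 fitted to the published IQR); low libido is
  an independent 1.2% draw.
- **Event chronology**: planted ED onset falls 1–45 days *after* the
  end of the last supply, the PDE5I prescription within ±30 days of
  onset, transient ED resolves within 90 days of stopping, persistent
  ED gets a final documentation code at stop + persistence with no
  resolution.  Placing onset after stopping keeps the case-truncated
  exposure duration equal to the planted one, so threshold recovery is
  well-posed; it also matches the persistence framing of the adverse
  event.  Dates are clipped to the study window (1992-01-01 to
  2015-09-30); exposure starts are drawn from 1998 onward so the
  PDE5I-era requirement never censors planted events.
- **Background noise**: 2.1% of unexposed men carry an ED code + PDE5I
  script and 0.8% a low-libido code (the naive-analysis base rates);
  10.5% of exposed men carry a pre-exposure dysfunction marker, so the
  clean-history filter removes a realistic fraction.
- **Streams**: outcome planting uses a random stream separate from
  cohort generation, so one cohort can host different planted models;
  (spec, seed) fully determines every byte of the output bundle.

**What passing tests show — and don't.**  The generator reproduces
marginal prevalences, a threshold-structured risk surface, and
refill-style prescription records; it does not model comorbidity
correlations, informative encounter timing, miscoding, care-seeking
behavior, or narrative text.  Recovery of the planted model therefore
validates the *algorithms* (duration union, case definitions, ODA/CTA
search and inference), not the clinical findings of any real-data
analysis; real multivariable node statistics are not reproducible from
synthetic data and are not claimed.

## Verification design and problem sizes

- Cutpoint search vs a naive brute-force midpoint scan: 500 random
  instances, n ≤ 200, mixed tied/continuous attributes.
- Exhaustive CTA vs an independent tree enumerator (binary predictors,
  own hypergeometric gate, endpoint classes by 2^k enumeration): 50
  instances, n ≤ 200, 3 predictors, depth ≤ 2.
- Permutation calibration: 1,000 null replicates at n = 60 (15 cases /
  45 controls), Gaussian attribute, Monte-Carlo p with n_mc = 199;
  empirical type-I error at α = 0.05 must lie within the binomial 99%
  band.  The unbalanced design and continuous attribute keep the
  discrete max-ESS null rich enough to be near-exact.
- Planted-model recovery: 50 cohorts of 20,000 (all-exposed), greedy
  CTA at depth 3 with the pool {prostate disease, exposure days, NSAID,
  age at first exposure, hypertension}; success = exact planted
  variable set and a duration cutpoint within one observed
  inter-observation gap of 208.5; ≥80% of replicates must succeed.
- Exposure-duration union vs a day-by-day oracle: 1,000 random
  prescription sets with duplicates and truncation.

These sizes keep the full suite within a routine CI run while leaving
each check statistically meaningful.

## Known limitations

- The exhaustive tree search is optimal only within its candidate
  family (one ODA-optimal split per predictor per node), not over all
  conceivable cutpoint combinations.
- Monte-Carlo split gating makes tree *structure* reproducible only
  with the recorded seed; all seeds are captured in the run manifest.
- The minimum-endpoint constraint is enforced at split time against the
  root cohort size; fitting on a filtered subcohort rescales it.
- Lab-value predictors are carried as optional ordered columns with
  pairwise-deleted missingness but the default generator does not
  emit them.
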
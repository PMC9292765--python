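# Methods

## The problem

Observational comparisons across *many* treatment groups — the motivating
case is estimating neighborhood effects on a rare health outcome across
tens of city areas — cannot rely on the usual propensity-score machinery:
with K in the tens, generalized propensity scores become tiny, overlap is
hard to certify, and pairwise matching does not scale. This package
implements an alternative: summarize each unit's categorical confounders
into a single scalar derived from the partial order of confounder
profiles, then rebuild the population so that every value of that scalar
is represented *equally often in every treatment group*. On the resulting
balanced artificial population, simple group-mean contrasts estimate
per-group treatment effects.

## Profiles, posets and the average rank

Each unit is reduced to its **profile**: the vector of its confounder
levels. Ordered variables contribute one integer coordinate (the level
index); nominal variables are dummy-expanded into one binary coordinate
per level, which keeps the order well defined without imposing an order on
the categories. Distinct profiles form a poset under the **product
order**: `x` is below `y` iff every coordinate of `x` is ≤ the matching
coordinate of `y` (and the profiles differ). Profiles with conflicting
coordinates are incomparable.

The **average rank** (AR) of a profile is its mean 1-based position over
all linear extensions of the poset. It is a scalar summary of where a
profile sits in the confounder ordering, playing the role a propensity
score plays in two-group matching — no substantive interpretation of the
value is needed, only that units with close ARs have nearby profiles.
Ranks live on distinct profiles (tied units form one node); units inherit
their profile's AR. Normalization to [0, 1] is `(AR − 1)/(P − 1)` with P
the number of distinct profiles (defined as 0 when P = 1).

Three estimators are exposed:

* **exact** — full enumeration of linear extensions, guarded by a cap on
  the extension count (exceeding it raises an explicit error rather than
  truncating). Used for small posets and as the oracle in tests.
* **lpom0** (default) — the local-partial-order closed form
  `AR(x) = (s(x)+1)(P+1)/(P+1−u(x))`, with `s(x)` the number of profiles
  strictly below `x` and `u(x)` the number incomparable to it. Exact on
  chains, cheap at the hundreds-of-profiles scale real data produce, and
  its approximation error is bounded against the enumeration oracle in the
  test suite. The estimator interface is pluggable, so a more refined
  approximation can be slotted in without touching the rest of the
  pipeline.
* **sampled** — Monte-Carlo over linear extensions. When the extension
  count is tractable (≤ 50 000) the sampler enumerates once and draws
  extensions uniformly by index — exactly uniform and fully vectorised.
  For larger posets with P ≤ 20 it falls back to the sequential counting
  sampler (also exactly uniform, via memoized extension counts over
  up-sets); beyond that, to random topological sorts with uniformly chosen
  minimal elements, which is only approximately uniform and documented as
  such.

Two profiles are treated as the same AR row downstream iff their ARs agree
after rounding to 9 decimals — a deterministic grouping rule robust to
floating-point noise.

### A structural caveat on nominal dummy expansion

If every combination of levels is observed, the dummy-expanded poset of a
nominal variable decomposes into disjoint, *identical* components (one per
nominal level combination). Identical components have identical average
ranks by symmetry, so the number of distinct AR values collapses — e.g. a
216-profile poset with three nominal variables yields only 12 distinct
ARs — and the matching becomes too coarse to balance well. Applied work in
this tradition therefore codes every confounder as an ordered factor,
assigning a working order even to variables like region of birth; the
ordering is arbitrary but harmless, because the AR is only a matching
score. The synthetic scenarios here follow that practice (all five default
confounders ordered); the nominal pathway remains implemented and tested
for data where no working order is acceptable.

## Matching

Units are cross-tabulated into an R × K frequency table: rows are the R
distinct unit-level AR values, columns the K treatments, cells the counts
`f_{r,k}`. For each row a **reference frequency** `f_r` is the row median
of the K counts, floored at 1 so that profiles present in the data are not
dropped merely for having a zero-median row (with an even K, the midpoint
of the two central order statistics is rounded up, keeping `f_r` integral
and favouring retention). `min` and `max` variants are exposed as a
sensitivity axis; `min` is deliberately not floored — a zero minimum means
the row lies outside the common support and contributes nothing.

The matching tolerance (**caliper**) is a quarter of the sample standard
deviation of the unit-level ARs, computed once on the full pre-matching
population — the usual propensity-caliper heuristic transplanted to the
AR scale. The multiplier is configurable.

Filling is two-pass. The *feasibility pass* discards a row when some
treatment has no unit with AR within the caliper of the row's value;
discarding removes the row's quota from **all** treatments, which is what
guarantees the equal-representation invariant exactly and enforces
overlap. The *fill pass* then, for every retained row and treatment with
count `c` and target `f_r`: copies the units once when `c = f_r`; draws
`f_r` with replacement from the row's own units when `c > 0` (also when
`c > f_r`, following the method's literal description; a
without-replacement downsample is available as a switch); and draws `f_r`
with replacement from the treatment's in-caliper donors when `c = 0` —
uniformly over the window by default, with a nearest-value option. A unit
may serve as donor for a row even if its own row was discarded (donor pool
= all in-caliper units of that treatment). The result is the balanced
artificial population: every retained AR value appears exactly `K·f_r`
times, `f_r` per treatment.

Diagnostics reported with every run: % of source units included, mean and
max repetition count over included units, per-group size (identical across
groups by construction) and total size.

## Balance measurement

Balance is quantified per (treatment, confounder-level dummy) by the
absolute standardized bias, in percent:

    ASB = 100 · |X̄_t − X̄| / sqrt((S_t² + S²)/2)

with sample variances (denominator n − 1); `X̄, S` are taken over the whole
analysis population — raw units before matching, matched records
(repetitions counted each time) after, since the matched dataset *is* the
analysis population. Degenerate dummies (zero variance in both group and
population) give ASB 0 when the means agree and an infinite-ASB sentinel
with a warning otherwise. Summaries use the eight-statistic layout (min,
Q1, median, Q3, max, mean, counts over 5% and over 10%); quartiles use
linear interpolation between order statistics (numpy's default, "type 7"),
and the over-5 count includes values over 10.

## Effect estimation

On the matched population, the effect of treatment `t` versus the rest is

    ATENC_t = mean(Y | t) − (1/(K−1)) Σ_{c≠t} mean(Y | c),

computed by plain group means over matched records — exact AR-level
balance makes covariate-adjusted weighting redundant by construction. The
vector of ATENCs sums to zero, and differences satisfy
`ATENC_a − ATENC_b = K/(K−1)·(ȳ_a − ȳ_b)`, so estimates for different
groups are directly comparable. Grouped contrasts between disjoint
treatment subsets (unweighted over treatments) generalize this; the
singleton-versus-complement case reduces to the ATENC.

Because matching repeats units, records are not independent. Standard
errors come from a **cluster bootstrap**: within every treatment, the
distinct source units are resampled with replacement, each carrying its
full set of matched copies (its repetition count acts as a weight). This
is a design choice — the estimator the original analyses used is not
public — and a model-based clustered variance could be substituted.
Default 1000 draws; p-values are two-sided normal (bootstrap-percentile
intervals would be a reasonable alternative; normal was chosen for
stability at rare outcomes). Multiplicity across the K per-group tests is
handled by Benjamini–Hochberg step-up flags at FDR 1%, 5% and 10%.

## Synthetic populations

The generator emulates the registry setting such studies draw on, since
the original data are restricted:

* **Confounders** — five categorical variables with 3–4 levels each (324
  theoretical profiles): age class, education, household composition,
  occupation, region of birth, with mildly non-uniform marginals. The
  joint distribution is the product of marginals log-linearly tilted by
  `exp(θ Σ_{i<j} z_i z_j)` on standardized level indices; the default
  θ = 0.25 gives the mild positive association demographic variables
  typically show (θ = 0 gives independence). Confounders are fixed across
  replications of a study, so the poset and ARs are computed once, exactly
  as on observed data.
* **Treatment** — multinomial logit over K groups (default 23, the last
  group as reference). Base coefficients are user-specified or drawn once
  per study from centered Gaussians (scale 0.3 for slopes, 0.3 for
  intercepts); each replication perturbs them with U(−0.01, 0.01)
  (additive scenario) or U(−0.1, 0.1) (scenario with all pairwise
  interactions between the variables' dummies) and rounds to 3 decimals.
  The slope scale 0.3 was chosen so the additive default produces a mean
  pre-matching ASB around 8% — the realistic "clearly unbalanced"
  starting point for a registry population — comfortably above the 5%
  threshold used in the replication studies.
* **Outcome** — Bernoulli with
  `P(Y=1|x,t) = clip(0.009 + x'γ + δ_t, 0, 1)`: a rare base rate matching
  the ~0.9% prevalence scale of the motivating outcome, a small confounder
  shift (γ drawn once, scale 0.002 per dummy — small enough that clipping
  essentially never occurs), and injected per-group risk differences δ.
  Because the effects are additive and clipping is negligible, the true
  ATENC is the ATENC algebra applied to δ, giving an analytic truth for
  recovery tests.

What the generator does **not** emulate: the real joint confounder
distribution of any particular city, unmeasured confounding,
interference between units, non-additive outcome effects, and ordinal
treatment structure. Passing tests therefore demonstrate the method's
internal correctness and its balancing behaviour under controlled,
additive, correctly-specified conditions — not robustness to violations
of those assumptions.

## Study sizes and numerical choices

The standard desk-scale studies are: balance replication at N = 20 000,
K = 23, 100 replications; effect recovery at N = 50 000, K = 10 with a
+0.004 injected risk difference (200 replications) and null-coverage
checks with 200–300 bootstrap draws. These sizes keep a full validation
run in the minutes range on one CPU while preserving the qualitative
behaviour of the full-scale setting (hundreds of thousands of units, 1000
replications): balance improvement appears at the same thresholds, at
somewhat attenuated magnitude because residual imbalance shrinks with N.

Other fixed choices: AR row identity at 9 decimals; exact-enumeration cap
100 000 extensions (an explicit infeasibility error beyond); per-replication
seeds derived from a master seed via numpy `SeedSequence.spawn`, making
every study reproducible from one integer.

## Known limitations

* The product order treats every declared level order as substantive;
  a mis-specified order changes the poset and hence the matching.
* LPOM0 ties profiles with equal (s, u) even when their exact ARs differ;
  with highly symmetric posets this coarsens the matching (see the nominal
  caveat above). The `sampled` estimator breaks such ties only in Monte-
  Carlo noise, the `exact` estimator not at all — the ties are genuine.
* With replacement sampling inside cells (the literal reading of the fill
  rule) adds Monte-Carlo noise to the matched population even where a
  without-replacement copy would suffice.
* Cluster-bootstrap p-values assume approximate normality of the ATENC;
  with very rare outcomes and small matched groups the normal
  approximation degrades.
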
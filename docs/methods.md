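# Methods

This note documents the statistical procedures, the synthetic data-generating
model, the defaults and why they were chosen, and the known limitations.

## Cause categories

Deaths are classified into four categories from the 3-character ICD-10 root
of the certificate's underlying-cause code: heart disease (I00–I09, I11,
I13, I20–I51), cancer (C00–C97), renal disease (N00–N07, N17–N19, N25–N27),
and "other" as the complement. Fourth-character detail never changes the
category, so subcodes are ignored. Any syntactically valid root outside the
three defined sets maps to "other" rather than erroring, because screening
data may contain arbitrary codes. The three definitions ship as defaults but
are ordinary configuration: a benchmarking program that defines categories
differently can supply its own range strings (en-dash or ASCII hyphen). No
ICD-10 validity dictionary is consulted and no underlying-cause selection
(ACME) logic is applied: the certificate's coded underlying cause is taken
as given. Deaths coded outside the three categories contribute to all-cause
totals but not to the three category rates.

## Death rates and screening

The inpatient death rate for category *c* at hospital *h* is
100·deaths(h,c)/hospitalizations(h,c); the all-cause rate divides total
deaths by total hospitalizations. Rates are raw: no case-mix adjustment and
no small-sample shrinkage (cohorts are expected to be pre-filtered to
hospitals with a meaningful death volume, e.g. ≥20 deaths/year).

Screening proceeds per disease category:

1. **Generalized ESD** (Rosner). At step i the value maximizing
   |x − mean|/s of the remaining data is removed and R_i recorded; the
   critical value is λ_i = (n−i)·t / √((ν+t²)(n−i+1)) with
   t = t_ν^{-1}(1 − α/(2(n−i+1))) and ν = n−i−1 (two-sided; the one-sided
   variant drops the factor 2 and uses signed deviations). The declared
   outlier count is the largest i with R_i > λ_i. Defaults: α = 0.1
   (two-sided) and k_max = max(1, ⌊0.2·n⌋), the conventional cap on the
   tested outlier fraction; both are configurable. If the remaining values
   become constant (s = 0) the procedure stops and declares no further
   outliers — constant data are legitimately outlier-free. The per-category
   outlier sets are unioned; the union leaves the cohort ("normalized"
   set). Running ESD per category rather than on a pooled statistic is an
   interpretation choice: it matches the "outlying in any disease category"
   selection rule and lets a hospital be extreme in one cause only.
2. **Normality re-check.** Shapiro–Wilk (scipy's implementation, which
   agrees with R's `shapiro.test` to ≥6 decimals on fixed data) on each
   normalized category rate set, α = 0.05. Failure is a recorded warning,
   never an abort: the tolerance-zone construction is a screening heuristic,
   not an inference requiring exact normality, and the pipeline proceeds
   exactly once per run. The check is skipped for a constant rate set, where
   W is undefined.
3. **Tolerance zones.** For each category the zone is benchmark ± 2·SD,
   where the SD is computed per category over the normalized hospital rates
   (different categories genuinely have different spreads, so a single
   pooled SD cannot produce per-category zone widths) and the benchmark is
   an externally supplied national rate — never estimated from the cohort.
   Packaged defaults (% of hospitalizations): heart 3.5, cancer 4.4, renal
   3.1, all-cause 2.0.
4. **Flagging.** A normalized hospital is flagged when its rate is at or
   above the upper zone bound in at least one *disease* category and
   strictly above the benchmark (the second condition only matters for a
   zero-width zone, where equality with the benchmark must not flag).
   Only the high side flags; the lower bound is computed and reported.
   The all-cause zone is reported for context but never flags — the model
   of interest is relabeling, which preserves all-cause rates.
5. **Study set.** Among the flagged, the top k (default 3) by all-cause
   death volume are selected (ties broken toward the smaller hospital id for
   determinism), and the study set is their union with the ESD outliers.

Zone-membership reports count, per region and category, that category's ESD
outliers, the remaining hospitals outside the zone (high side), and those
within; the three classes partition each region's hospital total. Counting
outliers as a class of their own (rather than folding them into "outside")
keeps the partition exact.

## Chart-review sampling

Sample sizes come from exact one-sample binomial power: the smallest n such
that the one-sided level-α test of H₀: p = p₀ (rejecting for large error
counts) has power ≥ the target against p = p₁. Defaults p₀ = 0.05,
p₁ = 0.20, α = 0.05, power = 0.80 give n = 27 charts per hospital, a
realistic clinical review load. The exact construction was chosen because
review error counts are small; the published study this design emulates
reported per-hospital samples of 18–33 without stating its formula, so the
default is documented as a choice, not a match. Samples are uniform draws
without replacement per study hospital from its certificates in the three
disease categories (optional per-category stratification is deliberately
omitted by default since an allocation rule is extra structure the design
does not need). Unavailable or incomplete charts are dropped
(complete-case); reviewed percentages are reported rounded to whole
percents. Per-hospital sampling seeds are derived from the master seed via
`numpy.random.SeedSequence` and recorded in the run manifest.

## Concordance statistics

Each reviewed death yields the matched pair (certificate category, chart
category); chart labels of "insufficient" are excluded and counted. The
per-hospital summary reports the percentage of discordant (inaccurate)
certificates, and per cause the percentage *of the inaccurate certificates*
whose certificate category was that cause — so a hospital's cause columns
sum to at most 100, with the remainder certified as "other". The mean row
is the unweighted mean of per-hospital percentages. Reported percentages are
rounded **half-up** to one decimal (71.85 → 71.9); banker's rounding would
differ on exact halves, and internal values are never rounded.

For cause X, b counts pairs with X on the certificate but not the chart
(overreporting) and c the reverse (underreporting). McNemar's exact test —
the default, because discordant counts are often below asymptotic comfort —
uses p = min(1, 2·P(Bin(b+c, ½) ≤ min(b,c))); the asymptotic form is
(b−c)²/(b+c) on one χ² df. The two agree only slowly: the continuity gap is
roughly 1.6/√(b+c) at worst, still ≈0.02 at b+c ≈ 2000, which is why the
exact form is the default. The matched conditional odds ratio is b/c, from
the conditional likelihood of the paired design; its exact-conditional CI
maps the Clopper–Pearson interval for b out of b+c through p/(1−p) (open
upper bound when c = 0), and a log-normal Wald interval
exp(ln(b/c) ± z√(1/b + 1/c)) is available. When a discordant count is zero
the reported OR uses the +½ continuity correction. Matched ORs were chosen
because the data are paired; an unmatched 2×2 construction would discard
the pairing. Direction is "overreport" when b > c, "underreport" when
b < c, "none" on ties.

## Synthetic cohort model

For each hospital and category, hospitalizations are negative binomial
(mean m_c scaled by a per-hospital size multiplier; shape k, variance
m + m²/k; Poisson as the k → ∞ special case via `hosp_dispersion=None`) and
deaths are Binomial(hospitalizations, p_c) with category-specific true death
probabilities. Each death's certified category is drawn from the transfer
matrix row of its true cause; its certificate ICD-10 root is sampled
uniformly from the certified category's code set (for "other", from ten
representative non-heart/cancer/renal roots); its chart category equals the
true cause; availability is independent Bernoulli. Everything derives from
one seed, and identical seeds give byte-identical studies.

Because D/H is conditionally unbiased for p, certified rates are unbiased
for the closed form
rate(h, c) = 100·Σ_t m_t·p_t·T_h[t, c] / m_c,
which serves as the Monte-Carlo oracle. Transfer moves labels, not deaths,
so all-cause rates are exactly invariant to T — bit-identical at a fixed
seed — mirroring the audit logic that all-cause rates near benchmark plus
cause-specific excess indicates misreporting rather than excess mortality.

The packaged scenario (`make_paper_like_scenario`) has 32 hospitals in two
metro regions (17 + 15). True death probabilities equal the packaged
benchmarks (heart 0.035, cancer 0.044, renal 0.031; other 0.0085 so the
all-cause rate is 2.0%); four-year category volumes average 3000 / 1500 /
1000 / 8000 with NB shape k = 50 (≈15% CV, the stability expected of
four-year aggregates — looser dispersion would make small-hospital rates
noisier than real aggregate data). Eight hospitals misreport in two tiers
mirroring the outliers-plus-top-contributors structure of the screening
flow: five small hospitals (0.3× volume) with severe transfer (90%
cancer→heart, 90% other→renal) and three large ones (2× volume) with
moderate transfer (70% / 45%). Chart availability is 0.88. Under these
conditions the screen recovers all implanted hospitals in ≈98% of
replicates and the pooled direction report detects heart overreporting and
cancer underreporting at exact p < 0.05 essentially always. An optional
informative-missingness flag (availability correlated with misreporting) is
deliberately *not* provided as a default mechanism; availability is
independent, so passing tests say nothing about selection bias from
missing charts.

What the generator does **not** emulate: patient covariates and case mix,
coding errors distinct from cause transfer, time trends, reviewer
disagreement (the chart label is a single gold standard), and death-count
inflation (all-cause totals are preserved by construction). Passing
recovery tests therefore demonstrate the pipeline's behavior under pure
relabeling with known truth — not robustness to confounded case mix or
informative chart loss.

## Numerical and degenerate-input choices

- ESD with constant remaining data stops early (no outliers); ESD requires
  n ≥ k_max + 2; argmax ties resolve to the first position, so results are
  deterministic given input order.
- Zero-width tolerance zones flag nothing (the strict-above-benchmark
  condition).
- Exact McNemar at b + c = 0 returns p = 1; the asymptotic form refuses it.
- Odds ratios refuse b = c = 0; c = 0 requires the continuity correction for
  a point estimate, while the exact-conditional upper bound is infinite.
- Percentages use decimal half-up rounding at report boundaries only.
- Validation failures raise `ValidationError` (CLI exit 2); statistical
  precondition failures raise `StatisticalError` (CLI exit 3).

## Problem sizes

The test suite and the acceptance script run the packaged 32-hospital
scenario with 100–200 replicates (a few thousand death records per
replicate), 100 seeded datasets for the ESD/Grubbs equivalence, and the
full b + c ≤ 25 grid for the exact McNemar enumeration; these sizes give
Monte-Carlo error well below the decision margins while keeping a full run
in tens of seconds on one CPU.

## Limitations

- Benchmarks are taken as exact constants; benchmark sampling error is not
  propagated into the zones.
- The per-category-ESD-with-union and per-cause paired-indicator McNemar
  constructions are documented interpretations of a screening design whose
  original operational details (pooled vs per-category ESD, exact k_max,
  sample-size formula) are not fully specified anywhere; alternatives are
  configurable where they matter.
- Raw rates mean small hospitals have noisy rates; the ESD step partially
  absorbs this, but a shrinkage estimator is explicitly out of scope.
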
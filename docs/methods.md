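# Methods

## Germination schedules and indices

The unit of observation is one Petri dish scored daily: `daily_counts[i]`
is the number of seeds whose radicle first reached 1 mm on day `i + 1`
(day 1 = first 24-h check after sowing). Counts are strictly daily
increments; cumulative input series are differenced only when the reader
is explicitly told to allow it (`allow_cumulative`), because a
non-decreasing daily series is otherwise indistinguishable from
cumulative data.

All ten indices follow the classical definitions (see README for the
formulas). Points where the definitions need a decision:

- **Undefined indices.** With zero germinations MGT, MGR, FDG, LDG, T₅₀,
  s²ₜ, CVₜ and CVG have no value; they are carried as explicit missing
  values (`None` / NaN, printed as "NA"), excluded from replicate means,
  and never silently zeroed — a silent zero would bias small-trial
  treatment summaries downward. FGP, GRI and GI are genuinely 0 in that
  case. The dispersion pair additionally needs ≥ 2 germinations (its
  denominator is Σnᵢ − 1).
- **T₅₀ degenerate cases.** The interpolation formula assumes adjacent
  cumulative counts bracketing the half-count target (N′+1)/2 (N′ = seeds
  germinated). When a cumulative count hits the target exactly, its day
  is returned; when all germination falls on one day, or the first event
  day already reaches the target, that day is returned — both are the
  continuity limit of the interpolation. With this rule FDG ≤ T₅₀ ≤ LDG
  always holds.
- **GRI convention.** G_d is read as the *daily* germination percentage
  increment (100 n_d/N), the Esechie convention, which keeps GRI additive
  over events; the cumulative-percentage reading is available via
  `cumulative=True`. The two differ substantially, so the choice is
  exposed rather than buried.
- **GI weights.** The day weights generalize to (k − d + 1) so any trial
  duration is supported; k = 60 reproduces the conventional 60…1 weights.
- **Exact identities.** MGR·MGT = 1 and CVG = 100·MGR hold to floating
  precision by construction and are asserted as properties. Doubling
  every count leaves FGP/MGT/MGR/CVG exactly unchanged; T₅₀ and CVₜ carry
  small-sample corrections ((N′+1)/2 target, n−1 denominator) and are
  only asymptotically scale-invariant.
- **Replicate summaries** report mean ± sd across dishes; the
  `table2_style` formatter rounds to the customary printed precision
  (1 d.p., 3 d.p. for MGR). Published per-treatment MGR/CVG are treated
  as means of per-dish values; note the alternative reading (transforms
  of the mean MGT) differs by Jensen's inequality — for the published
  1-d.p. MGT values both readings agree at printed precision, which is
  what the acceptance checks exercise.

## Group comparison

Dispatch follows the classical small-trial scheme: 2 related samples →
Wilcoxon signed ranks; 2 unrelated → Mann–Whitney U; > 2 related →
Friedman; > 2 unrelated → Kruskal–Wallis H. All tests are two-sided;
ties get mid-ranks and tie-corrected statistics throughout.

**Exact small-sample p-values.** Whenever the number of distinct
arrangements is at most `MAX_EXACT_ARRANGEMENTS` (default 200,000,
configurable per call), p-values come from full enumeration: group
reassignments for Mann–Whitney (scipy's exact recurrence on tie-free
data, direct mid-rank enumeration otherwise), the 2ⁿ sign vectors for
Wilcoxon (zero differences dropped first), rank-multiset assignments for
Kruskal–Wallis, and within-block permutations for Friedman. Beyond the
threshold the usual normal / χ² approximations apply. Two-sided exact
p-values use the symmetric-deviation rule P(|T − μ| ≥ |t − μ|), which on
these symmetric null distributions equals the doubled-tail convention.

**Bonferroni contrasts.** Every unordered pair is tested with the
design-appropriate two-sample test and judged at α_B = α/k, where k is
the number of contrasts actually performed in that family (per index,
per table) — not a global count. Pairs with all values identical are
degenerate: p = 1, flagged.

**Compact letter display.** Insert-and-absorb: start from one column
containing all groups; for each significant pair, split every column
containing both; absorb duplicate/subset columns; order columns by their
earliest group in input order and assign letters a, b, c…  The algorithm
guarantees two groups share a letter *iff* their pair is non-significant,
verified exhaustively for all significance matrices on up to 5 groups.

**Kendall trend.** τ-b with tie correction; exact p for n ≤ 10 tie-free
pairs, normal approximation beyond.

**Calibration.** Under the global null the family-wise false-positive
rate of the Bonferroni-adapted contrasts is checked by simulation with 4
groups of 8 observations (2,000 replicates, ≤ 0.06). Eight observations
per group make the check non-trivial: at the study's own 4 dishes per
treatment the smallest attainable exact two-sided Mann–Whitney p (2/70)
already exceeds α_B = 0.05/6, so no contrast can ever fire and the rate
is trivially zero — which is also why four-dish trials yield shared
letters unless separations are extreme.

## Climate window trends

Within each window the annual value is regressed on the year (OLS); the
reported change is fitted(end) − fitted(start) = slope × span, and the
window mean (which for OLS equals the mean of the in-window
observations) is reported alongside so a "window average" reading is
also checkable. Windows need ≥ 3 usable years; a window with < 80%
year coverage is flagged rather than rejected. Per-window deltas from
independent fits are *not* additive across windows — asserted in the
suite as a documented non-property. Batch summaries report failed
windows as error rows instead of aborting.

## Land-cover and ESA accounting

Composition shares use the sum of **non-missing** areas of that year as
denominator; "n.a." entries are tracked and flagged, never counted as
zero. Rounding to 1 d.p. happens only at presentation. The level-1
rollup groups level-III codes by leading digit; `rounded_shares=True`
sums the 1-d.p. class shares first, reproducing the convention of
printed composition tables whose group totals are sums of printed
percentages (the packaged 2018 column gives 58.15% unrounded vs 58.1%
by the printed convention). Crosswalks (e.g. CNR-TCI → CLC) are
user-supplied many-to-one maps; area conservation is checked to 0.01 ha.
For the packaged 1958 column the printed percentages imply a slightly
larger territory (~42,480 ha) than the recorded areas sum to
(42,263 ha) — presumably unrecorded urban/water area — so both readings
are reported and the 1958 shares are not treated as exactly
reproducible. The ESA summary reports per-class share deltas between
consecutive years and an "affected land" aggregate over a configurable
class subset, defaulting to all fragile + critical classes; per-year
shares must sum to 100 ± 0.5 (renormalization optional).

## Synthetic data

Generators are pure functions of (config, seed) via
`numpy.random.default_rng`; identical inputs give byte-identical
outputs.

- **Germination.** Each seed germinates independently with probability
  `p_germ`; germinating seeds draw a day from a normal law truncated to
  [1, k] (lognormal available by flag — both reproduce onset ≈ day
  25–32 and spans ≈ 37–42 d at suitable parameters), rounded half-up to
  whole days. Defaults mirror the study design: 4 treatments × 4 dishes
  × 20 achenes, 60 days, p_germ ∈ {0.17, 0.14, 0.32, 0.23}, mean days
  {30.3, 36, 32.5, 34.4}, day sd from the published CVₜ (≈ 3.6–5.7 d).
  Non-germinating seeds split empty/dead/viable at 0.80/0.15/0.05, the
  published cut-test proportions. What this emulates — and what it does
  not: real dormancy may correlate germination day and fate across seeds
  in a dish and across dishes; the simulator's independence assumptions
  mean passing recovery tests demonstrate estimator correctness, not
  field realism.
- **Climate.** Piecewise-linear means per variable plus Gaussian noise
  (defaults: temperature sd 0.3 °C, rainfall sd 100 mm, segments shaped
  like the study area's 90-year record with window deltas −0.2/+1.1/−1.0
  °C and 1050→850/950→800/880→1050 mm). At these settings the two large
  temperature deltas are sign-recovered on ≥ 95% of seeds, while the
  −0.2 °C delta (fitted-delta se ≈ 0.19 °C) is only ~85% detectable —
  the full sign pattern lands near 5 in 6, a power fact stated rather
  than hidden.
- **Land cover / ESA.** Shares evolve by explicit pp-transfer lists per
  period, clipped at 0 and renormalized to 100, scaled to a constant
  territory (default 42,400 ha); ESA shares evolve identically over the
  eight sensitivity classes.
- **Power at the study's n.** Parameter recovery is asserted at 500
  dishes (FGP within 2 pp, MGT within 0.5 d); at the study's 4 dishes
  the sd of the treatment-mean FGP is several points, asserted as a
  documented wide-interval fact.

## Problem sizes in the suite

Exhaustive oracles run at the largest sizes where full enumeration is
exact and fast: all 3,003 daily-count vectors with ≤ 6 germinations in an
8-day trial for the indices; Mann–Whitney up to 8+8 (12,870
assignments) and Wilcoxon to n = 8; Kruskal–Wallis and Friedman at
multinomially feasible sizes (hundreds of thousands of arrangements
explode combinatorially beyond ~4 per group, where the configurable
exact/asymptotic threshold takes over); all 1,098 significance matrices
on ≤ 5 groups for the letter display; 2,000 replicates for the
family-wise error rate and 100–500 seeds/dishes for Monte-Carlo
recovery checks.

## Known limitations

- The published field results themselves (treatment FGPs, station
  trends, MEDALUS sensitivity shares) rest on unpublished raw data;
  only internal consistency of the printed tables and the behavior of
  the methods on synthetic data are verifiable.
- No GIS geoprocessing: class areas are taken as given tabular inputs.
- The Friedman/Kruskal exact paths enumerate naively (clarity over
  speed); they are meant for the tiny samples where exactness matters.
- Letter displays are minimized heuristically (insert-and-absorb); the
  absolute minimum number of letters is not guaranteed, only correctness
  and determinism.
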
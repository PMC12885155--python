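# Methods

## Model and estimands

A scale of k items with integer response codes is analyzed under the
cumulative (Guttman) model: items map increasing regions of one latent
construct, and endorsement frequency proxies inverse intensity — the
less frequently endorsed an item, the harder it is. For a dichotomous
pair with endorsement proportions p_a ≥ p_b (a the easier item), a
Guttman error is the pattern (X_a = 0, X_b = 1). The pairwise error
ratio is

    e_ab = F_ab / E_ab,

with F_ab the weighted count of error patterns and
E_ab = n_eff (1 − p_a) p_b the count expected under statistical
independence at the observed margins, n_eff the total analyzed weight.
Its complement h_ab = 1 − e_ab is the pairwise Loevinger coefficient.
Item and total coefficients pool numerators and denominators:

    h_i = 1 − Σ_j F_ij / Σ_j E_ij,     H = 1 − ΣΣ F / ΣΣ E,

sums over defined pairs only. e_ab may exceed 100% (negative h); it is
reported numerically as-is and the color field clamps at the deepest
red.

### Polytomous items

Item j with m_j + 1 categories contributes m_j item steps, the
indicators X_j ≥ s. For an item pair, every step pair is classified
easy/hard by step popularity (ties keep the item that comes first in
the display ordering, which cannot change the result because at equal
popularity both orientations give identical F and E). F and E sum over
the m_a × m_b step pairs, unweighted. With this convention

    1 − F/E = cov(X_a, X_b) / Σ_steps p_hard (1 − p_easy),

the classical cov/cov_max construction, and the m = 1 case reproduces
the dichotomous rule bit for bit. The tests verify both identities
against an independent covariance oracle computed from joint tables.

### Degenerate items

A pair whose expected error mass is zero (an item or item step endorsed
by all or by none) has an undefined error ratio. Such pairs are flagged,
drawn blank, and excluded from the pooled h_i / H sums with a warning —
never silently treated as zero error.

## Survey weights

Guttman-error counting needs only point estimates, so weights can enter
in two equivalent ways. The default engine weights frequencies
directly. The alternative engine replicates each record an integer
number of times, which requires integer weights; raw weights are first
transformed by

    sw1_i = round(sw_orig_i · s / min(sw_orig)),

with half-away-from-zero rounding (0.5 → 1) and a user scaling factor
s ≥ 1. The minimum-weight record maps to round(s), so no record is lost;
larger s retains more of the continuous weight resolution at the cost
of a larger expanded dataset (default cap 5 × 10^6 rows, configurable).
Rounding-half-away was chosen because the transform's purpose is to
keep every record alive: the narrative failure mode it fixes is raw
weights below 0.5 rounding to zero. For weights spanning 0.311–2.052,
s = 100 yields the integer span 100–660; for a minimum weight of 2.699
at s = 1 the minimum internal weight is 1. (For a maximum weight of
5828.684 over minimum 2.699 at s = 1 the formula gives
round(2159.57) = 2160; a previously published account of the same
transform reports 2159, consistent with truncation rather than
rounding. We follow the formula as stated.) The diagnostics report
(`--sclmsg`) prints both ranges, the number of distinct integer
weights, the expanded size, and how many observations naive rounding
of the raw weights would have dropped or left unexpanded.

The two engines are proven equivalent to 1e-12 on random weighted
fixtures in the test suite; direct weighting is the default because it
is O(n) in the original sample.

## Classification and color

Mokken's cutoffs for Loevinger coefficients — poor < 0.3, weak
[0.3, 0.4), moderate [0.4, 0.5), strong ≥ 0.5 — are applied as printed;
the published wording leaves 0.5 itself unassigned ("0.4 to < 0.5",
then "> 0.5"), and we assign it to strong. Inverted to the error scale,
the acceptability bands are ≤ 50% (no problems), (50, 60]% (admissible
with reservation), (60, 70]% (borderline) and > 70% (problematic),
half-open exactly as listed. The two classifications are
rank-consistent through h = 1 − e/100, which a test checks on a dense
grid.

The color gradient is a 7-stop piecewise-linear palette anchored at
0, 25, 50, 60, 70, 85 and 100% (green → greenish-yellow → yellow →
orange → deep red), clamping above 100%. The exact published palette
RGBs are not recoverable from text, so these stops are a documented
approximation; `BandScheme` accepts any replacement stop list.

## Rendering

The map is a symmetric k × k grid, both triangles carrying the same
value, the diagonal always blank. Cell colors come from a per-pixel
value field rasterized at 25 pixels per cell (odd, so one pixel center
coincides with each cell center):

- smooth = 0: blockwise-constant field, every pixel of cell (i, j)
  carries e_ij exactly;
- smooth = 100: bilinear (Delaunay-linear) interpolation of the
  off-diagonal cell-center values, nearest-neighbor fill outside their
  convex hull; cell centers are interpolation anchors;
- intermediate t: the per-pixel convex combination
  (1 − t/100)·discrete + (t/100)·continuous, blended in value space
  before color mapping. The blend definition is this package's choice
  (only the endpoint behaviors are canonical); the convex combination
  was picked for monotonicity in t.

Diagonal cells are masked after interpolation, so the empty diagonal
survives every smoothing level. Smoothing never touches the numeric
annotations, which are always formatted from the exact e_ij values
(default `%.1f`; annotation size 0 removes them). Annotation font
sizes map 1:1 to points except the value size, which is scaled ×4
(the native unit of the originating routine is smaller than a point).
A missing font family falls back to generic serif with a suppressible
warning. SVG export pins the hash salt and strips the creation date, so
rendering is byte-deterministic in its inputs. Supported formats: SVG
(default, convertible to editable objects downstream), PDF, PNG, PS,
JPG.

## Synthetic data

`generate_guttman` draws a uniform(0, 1) latent trait per respondent,
endorses item j iff the trait exceeds difficulty_j (a perfect
scalogram, so error_rate = 0 gives e ≡ 0 and H = 1 for every seed), then
flips each response independently with probability error_rate. The
uniform trait is the simplest model consistent with the scalogram
definition and is deliberately swappable; at rate 0.5 the responses are
independent Bernoulli(0.5) and mean e_ij converges to 100% of the
independence expectation, which the suite checks at n = 50,000 within
3 Monte-Carlo standard errors estimated from replicate runs.

`emulate_dataset` reproduces a confidentiality-preserving resampler:
(1) trim (uniform subsample without replacement — the trimming rule is
our reading; head-truncation would bias ordered sources) or expand
(resample with replacement) the source to n_target = 1000 rows; then,
per output row, (2) draw n_target candidates with replacement and (3)
pick one uniformly. Steps 2–3 compose to a single uniform draw; the
literal path is implemented so the procedure is testable as written,
with a fast single-draw path proven distributionally equivalent by a
chi-square test. Whole rows are resampled, preserving inter-item
dependence (the overlap profile) while matching item marginals in
expectation.

`generate_weights` draws log-uniform weights with both range endpoints
pinned into every fixture, echoing realistic survey-weight spans
(0.311–2.052; 2.699–5828.684).

What passing tests on these generators do not show: real response data
have item-specific error processes (not an exchangeable flip), latent
traits are rarely uniform, and real weight distributions are lumpier
than log-uniform. The generators exercise the estimator's limits and
invariances, not the sampling behavior of any particular instrument.

## Numerical choices and problem sizes

Tie-breaks in the endorsement ordering are stable by input position.
Equality tolerances in tests are 1e-12 for algebraic identities (error
counting vs covariance oracle, engine equivalence) and 3 Monte-Carlo SE
for stochastic limits. Oracle sweeps use 500 random 5-item matrices at
n = 200; engine-equivalence sweeps 100 fixtures at n = 50; independence
limits 8 replicates at n = 50,000 — sizes chosen to make the checked
identities sharp while keeping the default suite fast.

## Known limitations

No standard errors or confidence intervals for H (the point-estimate
focus is intrinsic to the method); no automated item selection,
monotonicity, or invariant-item-ordering checks; no design-based
variance estimation (strata/PSUs are ignored beyond the weights); no
imputation — missing responses are deleted listwise with a logged
count, a policy choice the data source does not dictate.
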
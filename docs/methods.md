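# Methods

## Anthropometric scoring

Z-scores are computed with the LMS method against gridded reference
tables (Box-Cox power `L`, median `M`, coefficient of variation `S`):

    z = ((x/M)^L − 1) / (L·S),      with the limit ln(x/M)/S as L → 0.

`L`, `M` and `S` are interpolated linearly between the two bracketing
grid rows; an index outside the grid makes the score *unavailable*
rather than extrapolated, and such children are excluded downstream
(reason `score_unavailable`). The log-limit branch is taken when
|L| < 1e−8, avoiding catastrophic cancellation near L = 0.

The weight-based indicators (WAZ, and WHZ) use the **restricted**
z-score standard in reference software: beyond ±3 SD the measurement
scale is extended linearly with the local SD2–SD3 spacing,

    z > +3:  z = 3 + (x − SD3) / (SD3 − SD2)
    z < −3:  z = −3 + (x − SD3⁻) / (SD2⁻ − SD3⁻)

where SDk is the measurement at z = k. The restriction is continuous at
±3, strictly increasing, and coincides with the plain score whenever the
reference is already linear (L = 1). Height-for-age is scored with the
plain formula.

WHZ is taken against the weight-for-length table below 24.0 months of
age and weight-for-height from 24.0 months. If the measurement position
contradicts the age standard, the height used for scoring (both HAZ and
WHZ) is converted by ±0.7 cm (standing under 24 months: +0.7; recumbent
at ≥24 months: −0.7); position `unknown` is left unadjusted. The
conversion is a config switch (`adjust_position`, default on).

## Inclusion, flags, country retention

A child is analyzed only if age, sex, weight, height and MUAC are all
present and age ∈ [6.0, 60.0) months. Oedema and measurement position
are not inclusion fields; a missing oedema cell is treated as no oedema.
Included children failing any plausibility flag are dropped entirely:
MUAC < 70 or > 220 mm, WHZ outside ±5, HAZ outside ±6, WAZ < −6 or > +5.
All flag bounds are strict — a child exactly on a bound is kept, reading
"outside ±5" literally; the choice only moves children sitting exactly
on a bound. One reason is recorded per child, with precedence
missing-field → age-range → flags (MUAC, WHZ, HAZ, WAZ) → unavailable
score. Countries contributing fewer than `min_surveys` (default 5)
surveys are removed from every stratum.

## Case definitions and program sets

With default thresholds (MUAC in mm, z-scores in SD):

| profile | definition |
|---|---|
| SAMmuac | MUAC < 115 or oedema |
| MAMmuac | 115 ≤ MUAC < 125, no oedema |
| SAMall  | MUAC < 115 or WHZ < −3 or oedema |
| MAMall  | (MAMmuac or −3 ≤ WHZ < −2) and not SAMall |
| SWAZ    | WAZ < −3 |
| WA+ST   | WHZ < −2 and HAZ < −2 |
| Target MUAC+SWAZ | MUAC < 115 or WAZ < −3 or oedema |
| Target ExpMUAC   | MUAC < 125 or oedema |

Each **supplement** is defined as the set difference target ∖ SAMmuac
rather than by re-stated threshold arithmetic. This makes
|target| = |SAMmuac| + |supplement| an exact identity (a child with MUAC
exactly 115 and WAZ < −3 belongs to the supplement) and keeps an
oedematous child with intermediate MUAC classified as SAM, never MAM.
Every threshold lives in one `Thresholds` object so variant strategies
(e.g., a different Expanded-MUAC cut-off) are configuration, not code.

## Metrics

All metrics are computed from pooled raw counts (children summed
survey → country → region → overall), never as means of per-survey
percentages. For target/supplement set T and condition C:
sensitivity = 100·|C∧T|/|C|; composition = 100·|C∧T|/|T|; size ratio =
|T|/|C|. Demographics report the share female and the share aged
6–23 months (age < 24.0; exactly 24.0 counts as older) within SAMall,
SAMmuac and the MUAC+SWAZ target. A zero denominator yields an
*undefined* marker rendered as a blank cell — never 0 or 100, which
would fabricate an extreme value in tiny strata. Rendered tables use
half-up rounding, percentages at 1 decimal and ratios at 2.

## The synthetic generator

The generator emulates population-representative two-stage cluster
surveys of children 6–59 months. Per cluster, one N(0, σ_c²) shift is
added to both the HAZ and WHZ means (shared environmental deficit);
per child, (HAZ, WHZ) is bivariate normal, height is the inverse
height-for-age LMS of HAZ at the drawn age, weight the inverse
(tail-extended) weight-for-length/height LMS of WHZ at that height, and
MUAC is linear in age and WHZ with Gaussian noise. **WAZ is never drawn**:
it emerges from the generated height and weight, which is what makes
severe underweight overlap stunting — the mechanism the MUAC+SWAZ
strategy leans on. Oedema is a rare independent Bernoulli event.
Measurements are rounded to instrument precision (weight 0.1 kg, height
0.1 cm, MUAC 1 mm; each disableable). A draw whose height leaves the
weight-for-height grid is redrawn (and counted), not clipped — clipping
would pile probability mass exactly where the plausibility flags
operate. One seeded stream per survey (spawned from the root seed in a
fixed order) makes any survey reproducible in isolation.

The synthetic LMS reference uses smooth parametric forms — height
median 45 + 35·ln(1 + t/12) cm (male ×1.01), weight-for-height median
6.26·10⁻⁴·h^2.19 kg (male ×1.03), and a weight-for-age median *composed*
from the two so a child at the median of every table scores 0 on all
three indicators — with constant L and S per indicator (hfa: L = 1,
S = 0.035; wfl/wfh: L = −0.35, S = 0.11; wfa: L = −0.25, S = 0.15).
These magnitudes are realistic for 6–59-month children but the tables
are synthetic, not WHO values.

Default conditions (chosen once, as a plausible high-burden humanitarian
setting, and validated against `true_prevalence`): HAZ mean −1.25 SD 1.1,
WHZ mean −0.85 SD 1.0, correlation 0.25, cluster-shift SD 0.3, MUAC
model 129.5 + 0.4·age(months) + 5.0·WHZ + N(0, 8²) mm, oedema 0.5%, ages
uniform on [6, 60). Under these defaults roughly 2% of children are SAM
by MUAC/oedema, 4% SAM by any criterion, 7–8% severely underweight and
6% concurrently wasted and stunted — prevalences of the order reported
by large pooled humanitarian survey collections, i.e. the regime in
which MUAC- and WAZ-based screening genuinely disagree. The default
collection is 6 countries × 10 surveys × 25 clusters × 20 children
(30,000 children), large enough that overall-aggregate percentages are
stable to a few tenths of a point while the whole pipeline runs in
seconds.

`true_prevalence` draws children down the *same* generative path
(including per-child cluster shifts, rounding and the exclusion rules)
without survey assembly and reports each category probability with its
binomial standard error; parameter-recovery tests compare pooled
pipeline prevalences on 100 simulated surveys against a 10⁶-draw truth,
combining the standard errors of both Monte-Carlo estimates (the
pipeline side uses the between-survey dispersion, which absorbs the
cluster design effect).

### What the generator does not emulate

No digit preference, age heaping, inter-observer error or gross data
entry errors — so flag rates are near zero rather than the fractions of
a percent seen in field data. No survey weights or non-response. MUAC is
conditionally Gaussian given age and WHZ, with no direct stunting
pathway. Country differences are limited to independent seeds: the
generator deliberately does not calibrate per-country prevalences to any
published table, so passing tests demonstrate correctness of the
*pipeline arithmetic and its identities* on realistic magnitudes, not
agreement with any field dataset's cell values.

## Numerical choices

* L→0 switch at |L| < 1e−8; round-trip inverse/forward agreement is
  tested to 1e−9 over 10⁴ random parameter draws.
* Linear interpolation of L, M, S on the grid (1-month ages, 0.5-cm
  heights); scoring at a grid point equals the raw row exactly.
* NaN propagates as the "unavailable" signal through scoring and can
  never satisfy a flag or case comparison.
* Generator redraw cap: 100 rounds, then a hard error (a configuration
  whose draws almost never land on the reference grid is a user error).
* Table rendering uses decimal half-up rounding to match conventional
  survey-report precision exactly; internal JSON summaries keep full
  float precision.

## Known limitations

* The evaluation is cross-sectional: it says which children each
  strategy admits, nothing about treatment outcomes or mortality risk.
* Pooled metrics carry no confidence intervals or design-effect
  corrections, matching the pooled-count estimand; survey-level
  dispersion is available from the per-survey strata if needed.
* The synthetic reference is not the WHO 2006 standard; real-data runs
  must load real LMS tables through the same file interface.
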
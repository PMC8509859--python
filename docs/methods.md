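# Methods

This note documents the models and procedures implemented in `actisleep`,
the choices made where the design was genuinely open, and what the bundled
synthetic data can and cannot establish.

## Hypnogram representation

A recording is an ordered, gap-free tiling of the wear span by half-open
intervals `[start, end)` labeled sleep or wake.  The half-open convention
means abutting bouts never double-count an instant, so every duration
identity downstream (sleep + wake = span) holds exactly.  Timestamps are
timezone-naive local clock time; recordings that span a daylight-saving
transition are assumed to have been excluded upstream and no DST arithmetic
exists anywhere in the package.  Nonwear periods arrive as *imputed* bouts
carrying a probability of sleep; they are resolved to sleep iff
`p_sleep > 0.5` (strict), and the imputed flag survives resolution so the
day-level imputation filter can still see which minutes were imputed.  One
probability per bout is assumed; sub-bout probability structure is not
modeled.  A participant whose file violates the interval invariants
(overlaps, gaps) is dropped with a logged reason rather than aborting the
batch; an unparseable row is a hard error, since it indicates a malformed
file rather than a bad participant.

## Primary sleep period

Within bouts coalesced into maximal same-state runs (the imputed flag is
ignored here; it matters only for data-quality filtering):

1. *anchors* are sleep runs ≥ 30 min;
2. consecutive anchors chain when the time from one anchor's end to the
   next anchor's start is ≤ 60 min — whatever fills the gap (wake or
   sub-30-min sleep) counts toward the gap clock and does not reset it;
3. each maximal chain spans first-anchor start to last-anchor end;
4. the primary sleep period (PSP) is the chain with the longest *span*
   (not the largest total sleep), ties broken to the earliest onset.

"Longest span" was chosen because the defining phrase is a *time period*;
the tie rule exists purely for determinism.  Inside the PSP, all sleep
counts as sleep (including sub-anchor bouts), all wake is WASO, maximal
wake runs are awakenings, and the longest maximal sleep run is the longest
sleep bout.  Naps are maximal sleep runs wholly outside the PSP that are
strictly longer than 30 minutes — note the deliberate asymmetry with the
≥ 30-min anchor rule, which mirrors how the two thresholds are
conventionally stated.  The detector is validated against a brute-force
oracle that enumerates every contiguous anchor subsequence.

## Days, validity, and aggregation

Days run 3 PM → 3 PM, indexed from the first 15:00 at or after the
recording start.  Per-day clock measures are expressed in hours since
midnight of the date on which the window opens, so 11:30 PM is 23.5 and
1:00 AM the next morning is 25.0.

The PSP for a day is detected on the day's bouts extended by a ±6 h margin:
clipping first would make a boundary-crossing sleep period undetectable.
Among detected chains, the day's PSP is the longest-span chain overlapping
the window.  Invalidity reasons, in precedence order:

1. `no_qualifying_sleep` — no sleep run ≥ 30 min touches the day;
2. `psp_crosses_boundary` — the PSP extends past a 15:00 boundary;
3. `imputed_gt_10pct` — more than 10% of the day's 1,440 minutes imputed
   (denominator is always the full 1,440, a conservative, deterministic
   choice even for partially covered windows);
4. `partial_coverage` — windows not fully covered by the recording are
   invalid even when rules 1–3 pass.

Participant-level measures are medians across valid days; per-day sleep
efficiency (`sleep/span`, identically `1 − WASO/span`) is medianized as a
per-day quantity rather than recomputed from median WASO and median span,
matching the reading of efficiency as a per-day fraction.  The two
variability measures use the *unscaled* median absolute deviation
(`median |x_i − median x|`, no 1.4826 consistency factor); a
mean-absolute-deviation variant is exposed via `variability="mean"` because
the two conventions coexist in the actigraphy literature and the choice
deserves to be explicit.  Participants are excluded with fewer than 2 valid
days or a median wake-up of ≥ 36.0 h (clock noon of the post-midnight day)
— the operationalization of "habitual afternoon waker", configurable.

## Cohort construction

Disorders are inclusive 3-character ICD-10 prefix sets (F32.1 ∈ F32–F33):
schizophrenia spectrum F20–F29, bipolar/mania F30–F31, major depressive
disorder F32–F33, anxiety F40–F41, plus the union composite.  Per disorder:
a participant with an inpatient record on or before the accelerometry date
is a **case** (even if non-inpatient records coexist; the exclusion rules
exist to protect the control group, not to unmake cases).  A non-case is
**excluded** when their first inpatient record postdates accelerometry, or
when any in-range primary-care/death/self-report record exists — undated
self-reports also exclude, since "preexisting" cannot be verified without a
date; this is deliberately conservative and may exclude slightly more
participants than a date-gated rule.  Everyone else is a **control**.  The
composite is case if case anywhere, else excluded if excluded anywhere,
else control.  Exclusions reach the regression stage as NaN exposures, so
each disorder's battery automatically drops exactly its excluded set.

## Polygenic risk scores

Harmonization matches summary statistics to cohort genotypes on chrom:pos:
strand-ambiguous variants (A/T, C/G) are dropped; effect/other alleles are
matched to alt/ref directly, after swapping (flipping the dosage axis,
`d → 2 − d`), or after strand complementation; residual mismatches are
dropped; duplicate positions keep the first occurrence.  Thresholding is
strict (`p < 0.05`).  Pruning is greedy: variants visited in descending
minor-allele frequency (ties by position), each kept variant eliminating
later variants on the same chromosome within ±500 kb whose dosage r²
(squared Pearson correlation, pairwise-complete) exceeds 0.2.  The
descending-MAF visit order is this package's operationalization of
"frequency-informed" pruning; it is a documented stand-in for tool-specific
behavior that is not publicly pinned down.  Zero-variance variants have
undefined r² and are treated as unlinked (r² = 0, logged).  Scores are the
weighted dosage sums with per-variant mean imputation of missing genotypes
over the scored cohort (the only panel in hand), and are z-standardized by
default so that battery coefficients are per SD of PRS.  Genome-build
concordance between inputs is the caller's responsibility; no liftover is
attempted.

## Association battery

Each of the 10 measures is regressed on each exposure with OLS, adjusting
for age, season (meteorological quarters, categorical with winter
reference), sex, Townsend index, and PC1–PC10.  Outcome and exposure are
z-scored — binary exposures on their 0/1 coding — making the exposure
coefficient a standardized β comparable across measures and exposures.
Confidence intervals and p-values use normal critical values, appropriate
at cohort sizes in the thousands (configurable in principle via the
residual t if ever needed at small n).  Constant exposures raise a
degenerate-exposure error; fits below a configurable n floor (default 30)
are emitted as flagged rows, never silently dropped.  Benjamini–Hochberg
step-up adjustment is applied across all fitted tests of a battery run by
default; a per-exposure family is available because the correct family is a
genuine analysis choice, not derivable from first principles.  The BH
implementation is validated against the reference implementation in
statsmodels to 1e-12.

## Synthetic cohort

The generator works at two levels.

**Full bundle** (`generate`): per participant, latent bedtime and sleep
duration means are drawn from between-person normals (defaults: bedtime
23.3 h ± 1.0, duration 7.9 h ± 0.8) anchored to typical community-cohort
medians; each night draws within-person noise (±0.5 h, ±0.6 h), a
Poisson(1.2) number of awakenings of 3–12 min placed inside the sleep
period, a >30-min afternoon nap with probability 0.3, and a nonwear/imputed
block with probability 0.15 per day.  Hypnograms are rendered on a
one-minute grid (so conservation identities are exact) and run-length
encoded into bouts, which satisfy all recording invariants by construction
— asserted at generation time, not assumed.  Genotypes are binomial(2, MAF)
with planted LD (every tenth variant a noisy copy of its neighbor) and an
additive liability over 30 causal variants; diagnoses follow a
liability-threshold model at the configured prevalences (defaults match
inpatient-diagnosis rates of roughly 1.7%, 0.9%, 0.14%, 0.08% for
depression, anxiety, bipolar, schizophrenia); GWAS summary statistics come
from an *independent* simulated panel so that PRS construction is evaluated
out-of-sample.  Contaminating records (primary-care/death/self-report, and
post-accelerometry inpatient) are sprinkled at low rates to exercise the
exclusion rules.  Planted diagnosis effects shift the latent per-person
means; the renderer honors bedtime, sleep-duration, and nap-propensity
effects.

**Measure-level simulator** (`simulate_association_cohort`): draws the 10
participant measures directly as unit-variance Gaussians composed of
planted standardized effects on z-scored exposures, a fixed covariate
contribution (R² = 0.2 via age/sex/Townsend loadings), and independent
noise.  Planting effects on the measures themselves makes the battery's
estimand *exactly* the planted value, which is what calibration studies
(type-I error, effect recovery, CI coverage) need; Gaussian outcomes also
make OLS p-values exact, so calibration checks test the battery code rather
than distributional approximations.

All randomness flows from one seeded generator with per-participant
substreams; a fixed config yields byte-identical bundles.

What the synthetic data does **not** emulate: real accelerometer
misclassification (awake-in-bed scored as sleep), truly fragmented sleep
phenotypes, correlated measure noise, population structure in genotypes,
age/sex effects on sleep, or diagnosis-date information content.  Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under the stated generative model — not that the
pipeline's epidemiological conclusions transfer to any real cohort.

## Problem sizes and numerics

The validation studies use sizes chosen to make the statistical assertions
sharp while keeping the suite quick to run: 1,000 random bout sequences for
the detector oracle; 25 null batteries of 80 tests at n = 10,000 (2,000
tests) for type-I error, giving a binomial 95% band of ±0.0096 around 0.05;
500 replicates at n = 10,000 for effect recovery (Monte-Carlo SE of the
mean estimate ≈ 0.0004, far inside the ±0.01 assertion); 100 random
50-variant instances for the pruning maximality oracle.  Durations are
exact minute arithmetic throughout; equality assertions on conserved
quantities use 1e-9 slack only to absorb float division in the efficiency
identity.

## Known limitations

- The boundary-crossing test uses a ±6 h detection margin; a sleep period
  extending more than 6 h past a 3 PM boundary would be truncated before
  crossing is assessed.  At that point the "day" assignment itself is
  ill-posed; such days are rare and almost always invalid anyway.
- Frequency-informed pruning is a documented greedy stand-in (above), not
  a reimplementation of any specific tool's flag semantics.
- Season is categorical; harmonic seasonality terms are not implemented.
- The afternoon-waker and undated-self-report rules are deliberately
  conservative operationalizations of informally stated criteria.
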
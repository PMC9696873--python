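# Methods

## The measurement model

The package analyses the classic test–retest design of performance
testing: n subjects, k test sessions separated by days to weeks, T trials
per session per test. A trial-level measurement is modelled as

    y_ijt = μ + δ_j + b_i + s_ij + ε_ijt

where μ is the grand mean, δ_j a *fixed* shift of session j (a learning
or fatigue effect — fixed rather than random because it is exactly the
"systematic bias" the repeated-measures ANOVA targets), b_i ~ N(0, σ_b²)
the subject's stable level, s_ij ~ N(0, σ_s²) the subject-by-session
interaction (day form, sleep, motivation) and ε_ijt ~ N(0, σ_e²)
trial-to-trial noise. Gaussian components are the modelled regime
throughout, because the design's normality gates are expected to pass for
these outcomes; a lognormal option exists to exercise gate failure.

Trials are collapsed to session scores under one of three rules: *Avg*
(mean of the session's trials), *Hv* (highest trial) or *Lv* (lowest
trial; only for hop contact time, where short contacts are better).
Reactive hops have an extra level: each session holds 2 sets of up to 10
hops, hops flagged as heel contacts are discarded, and each set
contributes one "trial" per outcome — the *maximum* peak force over its
valid hops and the *mean* contact time of its valid hops. A set with no
valid hop is a hard error at analysis time; the generator instead redraws
such a set's validity flags, as an athlete would simply repeat the set.

## Statistics

**ICC (relative reliability).** Two-way model, absolute-agreement
definition: ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))
for single session scores (Hv/Lv) and ICC(A,k) = (MSR − MSE)/(MSR +
(MSC − MSE)/n) for k-session averages (Avg), from the complete-matrix
mean squares MSR (subjects), MSC (sessions), MSE (residual). Confidence
intervals use the F-based method with Satterthwaite denominator degrees
of freedom; the ICC(A,k) interval is the single-score interval stepped up
with Spearman–Brown, L → kL/(1 + (k−1)L). The point estimate is the same
under two-way random and two-way mixed readings of the model; the CI is
the agreement-definition one that standard implementations (R's `irr`,
Python's `pingouin`) produce, and the test suite pins the implementation
to `pingouin` as an independent oracle. Estimates below zero are reported
as computed, never clamped — clamping hides degenerate data. A matrix
with no variance at all raises; a perfect-agreement matrix returns
ICC = 1 with the CI collapsed to [1, 1] and a logged note.

Qualitative bands follow Koo & Li with the boundaries read literally:
values below 0.50 are poor, 0.50–0.75 moderate, above 0.75 up to and
including 0.90 good, and strictly above 0.90 excellent.

**CV% (absolute reliability).** The printed formula SD/mean × 100 does
not fix the pooling level; "within-subject variation" does. The default
is therefore each subject's sample SD across the comparison's sessions
over their own mean, averaged across subjects. A pooled alternative
(RMS within-subject SD over the grand mean) sits behind a config switch.
Any subject mean ≤ 0 makes the CV undefined and raises.

**Bias test.** One-within-factor repeated-measures ANOVA on session,
F = MSC/MSE with (k−1), (n−1)(k−1) degrees of freedom, run for the full
design and each pair; for k = 2 it is exactly the squared paired t test.
No sphericity correction is applied by default (a Greenhouse–Geisser
option exists) and no multiple-comparison correction is applied across
variables or comparisons — deliberately, to mirror standard practice in
this literature; interpret the per-comparison α accordingly. Zero
residual variance with a genuine session effect reports p = 0 with a
degenerate flag rather than dividing by zero.

**Distribution gates.** Shapiro–Wilk per session column (skipped with a
warning below n = 3) and Levene across columns (mean-centered classic
form by default, median-centered by config). Gates are advisory: they log
and report, but never abort the analysis.

**Sensitivity chain.** SD_pooled is the root of the mean of per-session
sample variances (the standard equal-n pooled SD; a mean-centered
all-cells variant is available by config), mean_pooled the mean of
session means, both over exactly the comparison's sessions. Then
SEm = SD_pooled·√(1 − ICC) with the point ICC of the matching form
(mean-form for Avg rows, single-form for Hv/Lv rows, as each reliability
table row is paired with its sensitivity row), SWC = 0.2·SD_pooled
(0.2 = the "small" standardized effect; config-exposed),
MD = SEm·1.96·√2 ≈ 2.772·SEm, and SEm%/MD% as percentages of
mean_pooled. The verdict "sensitive" is the strict inequality SEm < SWC,
which for fixed SD flips exactly at ICC = 1 − 0.2² = 0.96.

## Published-table re-derivation

The motivating nine-week study's raw data are unavailable, but its
printed summary tables are internally redundant. `retestkit.published`
stores the printed numbers as strings (so each carries its display
precision) and re-derives MD from SEm, SEm% and MD% from the printed
session means, and SWC from the printed SDs, propagating each operand's
half-unit rounding interval; a relation is consistent when the propagated
interval overlaps the printed value's own interval. 183 of 192 relations
are consistent. The nine failures are documented in
`KNOWN_DISCREPANCIES` and are properties of the printed tables, not of
the arithmetic: one SEm% cell (jump height, highest value, all sessions)
prints 2.7% where its own row implies 3.7%, and the knee-extension SWC
column implies an unrounded pooled SD about 2% below what the
whole-number printed SDs give. The acceptance suite asserts that the
inconsistent set is exactly this documented list.

## The synthetic reference study

`reference_fixture()` generates one fixed-seed dataset shaped like the
motivating study: 17 subjects, sessions S1–S3, 3 trials per session for
knee-extension torque (≈256 ± 90 Nm), handgrip force (≈46 ± 12 kg), jump
height (≈44 ± 11 cm) and jump peak power (≈46 ± 10 W/kg), plus 2×10 hops
per session with a 5% heel-contact rate. Between-subject SDs match the
printed descriptives; interaction and trial SDs are set so session CVs
land in the printed 2–8% band and the implied ICCs sit where the study
found them (≈0.99 for the strength/jump outcomes). Session effects are
zero for those four variables — the study found no systematic bias there
— while hop peak force carries shifts (−0.05, −0.02, +0.24) kN, a
realistic motor-learning effect that makes the S1–S3 and S2–S3 bias
tests fire, and hop contact time is interaction-dominated
(σ_s ≈ σ_b ≈ 0.011 s), putting its true ICC near 0.45 so the estimate
lands in the poor-to-moderate band.

Seeding: one master seed with fixed per-variable substreams
(`default_rng([seed, stream])`), so adding a variable never perturbs
another's draws and every output is byte-reproducible. Within a session
the interaction draw is shared across both hop sets; per-hop noise is
independent. Trial values are clipped at zero (scores are nonnegative);
at the fixture's scales clipping is rare and logged.

What the generator does *not* emulate: force–time waveforms, within-
session fatigue or ordering effects, inter-day biological drift beyond
fixed session shifts, heteroscedasticity across the ability range, and
non-Gaussian tails (except the lognormal test option). Passing tests on
this generator therefore validate the statistical machinery under the
model's assumptions, not the field behaviour of any specific device.
One consequence of honest sampling at n = 17: a 5% bias test fires
occasionally on null data, and at the packaged default seed the
knee-extension stream happens to be such a ~2% tail draw.

## Simulation studies and their sizes

`simulate_icc_recovery` draws replicate datasets at the design size
(default n = 17, k = 3, T = 3), forms Avg scores and runs the package's
own ICC path, reporting the mean estimate and empirical 95% CI coverage;
the default study size of 500 replicates gives a coverage standard error
of about 1%. The ANOVA ICC estimator is known to be biased slightly
downward at small n: at a generating ICC(A,1) of 0.5 the mean estimate
sits about 0.02 low at n = 17 (the bias shrinks toward zero as the ICC
approaches 1), which is the expected behaviour of the estimator, not an
implementation artefact. `simulate_bias_power` puts a shift of
0.5·σ_b on the last session only and reports per-pair rejection rates
against the matched null; with the default noise settings the straddling
pairs reach power ≈ 1 while false-positive rates stay at the nominal 5%.

## Numerical choices

Mean squares are treated as exactly zero below a relative tolerance of
1e−12 on the squared data scale, which routes degenerate matrices to the
explicit special cases above instead of amplifying float noise. Ties in
Hv/Lv aggregation return the tied value itself (no index), so trial order
never matters. Report tables round to the journal's conventions (ICC 3
decimals, percentages 1 decimal, unit values at each variable's display
precision: 1 decimal for Nm/kg/cm/(W/kg), 2 for kN, 3 for s); every
downstream consumer reads the full-precision sidecar CSVs instead.
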
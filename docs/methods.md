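# Methods

## Observer model and synchrony fitting

An SJ observer answers "synchronous" with probability

    p(x) = (1 − λ) · A · exp(−(x − μ)² / (2σ²)) + λ/2

at signed SOA `x` (ms; negative = auditory first). `A ∈ (0,1]` is the peak
synchrony probability, `μ` the curve center (the generative PSS), `σ > 0`
the width, and `λ ∈ [0,1]` a stimulus-independent lapse split evenly across
the two responses — the standard psychophysics convention. The TOJ observer
reports "visual first" with probability
`(1 − λₜ)·Φ((x − μₜ)/σₜ) + λₜ/2`. The TOJ model is a stand-in: the analyses
only consume TOJ *error percentages*, so its parameters are unconstrained
by any published fit; group defaults were chosen to produce a
CD > TD > AD error ordering in the visual-leading condition.

Fitting uses *unweighted* nonlinear least squares of the three-parameter
Gaussian `A·exp(−(x−μ)²/2σ²)` on the 16 observed proportions (equal trial
counts per point make weighting moot). The lapse is deliberately not a fit
parameter: with a 2 % default lapse the induced bias in the recovered mean
window is under 1 ms at study scale (measured by `validation.
parameter_recovery`), far below the between-subject spread. Initialization
is moment-based (μ₀ = proportion-weighted mean SOA, σ₀ = weighted SD,
A₀ = max proportion) plus two deterministic perturbations (μ₀ ± 50 ms,
σ₀ × 0.6 / × 1.8); the lowest-SSE solution wins. Bounds: A ∈ (0, 1],
μ ∈ [−600, 600] ms, σ ∈ [5, 2000] ms. A solution with σ pinned at its upper
bound is reported as non-converged: the curve is flat over the data and the
width is not identifiable (e.g. all-ceiling responses).

## Window extraction

The criterion is an **absolute** 70 % synchrony line. The crossings are
available in closed form, `x = μ ± σ·√(2 ln(A/c))`; the left crossing
magnitude is the AV half-window, the right crossing the VA half-window,
`TBW = AV + VA`, `PSS = (VA − AV)/2 = μ`. A `criterion_mode =
"relative_to_peak"` switch instead places the line at `c·A`, since part of
the precedent literature uses relative criteria. Statuses per side:
`detected`, `beyond_range` (crossing outside the 500 ms tested range),
`below_criterion` (A ≤ c), `no_fit`. A left crossing on the positive side
(window entirely visual-leading) clamps the AV half-window to 0 and sets a
flag; the mirrored case clamps VA. By default a `beyond_range` side
contributes no number and the participant is excluded listwise from window
analyses; `censor_beyond_range=True` right-censors at 500 ms instead.

Participant classification order: chance-level (max observed proportion
≤ 0.55), ceiling on the VA side (all VA proportions ≥ 0.90 with no VA
crossing in range), flat response (observed span < 0.45), optimizer
failure, crossing beyond range, and a fitted curve that never reaches the
criterion (counted as flat — its variation range cannot cross the line).
The span default of 0.45 sits between the expected observed range of a
truly flat responder at 20 trials/point (≈ 0.37) and that of the flattest
admissible clean observer (≳ 0.6). Anything other than `ok` is excluded;
exclusion percentages are rounded half-up to 2 decimals.

## Synthetic cohort

The default cohort emulates a three-group developmental study: 53 dyslexic
children (CD), 53 typically developing children (TD), 37 adults (AD), the
last two adults TOJ-only. Group observer parameters are truncated normals.
The width distribution is derived from target window statistics: with the
criterion crossing the *effective* curve at
`d = σ·√(2 ln((1−λ)A / (c − λ/2)))`, setting `σ = TBW/2 / √(2 ln(…))`
makes the group's true mean total window equal its target (CD 394.29 ms,
TD 316.34, AD 318.12; SDs 181.31/169.97/138.12), and the PSS target maps
directly onto μ (44.13/28.43/4.78; SDs 57.02/58.11/47.73). A = 0.95
(SD 0.03, truncated [0.8, 1]), λ = 0.02 (SD 0.01, [0, 0.06]). Raw
truncated-normal means are calibrated numerically so the post-truncation
means hit the targets exactly.

Truncation corners — μ ∈ [−120, 150] ms, σ ∈ [60, 400] ms — are chosen so
that the farthest true crossing (μ_hi + d(σ_hi) ≈ 460 ms) stays ~40 ms
inside the 500 ms range: a clean observer is never truly beyond range, and
sampling noise only rarely (≈ 1 cohort in 8) pushes a fitted crossing past
it. The truncation narrows the realized between-subject SDs some 10–15 %
below the configured values; all group-level checks are on means and
signs, which are unaffected.

Each group contains a fixed number of degenerate observers exercising the
failure taxonomy: CD 8 (1 VA-ceiling, 4 chance with λ = 1, 3 flat with
A = 0.62, λ = 0.15, σ = 1600 ms), TD 4 (3 ceiling, 1 chance), AD 3
(ceiling), placed at seeded-random positions among SJ-taking participants.
Noise can relabel a degenerate observer between the non-ok codes, but all
of them are excluded, so fitted group sizes are 45/49/32 by construction.

Behavioral scores: per-group normal draws with the configured means/SDs,
clipped to instrument ranges (phonological awareness 0–40, orthographic
knowledge 0–80). Children's reading fluency is
`mean_g + sd_g·(0.29·z_PA − 0.43·z_RAN − 0.17·z_VATBW + 0.838·ε)`, with
predictors standardized against their configured moments (the VA
half-window against its within-group sample moments) and the residual
fraction chosen as √(1 − Σw²) so the marginal SD matches its target.
Character recognition uses weights (0.30, −0.35, 0) — literacy skills
predict it, the window does not. Adults receive demographics only.

Seeding: a master seed fans out to per-participant substreams via
`SeedSequence([master, crc32(participant_id), stream])`, so adding a
participant never perturbs another's data; identical configs produce
byte-identical CSVs. Trial order within a session is a seeded permutation
(it provably does not affect any aggregate; tested). Reaction times are
uniform placeholders in [400, 1500] ms; timeouts are off by default (their
handling — exclusion from denominators — is a policy, since how such
trials were scored in the emulated design is unstated).

### What the generator does *not* emulate

Independent Bernoulli trials: no sequential dependencies, learning,
fatigue, or attention drift across blocks; no RT–accuracy coupling;
symmetric single-σ synchrony curves (real observers are often asymmetric);
Gaussian score distributions without floor/ceiling clumping. Passing tests
therefore validate the *estimators and statistics under the stated model*,
not robustness to real-data pathologies.

## Statistics

- Mixed ANOVA (between = group, within = 8 ISIs, per order) via pingouin,
  no sphericity correction by default (the design's uncorrected dfs are
  (2, N−3) and (7, 7(N−3))); Greenhouse–Geisser available via `correction`.
- Simple effects: one-way group ANOVA at each ISI (an interpretation —
  the error-term construction for follow-ups is ambiguous in the emulated
  analysis; per-ISI one-way is the transparent choice).
- LSD post hocs: unadjusted pairwise t on the pooled within-cell error
  term, df = N − g. Implemented directly; no multiplicity adjustment by
  design.
- Paired VA-vs-AV contrast: one-within repeated-measures F (df 1, n−1);
  equals the squared paired t (tested).
- ANCOVA: homogeneous-slopes model, group F at (g−1, N−g−1); adjusted
  means from an OLS at the grand covariate mean; a group × covariate
  interaction p is emitted as a slope-homogeneity diagnostic. The SJ
  covariate is order-specific by default (`covariate="overall"`
  available) — the emulated description is ambiguous between the two.
- Hierarchical regression: blocks (gender, age, Raven) → (+PA, RAN) →
  (+window measure); all variables z-scored (gender 0/1 first) so
  coefficients are standardized β; ΔR² with F-change p per block;
  rank-deficient blocks raise naming the block.
- Demographics: independent t (df n₁+n₂−2) for continuous measures,
  Pearson χ² without continuity correction for gender/grade.
- Partial η² = SS_effect/(SS_effect + SS_error) for every effect.

## Validation choices

Null-calibration simulations run 1,000 replicates per test at modest cell
sizes (20 per group; 4 within-levels for the mixed ANOVA; n = 60 for the
regression) — under the null the rejection rate is size-free, so small
cells are a pure speed choice. The replicate-cohort power check runs 200
child-only cohorts through the full simulate → aggregate → fit → group-mean
pipeline. The crossing oracle compares the closed-form crossings against
Brent root-finding at xtol 1e-12 over 1,000 random curves constrained to
straddle zero (the clamped cases are policy, not crossings). Degenerate
inputs: profiles with fewer than 16 valid points are not fitted; a zero
total-variance profile gets an undefined R²; empty groups raise.

## Known limitations

The absolute-70 % criterion cannot produce windows for observers whose
peak synchrony is below 0.7 — a real phenomenon in the emulated population
(handled by exclusion), but it makes the TBW undefined rather than wide.
The three-parameter fit ignores the lapse floor, which inflates fitted σ
by a small amount that grows with the true lapse. Single-cohort ANOVA
F-values are not reproducible quantities — only their dfs, calibration and
effect directions are meaningful checks, and the published group means are
targets for the generator, not for the fitted output of any single seed.
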
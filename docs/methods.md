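# Methods

This note documents the models and procedures implemented in `propriokit`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic cohorts do and do not emulate.

## The APM task and its parameters

A session is 54 trials: nine targets on a 20 cm × 20 cm grid (eight outer
targets around a centre target), each visited once per block in pseudorandom
order, six blocks. The robot moves the affected arm; the participant
mirror-matches with the other arm, and matched positions are reflected
across the body midline (x only) into the robot's workspace before any
computation.

The parameter definitions are this package's normative definitions, chosen
to match the standard qualitative descriptions of the task and the known
directionality of each measure (they may differ in detail from proprietary
analysis software):

* **Absolute Error** (m, per axis): mean of |mirrored match − robot| over
  all 54 trials.
* **Variability** (m, per axis): sample (n−1) SD of the mirrored match
  across each target's six repetitions, averaged over the nine targets.
* **Contraction/Expansion** (ratio, per axis): range of the per-target mean
  mirrored matches across the eight outer targets, divided by the range of
  the corresponding robot targets. 1 = veridical, <1 = contracted
  workspace. The centre target is identified as the per-target robot mean
  nearest the target centroid, so the definition does not depend on target
  numbering.
* **Shift** (m, per axis, signed): mean of (mirrored match − robot).

Absolute error is per-axis (not Euclidean) because the downstream feature
set scores X and Y separately. These definitions give two useful exact
invariants used by the tests: absolute error ≥ |shift| per axis, and pure
translations move shift/absolute error while leaving variability and
contraction untouched.

`APMSession` enforces the full 9×6 protocol by default; `strict=False`
admits partial sessions (aborted runs, toy analyses), and each parameter
function demands only the structure it needs (variability, for instance,
requires ≥2 repetitions per target present).

## The normative engine

Raw parameters are skewed and demographically confounded, so scoring is a
six-step chain fitted on a control population:

1. **Box-Cox.** Location shift `1 − min` when the minimum is ≤ 0 (else 0),
   exponent chosen by profile maximum likelihood on the fixed grid
   [−5, 5] in steps of 0.01. The grid keeps the fit deterministic and
   reproducible to the last digit; 0.01 resolution is far below the
   sampling noise of the exponent at any realistic n.
2. **Trimming.** Transformed values beyond ±3.29 SD (two-sided 10⁻³ tail)
   are removed once, after the transform and before the regression. The
   alternative order (trim after regression) is defensible; this order
   treats the trim as cleaning the marginal distribution the transform is
   meant to normalise.
3. **Weighted regression** of the transformed parameter on age (years),
   sex (female = 1) and handedness (left = 1), with per-observation weight
   1/(sessions contributed by that subject) so frequently re-assessed
   subjects do not dominate. The residual SD is the weighted RMS residual.
4. **z-scores**: z = (transformed − predicted)/residual SD. Raw values
   below the Box-Cox domain are scored at the domain edge with a warning
   flag rather than rejected — a stroke participant with, say, zero
   variability in a degenerate session still gets a (very negative) score.
5. **Folding and RSS.** Absolute error and variability are one-sided (only
   large values are abnormal): folded as max(z, 0). Shift and
   contraction/expansion are two-sided (deviation in either direction is
   abnormal): folded as |z|. The composite is the root sum square of the
   eight folded scores, itself Box-Cox transformed and standardised by a
   mean/SD learned on the same controls.
6. **Zeta transform.** ζ = Φ⁻¹((Φ(z)+1)/2), the half-normal quantile map.
   If z is standard normal, ζ is distributed as |N(0,1)|, so
   P(ζ < 1.96) = P(z < 1.645) = 0.95 — this is what makes 1.96 a 95th
   centile impairment threshold by construction. Implemented through
   log-space tail quantities (`log_ndtr`/`ndtri_exp`) so arbitrarily large
   z neither overflows nor saturates prematurely.

The directionality assignment in step 5 is a package decision; the
convention only fixes which side of the control mean counts as "bad" and is
tagged per parameter in the serialised model (a single JSON document with a
schema version). Fitting requires ≥50 control observations; the ≥20-value
floor on the Box-Cox and trim primitives guards the degenerate small-sample
regime.

## Synthetic cohorts

No public trial-level dataset pairs APM sessions with clinical scores and
lesion masks, so the package ships a generative model. A single
non-negative latent severity `s` per stroke participant drives every
modality; all effect sizes live in `SyntheticConfig`.

**Controls** (defaults: 799 subjects, 1 + Poisson(1.79) ≈ 2.8 assessments
each, ages uniform on 20–85, sexes balanced, ~10% left-handed — real
normative cohorts are strongly right-handed, so "balanced handedness" would
be unrealistic). Matched positions are the mirrored robot positions
distorted by an affine workspace scale about the workspace centre
(per-assessment jitter, SD 0.05/axis), a constant per-assessment bias
(SD 6 mm/axis) and i.i.d. trial noise. Trial-noise SD is 8 mm at age 20 and
rises 0.1 mm/year, with +1 mm additive terms for female sex and
left-handedness — structure for the normative regression to remove. Bias
and scale are modelled at the assessment level (set-up and postural drift
of the day) rather than as lifelong subject constants; this matches how
repeat assessments vary and keeps the effective sample for normative
calibration at the assessment count rather than the subject count.

**Stroke participants** (defaults: 133; ages N(60.2, 13²); 32% female; 59%
left-affected). Severity at two weeks follows a two-component mixture:
a half-normal mass near zero (SD 0.15; mild strokes) and a log-normal tail
(median 1, log-SD 0.5; substantial deficits), with tail membership odds
shifted by +1.2 log-odds for left-affected (right-hemisphere) participants
— proprioception is right-lateralised, and this reproduces a clearly
significant left > right Task Score difference at study scale. Half the
cohort recovers: their severity shrinks by 45% between two weeks and six
months. Severity raises trial-noise SD (+5 mm per unit) and contracts the
perceived workspace (−0.07 scale per unit); the matching bias is
deliberately severity-independent, so the Shift parameters carry no outcome
signal, as is the emulation target for that feature. Age is likewise
independent of severity.

Because the Task Score is a nonlinear composite of a fitted model, the
overall severity scale cannot be set analytically. It is calibrated by
geometric bisection against the supplied normative model using common
random numbers (the same noise draws re-scaled at every candidate), to
within 2 percentage points of the target six-month prevalence (36.1%
default); calibration failure after the iteration budget raises an error
rather than silently accepting a discrepant cohort. `severity_scale` can be
pinned to skip calibration (used for controlled experiments and the
null-severity limit).

Clinical scores are monotone transforms of two-week severity plus
discretised Gaussian noise, clamped to each instrument's legal range:
TLT = ordinal cut of s + noise at (0.35, 0.9, 1.6); BIT = 146 − 20·s + noise
(floor 0, neglect flagged below 130); FIM = 126 − 25·s + noise (floor 18).
Lesions are axis-aligned random ellipsoids on a 40×48×40 grid of 4 mm
voxels (a coarse MNI-like box; the geometry is pure metadata, no
registration exists or is pretended): base radius 10 mm growing 50% per
unit severity with log-normal jitter, centred inside a configurable
critical region with probability σ(−1.5 + 2·s), elsewhere uniformly. This
yields lesion volumes positively correlated with severity and a lesion-
location signal the VLSM stage can recover.

**What the generator does not emulate:** real brain anatomy or vascular
territories, registration error, measurement floor/ceiling artefacts of
the robot, neglect recovery dynamics (BIT < 130 is a flag, not a process),
correlated missingness, or the session-to-session learning effects of real
participants. Passing tests therefore demonstrate that the *analysis chain*
is correct and well calibrated under a plausible data-generating process —
not that the synthetic effect sizes equal the real cohort's.

## Lesion features

Lesion volume is voxel count × voxel volume, reported in cc. The VLSM map
compares the behavioural score (the two-week Task Score, matching the
feature's intended use for early prediction) between lesioned and
non-lesioned participants at every voxel lesioned in at least
⌈5% × n⌉ participants (7 at n = 133) with ≥2 participants per group. The
default statistic is the pooled-variance two-sample t mapped to z through
the normal quantile of the t CDF (sign positive when the lesioned group
scores worse); a rank-sum alternative (normal approximation with tie
correction) sits behind `test="ranksum"`. |z| is capped at 8.2 where the
normal quantile saturates numerically.

VLSM mean Z averages the map over a participant's lesioned *tested* voxels;
lesions touching no tested voxel yield 0 with an explicit flag. Computing
the map on the same cohort whose outcome it later helps predict is the
field's convention and is reproduced here; a leave-one-out mode
(`vlsm_leave_one_out`) that rebuilds the map without each participant is
provided as an extension, off by default.

## Statistics battery

Associations with the continuous six-month Task Score use OLS (plain and
adjusted R² both reported — published values of near-zero effects are
sometimes adjusted R², which can be negative), Spearman's rho for the
ordinal TLT, and pooled-variance t-tests for the binary demographics.
Group differences (impaired vs. unimpaired at six months) use Mann-Whitney
U over 14 features (age, TLT, BIT, FIM, lesion volume, VLSM mean Z, eight
robotic z-scores; sex and affected arm are categorical and excluded) at the
Bonferroni-adjusted alpha 0.05/14 = 0.00357. Student's pooled t (not
Welch) is used deliberately, matching the classical "two-sample t-test"
reading. Mann-Whitney p-values are exact (exhaustive tie-aware permutation)
for pooled n ≤ 14 — the normal approximation's mid-range error exceeds 0.02
at those sizes no matter the continuity handling — and continuity- and
tie-corrected asymptotic above.

## Outcome models

Five configurations, all containing the demographic base: Basic (age, sex,
affected arm), Clinical (+TLT, BIT, FIM), Imaging (+VLSM mean Z, lesion
volume), Robotic (+ the eight parameter z-scores at two weeks), Augmented
(all 16 features). Sex is coded female = 1 and affected arm left = 1 by
default; both encodings are configurable because coefficient signs are
only interpretable relative to them.

Fits are plain maximum-likelihood logistic regressions on z-standardised
features (an optional ridge mode exists but is excluded from AIC, whose
likelihood semantics a penalty would break). Evaluation is stratified
10-fold cross-validation with standardisation learned inside each training
fold; out-of-fold probabilities are pooled before computing metrics
(single reported values, no fold dispersion), classes use a 0.5 threshold,
AUC is the trapezoidal/midrank ROC area, and AIC = 2(p+1) − 2·logLik from
one unpenalised full-data fit (p features + intercept), since AIC is
undefined per fold. Feature importance ranks the standardised coefficients
of the full-data fit by absolute value. Rank-deficient designs are
rejected; non-convergence (the usual symptom of separation in unpenalised
fits) raises a warning naming the configuration.

## Numerical and reproducibility choices

* Every stochastic stage derives from one run seed; identical
  configuration ⇒ byte-identical outputs, verified via the SHA-256
  manifest the report stage writes. NIfTI outputs are gzip-deterministic.
* Box-Cox domain violations at scoring time clamp to a 10⁻⁹ floor and
  flag, never crash.
* The calibration bisection brackets the severity scale in [0.02, 40] and
  accepts only within 5 percentage points of the target (2 within the
  iteration budget).
* Test and example cohorts are scaled to desk size (hundreds of controls,
  133–500 stroke participants, 20-seed Monte-Carlo loops), the package's
  chosen problem sizes for routine verification; every size is a config
  field, so larger studies are a parameter change.

## Known limitations

* The APM parameter formulas are reconstructions from their standard
  descriptions; proprietary implementations may differ (e.g. whether
  contraction/expansion also uses an XY area term — only per-axis values
  are consumed here).
* The zeta/Task Score chain is a reconstruction with the defining property
  (95% of controls below 1.96) built in, not a port of any vendor code.
* The VLSM statistic underlying published mean-Z features is toolbox-
  dependent; pooled t → z is the default here with rank-sum as the
  alternative, and no family-wise error correction is applied because the
  map serves as a feature source, not an inferential endpoint.
* Synthetic severity couplings are plausible but invented; absolute
  classifier metrics on synthetic cohorts characterise the pipeline, not
  any real population.
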
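# Methods

This note documents the models, defaults, numerical choices, and known
limitations of the package. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Trial mechanics

A trial is a fixed phase schedule: baseline `[0, 5000)` ms, transition
`[5000, 8000)` ms, contingent `[8000, t_stop)` ms, disruption
`[t_stop, t_stop + 5000)` ms, with `t_stop ≤ 38000` ms. The cover is a grid
of square cells (default 25 px); cells clipped by the right/bottom screen
edge are smaller, and the uncovered fraction is always area-weighted.
During the contingent phase each *valid, on-screen raw sample* clears the
cell containing it — uncovering is driven by gaze points, not by detected
fixations, and is idempotent. The stop rule is evaluated per sample: the
phase ends at the timestamp of the first sample whose uncovering pushes
the fraction to the stop bound (default 0.20), with no sub-sample
interpolation, else at the 30-s cap. Gaze during baseline, transition, and
disruption never changes the cover. A config hook `uncover_radius_cells`
(default 0) optionally clears a Chebyshev neighborhood per sample; the
default reflects the minimal reading of one square per gaze point.

## Fixation detection

Dispersion-duration (I-DT family) detection: a window opens at a valid
sample and grows greedily; a valid candidate joins only if, after updating
the centroid (running mean of valid members), every member lies within the
dispersion radius (default 25 px, Euclidean) of it. The first candidate
that would break the radius closes the window with no backtracking.
Duration is offset minus onset and must *strictly* exceed the threshold
(default 200 ms). Runs of at most `max_gap_samples` invalid samples
(default 2, ≈17 ms at 120 Hz) are bridged inside a window — a blink
tolerance the detection rule itself does not fix, exposed in config;
longer runs close the window at its last valid member. Emitted fixations
are disjoint and ordered; when a closed window is too short the search
resumes one sample after its start. `detect_fixations_oracle` recomputes
the identical definition by exhaustive window checking with from-scratch
means (pure Python, O(n³)); the test suite and the acceptance script
require exact agreement on seeded random-walk traces.

Fixations are detected on the whole trial trace and may straddle phase
boundaries; each phase receives the clipped within-phase portion of the
duration.

## AOI geometry

The screen is partitioned into four corner quadrants by one vertical and
one horizontal split line; rectangles are half-open so the partition is
exact. With split lines at `(1/2 + a)·W` and `(1/2 + b)·H` the two
diagonal object quadrants cover the fraction `1/2 + 2ab` of the screen;
offsets are equal in magnitude (`|a| = |b| = sqrt(|f − 1/2| / 2)`) and the
rise layout mirrors the drop layout across the vertical midline. The
default object-area fraction is 0.5572; the exact pixel geometry that
produced that number in the original apparatus is not published, so the
fraction is a config knob realized by this symmetric construction. Split
lines are continuous (float) coordinates: integer-pixel lines cannot hit
an arbitrary fraction to the 1e-6 tolerance the layout contract promises.
Object boxes default to squares of 15% screen height centered in their
quadrants.

## Differential looking scores

`DLS = (T_obj − T_nonobj) / (T_obj + T_nonobj)`, fixation membership by
centroid quadrant, undefined (NaN) when the denominator is zero; NaN
trials drop out of condition means rather than contributing zero. Note the
calibration consequence: 0 means equal *time per quadrant*; spatially
uniform-by-area looking has expectation `2·f − 1` (≈ 0.1144 at f = 0.5572),
which the acceptance script verifies by Monte Carlo.

The split-half scores cut the *realized* contingent window (onset to the
realized `t_stop`) at its midpoint, not the nominal 30-s window. The
exploratory disruption score subtracts from `T_obj` the time of fixations
whose centroid lies on an uncovered part of an object rectangle at
disruption onset; the denominator keeps the raw total by default (so the
exploratory score is bounded above by the standard one), with a config
switch (`exploratory_denominator_excludes_visible`) to remove it from the
denominator as well — the verbal definition admits both readings.

Exclusion rules, applied per trial: baseline on-screen looking < 1 s
excludes the whole trial; the contingent and disruption phases are kept
only for engaged trials (contingent looking ≥ 10 s *or* the 20% stop
reached) — read literally the rule would discard exactly the engaged
trials, so the evident intent is implemented and flagged here; the
disruption phase additionally requires at least one fixation. Subjects are
aggregated as the unweighted mean of their two condition means (drop/rise),
which balances unequal trial counts; a subject is retained when each
condition keeps at least two trials that survived the whole-trial baseline
rule (the count deliberately uses "contributed" trials, since the
subject-level rule in the study design predates phase-specific exclusions).

## Bayesian layer

**JZS one-sample BF.** Cauchy(0, r) prior on the standardized effect,
r = 0.707 by default (the conventional default scale; the source design
only states that an uninformed default prior was used — exposed in
config). The marginal likelihood integrates the noncentral-t density of
the observed t statistic over the prior (`scipy.integrate.quad`);
one-sided tests truncate and renormalize the *prior* (not the posterior).
Deterministic; validated against an independent g-marginalization
quadrature and against `pingouin.bayesfactor_ttest` to ~1e-11 relative.

**Rank-based one-sample BF.** A nonparametric analogue of the Wilcoxon
signed-rank test: observations enter only through signs and ranks of
absolute values (zeros dropped); latent Gaussian scores constrained to
those signed ranks are Gibbs-sampled jointly with the effect δ under the
same Cauchy prior (scale mixture of normals). BF10 is the Savage–Dickey
ratio at δ = 0 with a Rao-Blackwellized posterior ordinate; one-sided
factors reweight by the posterior mass on the requested side. Defaults: 2
chains × 5000 iterations, 1000 burn-in, all seeded. Two numerical choices
matter here:

* when every sign agrees the rank data carry only the sign pattern, the
  likelihood in δ flattens above a threshold and the posterior inherits the
  prior's Cauchy tail; a Metropolis *joint translation move* with
  Cauchy-tailed proposals (shift all latents and δ together — the Gaussian
  likelihood terms cancel) is interleaved with the single-site updates,
  without which the latent level mixes by a slow random walk;
* the convergence diagnostic is the rank-normalized split-R̂ (robust to
  those heavy tails; cross-checked against `arviz.rhat`), threshold 1.1;
  failing results are returned flagged (`converged=False`) with a warning,
  never silently.

For all-positive samples the marginal likelihood has the closed form
`Φ(δ)^n / n!`, giving an exact quadrature oracle the tests compare the
sampler against on the log10 scale. In the extreme-evidence regime the
Savage–Dickey estimate is noisy across seeds (the posterior ordinate at
zero is vanishingly small); evidence *categories* are stable.

**Kendall tau-b BF.** tau-b with tie correction (scipy), asymptotic normal
sampling distribution with null variance `2(2n+5)/(9n(n−1))`, stretched
Beta(1/κ, 1/κ) prior on τ over [−1, 1] (uniform at the default κ = 1),
posterior normalized on an 8001-point grid, Savage–Dickey at τ = 0.
Deterministic. Digit-level parity with GUI implementations that use exact
rank-statistic distributions is out of scope; calibration (null median
BF < 1, strong evidence under monotone association) is what the tests pin.

**Sequential design.** Monitoring starts at n_min = 30; the first BF10 at
or beyond 3 (or at or below 1/3) stops the stream; data after the stop
never affect the decision. `design_simulation` draws seeded cohorts
(default N(effect, 1) subject scores, JZS directed test) and reports stop
probabilities and mean stopping n.

The repeated-measures Bayesian ANOVA of the original analysis chain is
deliberately replaced by the three post-hoc paired JZS comparisons
(baseline/contingent, contingent/disruption, baseline/disruption); the
omnibus model is a known limitation.

## Synthetic cohort

The generator emits alternating fixation/saccade event streams sampled at
120 Hz over the full nominal 43-s trial. Each fixation targets the union
of the object quadrants with a phase-specific probability p, else the
complement; the target point is uniform within the chosen region inset by
6 px (so ≤5 px jitter cannot flip its quadrant), samples are jittered and
dropped i.i.d. (default 10%). Defaults encode the qualitative effect
structure of the paradigm: baseline bias 0.64, contingent ramp 0.55 → 0.65
(linear in nominal phase time), disruption 0.60, ages uniform over
180–320 days with a disruption-bias slope of 8e-4 per day around the
cohort midpoint. Fixation durations are log-normal (median 300 ms,
σ = 0.5) and saccades 50 ms — plausible infant values, unconstrained by
published numbers, configurable.

Because fixation durations are i.i.d. and independent of the target, a
phase with constant bias p has `E[DLS] = 2p − 1` exactly under centroid
classification. Two deviations are worth knowing:

* *Detection-level absorption bias*: when consecutive fixation targets
  fall within the dispersion radius the detector merges them, absorbing
  the intervening saccade time into that region's looking time; close
  same-region pairs are more frequent in whichever region draws more
  fixations, inflating |group DLS| by roughly 0.02–0.03 at p = 0.8.
  Recovery tests therefore allow 0.05 absolute error rather than pure
  Monte-Carlo error.
* *Realized vs nominal phases*: the generator ramps p over the nominal
  30-s contingent window, but the simulator may stop earlier (20%
  uncovered), in which case early-disruption fixations were generated
  under late-ramp biases. The real experiment has the same property — an
  infant's generative "policy" does not know the stop time in advance.

What the generator does **not** emulate: sustained inattention or
off-screen looking episodes (so attentive default cohorts produce
near-zero exclusion rates and the exclusion engine is exercised by
constructed fixtures), calibration drift, head movement, smooth pursuit,
and saccade kinematics beyond linear interpolation. Passing tests
demonstrate pipeline correctness and calibration under this model, not
that real infant data would yield the same numbers.

## Problem sizes and determinism

The acceptance script runs a study-scale synthetic pipeline (45 subjects ×
16 trials), 30 trials per bias level for recovery, 100 traces for
detector/oracle agreement, 2000 fixations for the uniform-gaze
calibration, and 500 replicates for the null sequential design — sizes
chosen so the whole script completes in minutes on one CPU while keeping
Monte-Carlo error well inside the asserted tolerances. Every random step
derives from the single `--seed`; re-running a pipeline with the same
config and seed reproduces all CSV outputs byte for byte.
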
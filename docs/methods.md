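# Methods

`pulsebp` re-creates, end to end, a beat-to-beat cuffless blood-pressure
analysis: time-aligned ECG, PPG and continuous arterial-pressure (ABP)
waveforms are reduced to one feature row per cardiac cycle, and an
interpretable rule-ensemble regression maps the hemodynamic features to
per-beat SBP/DBP/MBP, with importance and interaction diagnostics. Because
no recordings of this kind are publicly deposited, the package ships a
synthetic signal generator whose ground truth makes every stage testable.
This note records the models, the tunable parameters, and the design
choices made where the design was genuinely open.

## 1. Synthetic cardiovascular sessions (`synthetic_data`)

A session emulates a 2-minute recording at 1000 Hz from an adolescent
subject (ages drawn uniformly on 13–18 y), at rest or during an isometric
weight-bearing test (WBT) that evokes a pressor response.

**Beat sequence.** RR intervals follow a stationary AR(1) process,
`rr_i − µ = 0.8 (rr_{i−1} − µ) + ε_i`, with resting mean µ = 0.75 s and
stationary SD 0.03 s; the WBT shifts µ by −0.10 s. The AR coefficient 0.8
gives realistic short-range heart-period correlation with one tunable
parameter. Per beat, the pulse arrival time (PAT) is N(0.25 s, 0.02 s)
(WBT: mean −0.02 s), the pulse amplitude AM is N(2.8, 0.2) in normalized
units, and an i.i.d. N(0, 1) `distractor` covariate is drawn that the BP
law never uses (a known negative control for the interaction screen).

**Generative BP law.** Per beat,

```
SBP = a0 + a1/PAT + a2·AM + a3·RR + a4·1{PAT < τ}·AM + ε,   ε ~ N(0, σ)
```

with defaults a1 = 6 mmHg·s, a2 = 5 mmHg, a3 = −10 mmHg/s, a4 = 2 mmHg,
τ = 0.25 s, σ = 2 mmHg; DBP uses the same form with smaller weights
(3, 2, −5, 0.8) and σ = 1.5 mmHg. The intercept a0 is anchored so that the
subject's baseline pressure is reproduced at the reference operating point
(PAT 0.25 s, AM 2.8, RR 0.75 s, interaction active half the time). The
1/PAT term encodes the standard inverse arrival-time–pressure relation;
the threshold interaction makes the law non-additive in (PAT, AM) so the
rule ensemble has real structure to recover. WBT adds +8.1/+4.7 mmHg to
the SBP/DBP intercepts; combined with the PAT and RR shifts the net state
effect is ≈ +11 mmHg SBP and ≈ +6 mmHg DBP, matching the pressor response
scale reported for this manoeuvre.

**Waveforms.** ECG beats are Gaussian lobes (P, R, T) with a dominant 8-ms
R spike. PPG pulses are the classic two-lobe synthesis — a systolic
Gaussian (peak 90 ms after the foot) plus a reflected lobe at 300 ms that
produces the dicrotic notch and diastolic peak — **plus a narrow negative
"foot dip" centred on the onset**. The dip gives the pulse foot a sharply
curved, well-localized minimum; without it the inter-beat valley of a
lobe-only synthesis is numerically flat and no detector could locate the
onset to ±2 ms, which is the accuracy contract of this pipeline. The ABP
wave is built per beat as a half-cosine systolic rise from exactly DBP (at
the foot) to exactly SBP (at the peak, 120 ms later) followed by a
normalized-exponential diastolic runoff that lands exactly on the *next*
beat's DBP, with a small dicrotic bump on the decay. Landing on the next
foot keeps the waveform continuous, so every foot is a genuine local
minimum even when consecutive DBPs differ by many mmHg. Additive white
noise: 0.01 (ECG and PPG, signal units), 0.08 mmHg (ABP).

Truth annotations (onset, systolic peak, notch, diastolic peak) are read
numerically off the *clean* rendered waveform before noise is added, so
the annotations and the signal can never disagree; `true_pat`, `amplitude`
and `rr` in the truth table are exactly the values the law consumed, which
is what makes noiseless coefficient recovery exact to 1e−6.

**Artifacts.** `flat_line` freezes a channel at its value at the interval
start; `flat_peak` clips samples above a window quantile (saturation). The
recorded exclusion interval is the span actually corrupted — for clipping,
the merged span of clipped samples (gaps < 50 ms bridged; spans < 50 ms
are noise-scale nicks and are not recorded).

**What the generator does not emulate:** respiratory and baroreflex
modulation, pulse-morphology drift, motion artifacts other than the two
flat classes, electrode/sensor transfer functions, and arrhythmias.
Passing tests therefore demonstrate the *pipeline's* correctness and the
estimator's recovery properties under the stated law — not performance on
real recordings, where morphology variability and the true (unknown)
feature→BP relation will dominate.

## 2. Preprocessing (`preprocess`)

ECG: 0.5–30 Hz; PPG: 0.5–15 Hz; both 4th-order Butterworth applied
forward–backward (zero phase, so pulse-arrival timings are unbiased).
The ABP channel is never filtered (filtering biases pressure extrema).
PPG is additionally smoothed with a centred moving average, default
**15 ms**, and z-scored (population SD) per recording segment,
normalization after filtering (order configurable). The smoothing window
sits well below the narrowest contour feature (crest time ≈ 90 ms); wider
boxcars (≥ 50 ms) measurably displace the foot minimum on the asymmetric
inter-beat valley and were rejected for that reason.

## 3. Fiducial detection (`fiducials`)

R peaks: Shannon-energy envelope of the normalized differentiated ECG,
smoothed 50 ms, peak-picked with a 200-ms refractory period, each
detection refined to the local ECG maximum. Within each R–R window the
PPG landmarks are, in order: max-upslope = maximum of the smoothed first
derivative; onset = signal minimum preceding it; systolic peak = first
local maximum after it; dicrotic notch = the post-systolic local minimum
closest to the e-wave of the second derivative, accepted only if followed
by a diastolic rebound of ≥ 2 % of the pulse amplitude (this rejects noise
wiggles on notch-free, monotone-decay pulses); diastolic peak = the
rebound maximum. The a–e waves are alternating extrema of the second
derivative over the systolic phase (a = its largest maximum); p1/p2 are
the first two zero-crossing-delimited maxima of the third derivative.
Derivatives are smoothed central differences (11-ms re-smoothing after
each differentiation). Beats with unresolvable landmarks are emitted with
absent fields and a `missing_landmark` flag — they become NaN rows and are
dropped by the cleaning step, never silently discarded. ABP foot/peak:
the systolic upstroke is located as the maximum slope before the wave
peak, the foot is the minimum in the 150 ms preceding it (pre-upstroke
minimum; a window-global minimum is wrong whenever the previous beat's
pressure was lower), the peak is the maximum after the foot.

Flat-artifact detection: runs of ≥ `min_run` (default 0.2 s) with zero
first difference, equal-level runs bridged across < 50 ms gaps. A run is
labelled `flat_peak` if it is a plateau local maximum (above its 30-ms
flanks) at or above the 0.5 quantile of its ±0.5 s neighbourhood,
otherwise `flat_line`; for a freeze at an arbitrary waveform phase the
label is best-effort, the interval itself is always reported.

## 4. Feature table and cleaning (`features`)

One row per cycle: PAT from R to onset/max-slope/systolic peak/diastolic
peak (`oPAT, msPAT, pPAT, diaPAT`), RR-relative versions (`RoPAT, RpPAT` =
PAT/RR — the only dimensionless per-beat normalization available), pulse
wave velocities `xPWV` = arterial path length / `xPAT` with path length
defaulting to 0.5·height (heart-to-finger approximation), amplitude `AM`,
crest time `cT`, onset-to-onset `dO` and peak-to-peak `dP` intervals,
contour descriptors (`AM25` = width at 25 % amplitude, `DA` = diastolic
amplitude ratio, `slope_BC` = mean second-derivative slope between the b
and c waves — provisional definitions isolated behind one function),
demographics (age, height, weight, BMI), and targets SBP, DBP,
MBP = (SBP + 2·DBP)/3.

Cleaning: (1) drop any row with a missing value; (2) one pass of
per-column z-scoring (sample SD, ddof = 1) on the post-step-1 table,
dropping rows with any |z| > 3. Z-scores are computed within
subject-and-state groups by default (state-level statistics are the
physiologically homogeneous unit); pooled cleaning is a config switch.
Constant columns are skipped. Both steps are logged in the provenance.
The two dispersion conventions are deliberate: signal normalization uses
the population SD, table cleaning the sample SD.

## 5. Rule-ensemble regression (`rulefit`)

Candidate **rules** come from gradient boosting on squared loss
(`n_trees` = 300, shrinkage 0.01, row subsample 0.5 without replacement):
each step fits a small regression tree to the current residuals, with
terminal-node count drawn as 2 + floor(Exponential) scaled so the mean is
`tree_size_mean` = 3 (minimum 2) — small trees keep rules short while
allowing pairwise and occasional deeper interactions. Every non-root node
contributes the conjunction of split conditions on its root path;
duplicate rules are removed and supports s_k computed on the full training
data. Candidate **linear terms** are winsorized at the 0.025/0.975
empirical quantiles (linear interpolation between order statistics — the
one quantile convention used everywhere).

The final model is an L1-penalized least-squares fit over
[rule indicators | winsorized linears], columns standardized internally,
coefficients reported on the original term scale. The penalty is chosen on
the training split only, by 5-fold cross-validation over a 30-point
log-spaced grid from the data-driven α_max down to 3·10⁻³·α_max, computed
with warm-started coordinate-descent paths; α = 0 falls back to exact
least squares (this is the oracle route the tests compare against the
normal equations). Modes: `linear_only`, `rules_only` (trees forced to
stumps → single-variable rules → a purely additive model), and
`rules_plus_linear`.

Diagnostics. Term importance: |a_k|·√(s_k(1−s_k)) for a rule,
|b_j|·sd(l_j) for a linear term (a constant column has sd 0 and hence zero
importance regardless of its coefficient). Variable importance: the
linear-term importance plus an equal share of every containing rule's
importance, scaled so the top variable reads 100. Partial dependence:
mean prediction over training rows with the variable(s) clamped to decile
grid values. Interaction strength: the Friedman–Popescu statistic

```
H_j² = Σ_i [F(x_i) − PD_j(x_ij) − PD_−j(x_i,−j)]² / Σ_i F(x_i)²
```

with all functions centred, evaluated on a 200-row subsample (an n×n
prediction matrix yields both partial-dependence functions at once),
clipped to [0, 1]. Because H_j is biased upward by finite samples and
lasso noise, it is referenced against a null distribution: an additive
surrogate (stump-rules main-effects model) generates 20 datasets as
surrogate predictions + resampled residuals, the full model is refit on
each, and H_j recomputed; a variable is flagged when its observed H
exceeds null mean + 2 SD (the recovery tests use the stricter 3-SD bar).
If the fitted model contains no multi-variable rule with a non-zero
coefficient, all H_j are exactly 0 and the null is skipped.

## 6. Evaluation (`evaluation`)

MAE and RMSE are computed over *pooled* held-out predictions of a seeded,
shuffled k-fold split (k = 10) — pooling, not averaging per-fold metrics,
is asserted by a test on unequal folds. Each training fold re-runs the
full fit including internal penalty selection. Folds are over beats by
default; subject-grouped folding is available (`fold_policy = "subject"`)
and materially harder, since it removes within-subject information from
training — beat-level folding is the default because errors of a few mmHg
are only achievable with within-subject calibration data. The
model-comparison report runs all three modes and emits held-out and
training-refit metrics side by side, with both the non-zero and candidate
term counts.

The rest-vs-WBT comparison collapses beats to per-subject means per state
(the subject is the pairing unit), then applies the exact two-sided
Wilcoxon signed-rank test to the paired differences, dropping zero
differences. With six subjects the normal approximation is invalid; the
exact null is enumerable (2⁶ sign patterns) and the tests verify the
implementation against full enumeration up to n = 10.

## 7. Pipeline and reproducibility (`cli`)

A TOML config with full defaults drives `synth → extract → fit →
evaluate`; every stage is callable alone on the previous stage's files and
the staged path is byte-identical to `run` (asserted in tests). All
randomness flows from the single config seed; the run log records the
fully-resolved config. Default study sizes in the bundled configuration
(2 subjects × 2 states × 2 min; model comparison for DBP at rest) keep a
default run on one CPU core in the minutes range; the full 3-target ×
2-state grid is a config change.

## 8. Numerical choices and degenerate inputs

Zero-variance signals raise a degenerate-signal error from z-scoring;
constant feature columns are skipped by the outlier pass and receive zero
importance; beats shorter than 250 ms are flagged, not processed; an
all-zero difference vector gives p = 1; α → ∞ collapses the model to the
intercept = mean(y); empty artifact windows warn and are ignored. Ties in
the importance ranking break deterministically by term identifier. Seeds
derived internally stay below 2³¹.

## 9. Known limitations

The synthetic law is a convenient stand-in, not a validated hemodynamic
model; absolute error levels on synthetic data say nothing about clinical
accuracy. The contour-descriptor definitions (`AM25`, `DA`, `slope_BC`)
are provisional and isolated for replacement. The flat-run classifier's
label (not its interval) can be wrong for freezes at high waveform phases.
H-statistic nulls are parametric-bootstrap approximations; with few null
replicates the flag threshold is itself noisy, which is why the negative
control (distractor) is part of the recovery tests.
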
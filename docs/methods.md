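# Methods

## Signal model and preprocessing

The navigator stream of one scan is a complex matrix `s_j(i)` (channel `j`,
TR `i`). Raw input is one 64-sample, 0.2 ms ADC readout per excitation; the
middle 32 samples are averaged (the leading/trailing quarters carry ADC
electronics transients), readouts of one echo train are averaged into a
single complex value per channel and TR, and the first 3 TRs are discarded
while the magnetization approaches steady state. Averaging stays complex
throughout; magnitudes are taken only where a metric requires them.

The reference vector for the Δref metric is the per-channel mean of the
*first 3 retained* TRs. Taking the reference inside the discarded transient
would contaminate it with the approach to steady state, so the discard and
reference windows do not overlap; both counts (`n_discard`, `n_ref`,
default 3 each) are parameters.

## Motion metrics

All four metrics are defined for TR `i ≥ 2` and stored with an explicit
start index (no zero padding), so integrators know a trace of `n` steps
contributes `n − 1` terms.

* Δref, Δ: mean over channels of `|s_j(i) − s_j(r)| / |s_j(r)|` with `r` the
  reference vector or the previous TR. These are complex-difference
  magnitudes: a pure phase rotation of a channel registers as motion.
* Δmax: magnitude-domain change `||s_j(i)| − |s_j(i−1)|| / |s_j(i−1)|`,
  averaged over the 3 largest channels, re-selected each TR. The
  magnitude-domain reading (as opposed to the complex difference of Δ) is
  deliberate: the channel-ranking step needs a quantity that is monotone in
  per-channel signal change, and the same quantity is then averaged. With
  fewer channels than `top_k` the mean runs over all channels (with a
  warning) rather than failing.
* CCC: `1 − r` with `r` the sample Pearson correlation across channels
  between `|s(i)|` and `|s(i−1)|` (N_c − 1 normalization); range [0, 2].
  A zero-variance magnitude vector leaves `r` undefined; those TRs return 0
  ("no detectable load redistribution") with a warning instead of NaN.

Denominators are guarded by a floor of `1e-12 × max |s|`; a channel below it
raises a degenerate-reference error naming the channel rather than silently
producing infinities.

All four metrics are invariant to a global positive gain, which is verified
end-to-end (scaling the simulated coil sensitivities leaves every trace
unchanged to 1e-9 relative).

## Integration and k-space weighting

`score = 1/(n·TR) Σ metricᵢ`, with `n` the number of outer phase-encoding
steps. `n` is identified with the number of retained TRs: the emulated
acquisition encodes one outer phase-encode plane per TR, so the i-th metric
sample aligns with the i-th acquired plane in acquisition order (linear
ordering, k-space center mid-scan). The weighted variant multiplies each term
by `w_i`, the relative energy (Euclidean norm) of the plane acquired at step
`i`, averaged over reference subjects. Weights are normalized to unit mean —
a normalization chosen here so weighted and unweighted scores share a scale
(with a constant metric trace they coincide); zero-weight vectors are
representable for testing via `normalized=False`. CCC scores are reported
×100 by convention (`report_scale`); all computation is on the natural scale.

A packaged analytic weighting (Gaussian bump on a flat baseline,
peak-to-periphery ≈ 4, unit mean) is provided for users with navigator CSVs
but no reference k-space; the simulator derives its own weighting from the
noiseless phantom k-space, interpolated from grid planes to acquisition
steps.

## Detection statistics

Grades are dichotomized either 1–2 vs 3–5 (non-diagnostic) or 1–3 vs 4–5
(impaired); a positive case is a motion-corrupted scan, called when
`score ≥ c` (non-strict, so the maximum observed score stays detectable).
ROC candidate thresholds are the sorted unique scores plus a `+∞` sentinel;
AUC is the trapezoid over (1−SP, SE) with FPR ties ordered by SE, which makes
it exactly the tie-corrected Mann–Whitney statistic (property-tested against
`scipy.stats.mannwhitneyu` and `sklearn.roc_auc_score`). Youden's
`J = SE + SP − 1` is maximized over candidates with ties broken toward the
smaller threshold (higher sensitivity).

The 0.632 bootstrap draws `b` replicates of size N with replacement,
re-derives the Youden threshold per replicate, and blends resubstitution and
out-of-bag accuracy as `0.368·Acc_r + 0.632·Acc_h`, separately for SE and SP;
AUC and J are reported as replicate mean ± SD. Replicates with a
single-class in-bag or out-of-bag set are redrawn (and counted). Replicate
RNG streams are spawned from the seed by counter-based splitting
(`SeedSequence.spawn`), so results are independent of execution order. The
constants are implemented as printed (0.368/0.632), not 1/e. The single
reported threshold is the full-sample Youden threshold — the only
reproducible choice.

Note a structural property of this estimator: with any nonzero within-class
spread the blended SE is strictly below 1 even for perfectly separable
classes, because the replicate threshold sits at the replicate's minimum
positive score and an out-of-bag positive can fall just below it.

Spearman correlation uses `scipy.stats.spearmanr` (average ranks, two-sided
t-approximation p); inter-rater agreement uses Cohen's weighted kappa
(`sklearn`, linear weights by default — the quadratic variant is a flag) with
a 95% subject-level bootstrap CI (2000 replicates, seeded).

## Scan-abort savings model

The running score is the cumulative metric sum scaled by `1/(n·TR)`; its
final element equals the integrated score, and non-negativity of all four
metrics makes it non-decreasing, so the first crossing is unique. At the
first TR `i*` with running score ≥ c, `FA = i*/n` and `FR = 1 − FA`.
Aggregate savings:

    T_savings(%) = 100 · (Σ_TP FR − Σ_FP FA) / (2(nTP + nFN) + nTN + nFP)

The denominator counts *every* non-diagnostic scan at 2·TA in the
no-monitoring baseline (acquisition + repeat), detected or not; the
alternative grouping `2nTP + nFN + nTN + nFP` is available as
`baseline="detected_double"`. Dollar lines use
`cost_per_minute = slot_cost / slot_minutes` (defaults $2828 / 45 min,
TA = 4.2 min): repeat cost = (grade 1–2 count)·TA·rate, net saving =
(minutes saved − minutes wasted)·rate, rounded to whole dollars only at the
report layer. The savings-direct threshold optimizer grid-searches the union
of final integrated scores plus midpoints, breaking ties toward the larger
threshold (fewer false aborts); between those candidates the savings
function can still vary (intermediate running-score values move the crossing
time), so the optimizer is specified — and tested — against that candidate
grid, not a continuum.

## Synthetic cohort

The simulator reproduces only the mechanism the metrics exploit: a
coil-sensitivity-weighted volume integral changing under rigid motion, plus
slow drift, pseudo-periodic fluctuation and complex Gaussian noise. It makes
no attempt at spin history, B0, flip-angle or reconstruction effects, and no
images are synthesized.

* **Phantom**: smoothed ellipsoid (semi-axes 60/75/65 mm) on a 32³ grid at
  6 mm spacing. The coarse grid is deliberate: the navigator is a volume
  integral, so fine spatial detail is irrelevant, and a 102-subject cohort
  generates in ~40 s.
* **Coils**: 32 Gaussian sensitivity profiles (σ = 55 mm) centered on 4
  rings of a 110 mm-radius cylinder with seeded jitter, each with a random
  phase. Opposite coils respond to a lateral shift with opposite-signed
  magnitude changes, which is what gives CCC its sensitivity.
* **Forward model**: `s_j(i) = Σ_x density(T_i⁻¹x)·c_j(x)·e^{iφ_j} + drift +
  fluctuation + ε`, with trilinear resampling (`scipy.ndimage`) of the
  rigidly transformed phantom. Identity poses reuse the base signal, so
  still scans are constant to machine precision and all metrics are exactly
  zero in the noiseless case.
* **Noise defaults**: complex Gaussian SD 5×10⁻⁴ of the mean channel
  magnitude — an FID navigator integrates signal over the whole head, so its
  SNR is in the thousands; drift up to 2×10⁻⁴ per TR per channel (~3% over a
  scan, enough to visibly degrade the reference-based Δref, mirroring its
  known drift sensitivity); sinusoidal fluctuation 10⁻³ at 4 s period
  emulating breathing/swallowing-like confounds.
* **Trajectories**: still; linear drift to a target amplitude; abrupt
  step(s) at event times in the middle half of the scan; and continuous
  restlessness as a mean-reverting random walk (θ = 0.15), which keeps
  excursion and per-TR speed coupled the way a fidgeting subject's do.
  Pose 1 is always identity.
* **Grades**: ground truth is the k-space-weighted mean displacement of six
  reference points 60 mm from the rotation center (so rotations count),
  binned at 0.5 / 1 / 2 / 4 mm into grades 5…1. Each simulated subject's
  trajectory is rescaled so its weighted displacement lands at a seeded
  point in the *central half* of the target grade's bin (sub-mm bins for
  good grades, multi-mm for severe motion — plausible for unsedated
  children, though uncalibrated against real scans). Severe grades (1–2) are
  generated as continuous restlessness — the archetype of severely moving
  children — while abrupt repositioning and slow drift, which genuinely
  produce weaker per-TR signatures than their image impact suggests,
  populate grades 3–4. Trajectories whose rescaling would exceed a 25 mm
  excursion (e.g. an abrupt event in a low-weight region) are resampled.
* **Determinism**: per-subject RNG streams are spawned from the cohort seed;
  the same seed yields byte-identical cohort files.

## What the synthetic results do and do not show

Passing tests demonstrate that the analysis chain — preprocessing, metrics,
integration, threshold selection, bootstrap correction, abort economics — is
internally correct and recovers planted ground truth (default cohorts
separate non-diagnostic from diagnostic CCC scores by ~6 pooled SDs, giving
full-sample AUC ≈ 1 and bootstrap SE ≥ 0.9 / SP ≥ 0.9). They do not certify
clinical performance: real navigator data carry spin-history and B0
confounds, non-rigid motion (swallowing, coughing, arm movement), scanner
drift structure and grade-label noise that the forward model does not
emulate, and real grade/motion relationships are far noisier than planted
bins. Detection numbers on synthetic cohorts are accordingly optimistic
upper bounds, and the simulator's motion-magnitude distribution is a
plausible choice, not a measured one.

## Numerical choices and degenerate inputs

* Denominator floor 1e-12 × max magnitude; violations raise named errors.
* Correlation values are clipped to [−1, 1] before forming `1 − r` to keep
  round-off from leaking outside CCC's range.
* Empty traces, empty cohorts, single-class label vectors, non-monotone
  grade thresholds, mismatched weight lengths and malformed navigator CSVs
  all raise specific exceptions rather than propagating NaN.
* Navigator CSVs round-trip complex values losslessly (`repr` on write,
  `float_precision="round_trip"` on read).
* CSV reports can embed a SHA-256 config hash in a leading comment line.

## Known limitations

* `Δref`'s reference window and the drift model interact: the simulator's
  drift makes Δref degrade gracefully but its absolute values are not
  comparable to clinical ones.
* The abort model replays recorded running scores offline; technologist
  reaction latency, patient recall and anesthesia economics are out of scope.
* The 0.632 bootstrap redraw policy (resample until both classes appear
  in-bag and out-of-bag) mildly biases replicate composition for very small
  positive classes; counts of redraws are reported.
* Slice-wise (2D) navigator variants and per-subject adaptive k-space
  weighting are not implemented.
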
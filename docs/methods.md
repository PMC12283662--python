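# Methods

This note documents the models and procedures implemented in
`strengthsense`, the assumptions behind them, the parameters that matter,
and the design choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A subject performs a seated shoulder-flexion repetition while three
bipolar sEMG channels record the anterior, middle and posterior deltoid
(nominally 10 kHz) and a six-axis IMU on the distal upper arm records
triaxial acceleration and angular rate (100 Hz). A therapist assigns an
MMT strength grade in {2, 3, 4, 5}. The task is to regress the grade from
the recordings. Grades 0–1 are excluded: they produce no reliable
voluntary sEMG. The ordinal grade is treated as a continuous regression
target, as is common in this line of work; the resulting approximation
error is discussed under Limitations.

## Signal conditioning

**Savitzky–Golay denoising.** Each sEMG channel is smoothed by
least-squares polynomial fitting in a sliding window (window 51 samples,
polynomial order 3). This filter preserves peak structure and slope
continuity better than a moving average at comparable noise suppression,
which matters because the downstream amplitude features integrate the
waveform. Edges are mirror-padded by (window−1)/2 samples, so the output
has the input's length and every sample is a genuine centred fit; the
degree-3 reproduction guarantee (any cubic passes through unchanged)
holds at interior samples, and the test suite checks the filter against a
brute-force per-window polynomial regression.

**Channel QC.** A channel fails if (a) its baseline drift — the
peak-to-peak range of the sub-1 Hz trend — exceeds 20% of the channel RMS
(or an absolute limit when configured), or (b) more than 20% of spectral
power lies within ±1 Hz of the mains frequency (50 Hz default, 60 Hz
switchable). The trend is estimated by block-mean decimation to ~20 Hz
followed by a zero-phase 2nd-order Butterworth at 1 Hz. The decimation
step is deliberate: a 1 Hz IIR filter applied directly at kHz rates has a
normalized cutoff near 1e-4, where edge transients of the order of the
signal amplitude dominate the trend estimate (we verified this against an
FFT low-pass oracle); filtering at the decimated rate is the same trend
definition, computed reliably. QC is report-only at the library level;
the pipeline marks trials with failing channels unusable.

## sEMG features

Per channel, over the aligned trial window (one scalar per feature per
channel per trial — no sub-windowing):

* RMS = sqrt(mean(x²)) — amplitude units,
* MAV = mean(|x|) — amplitude units,
* iEMG = Σ|x|/fs — amplitude·seconds, the rectangular-rule integral of
  the rectified signal, so iEMG = MAV × duration by construction,
* MF — the median frequency, in Hz: the point where the cumulative Welch
  PSD (Hann taper, 50% overlap, segment length min(N, 4096)) reaches half
  the total power.

For MF, each PSD bin's power is treated as spread uniformly over its
frequency cell [f−Δf/2, f+Δf/2] and the half-power crossing is
interpolated inside the cell. Interpolating between bin centres instead
biases the estimate by up to half a bin (a pure 50 Hz tone at 10 kHz /
4096-point segments comes out at 48.8 Hz rather than 50.0); the cell
convention removes that bias. Invariants: RMS ≥ MAV (Cauchy–Schwarz),
amplitude features scale linearly and MF is amplitude-invariant, MF is
stable under signal duplication.

## Orientation fusion

Accelerometer inclination (degrees):

    roll_acc  = atan2(a_y, a_z)
    pitch_acc = atan2(−a_x, sqrt(a_y² + a_z²))

with the X axis mounted anteriorly. The complementary filter blends the
propagated previous estimate with the accelerometer angle per step:

    roll  ← K·(roll_prev  + ωx·Δt) + (1−K)·roll_acc
    pitch ← K·(pitch_prev + ωy·Δt) + (1−K)·pitch_acc
    yaw   ← yaw_prev + ωz·Δt

K = 0.4 by default: the gyro term supplies short-term smoothness, the
accelerometer term long-term stability, and the K-weighted recursion
forgets its initial condition geometrically with ratio K. The "gyro
angle" is the previous *fused* estimate propagated by the rate — an
independent pure-gyro integrator would drift unboundedly and defeat the
blend. Yaw has no gravity (or magnetometer) reference and is pure rate
integration; it drifts slowly and is excited in the generator by a small
oscillation so the feature is non-degenerate. Limits K=0 (pure
accelerometer) and K=1 (pure integration) are exact and tested.

Each of the nine IMU channels is reduced to a per-trial scalar: peak
absolute value for acc/gyro, peak absolute excursion from the initial
angle for roll/pitch/yaw. Peak kinematics is the natural strength
correlate for a maximal-effort movement; mean and range are plausible
alternatives and the choice is config-exposed.

## Dataset

21 features = 3 muscles × {RMS, iEMG, MAV, MF} + 9 IMU scalars, in a
fixed documented column order. Normalization is the min–max map
x′ = (x−min)/(max−min) fitted per column **on the training partition
only** and applied to the test partition (whose values may leave [0, 1]);
fitting on all data leaks test information, and a `norm_on_all` flag
reproduces the looser convention for comparison. Labels are not
normalized. Splits are seeded 7:3 by trial (train = floor(0.7·n);
145 → 101/44), unstratified; 5-fold CV partitions are seeded, disjoint
and exhaustive (145 → five folds of 29). Pooled (by-trial) splitting
mirrors the protocol being emulated but lets a subject appear on both
sides of the split, which inflates absolute performance — a caveat for
any real-data use; grouping by subject is the stricter alternative.

## Particle swarm optimizer

Classic inertia-weight PSO, minimization convention:

    v ← ω·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),   x ← x + v

with r1, r2 uniform per particle per dimension, ω = 0.7 (mid value of the
commonly tuned 0.4–0.9 range; config-exposed), positions clipped to the
search box, and velocities clamped to ±v_max with
v_max = 0.2 × (hi − lo) per dimension. The v_max rule is the standard
stabilizer and its size matters: with learning factors c1 = c2 = 4.494
(used by the swarm-initialized network below) the update is outside the
classical stability region, and a full-span clamp leaves particles
teleporting wall-to-wall — a random search that cannot exploit. A 20%
clamp keeps such swarms productive while leaving well-behaved settings
(c1 = c2 = 1.7) unaffected; the fraction is config-exposed. The swarm can
be seeded with known candidate solutions (used by both hybrid trainers);
initial velocities are zero, and the best-so-far trace is non-increasing
by construction.

## Regressors

All four trainers consume normalized features and are seed-deterministic
end to end; `predict` is a pure function of the trained model, and models
serialize to JSON.

**BPNN.** One hidden layer of 5 tanh units, linear output, trained by
full-batch gradient descent on MSE (fixed learning rate 0.01, up to 1000
epochs) from a standard random initialization (N(0, 0.5²)). The
best-seen iterate is kept, so the final training MSE never exceeds the
starting MSE. Plain backprop from a random start is deliberately the
baseline: its sensitivity to initialization is the weakness the hybrid
below addresses.

**SVR.** ε-insensitive support vector regression with an RBF kernel;
C = 10, γ = 0.1, ε = 0.1 by default. The fit is delegated to a standard
QP solver; the test suite cross-checks small instances against an
independent SLSQP solution of the dual and the prediction is computed
from the stored support vectors, dual coefficients and intercept.

**PSO-SVR.** The swarm searches (C, γ) in C ∈ [1, 100], γ ∈ [0.001, 1]
(10 particles, 100 iterations, c1 = c2 = 1.7), scoring each candidate by
five-fold cross-validated RMSE on the training partition, then refits on
the full training partition at the optimum. CV fitness rather than raw
training RMSE is the default because raw training error is minimized by
driving C up and overfitting (`fitness="train"` reproduces the literal
reading). ε is not searched by default. The stock (C, γ) seeds the
swarm when it lies in the box, so the tuned configuration is a minimum
over a set containing the default: under the tuning fitness it can never
be worse.

**PSO-BPNN.** The swarm searches the network's flattened weight vector
(5 particles, 100 iterations, c1 = c2 = 4.494) minimizing training MSE,
and backpropagation fine-tunes from the swarm optimum with the same
monitored descent as the plain network. The search box is ±0.5 for
weights and hidden biases — a few times the 1/sqrt(fan-in) scale; a wider
box (±2 with 21 inputs) saturates the tanh units, flattening both the
fitness landscape and the fine-tune gradients — while the output-bias
dimension spans the label range, since a box that excludes every
well-fitting network makes the global phase useless. The swarm is seeded
with the same random initialization the plain network would use, so the
searched start never trails it.

## Evaluation

Metrics on test predictions: R² = 1 − SS_res/SS_tot, RMSE, MAE, and
MBE = mean(actual − predicted). Note the sign convention: negative MBE
means over-prediction; a flag flips it for the opposite convention.
Identities rmse ≥ mae ≥ |mbe| are property-tested.

The harness repeats the whole protocol (fresh seeded split →
normalization → train all four models on identical partitions → test
metrics) and reports mean ± SD over repeats (SDs are over repeats, not
folds). Model comparison: one-way repeated-measures ANOVA per metric,
implemented from first-principles sums of squares (models as the within
factor, repeats as subjects; no sphericity correction), verified in the
tests against an independent statistics package and against the F = t²
identity for two models; pairwise paired t-tests carry the Bonferroni
multiplier k(k−1)/2 capped at 1; CIs are Student-t over repeats. A single
master seed fans out to per-repeat and per-stage seeds through a
documented splitting scheme, so the full report is bit-reproducible.

## Synthetic-data generator

The generator emulates the acquisition structure — 15 subjects × 10
trials, grades 2–5, 10 kHz sEMG (2 kHz desk-scale option, sufficient for
the 20–450 Hz band) and 100 Hz IMU, 3 s trials, 5 of 150 trials flagged
unusable — with these mechanisms:

* A latent true strength s = grade ± 0.5 (uniform) drives the
  physiology while the label stays at the integer grade. This encodes
  that an ordinal MMT label only coarsely reflects actual strength and is
  the main source of irreducible error; without it the synthetic task is
  nearly noiseless and every model saturates, which no field study of
  this kind achieves.
* sEMG per channel: Gaussian noise band-passed around a
  strength-dependent centre frequency (80→125 Hz across grades, within
  20–450 Hz), scaled by a strength-dependent amplitude gain that
  doubles per grade (sEMG amplitude grows super-linearly with force), a
  per-subject log-normal effect (σ = 0.15), fixed channel gains
  (anterior 1.0, middle 0.8, posterior 0.6 — the anterior deltoid is the
  prime mover in flexion), and a smooth activation envelope peaking
  mid-flexion.
* IMU: a smooth flexion pitch trajectory θ(t) = peak·sin²(πt/T)
  (raise and return), with the peak angle rising with strength and
  saturating toward 90° at the top grades (grades 4 and 5 complete the
  range and differ in resistance tolerated, which range cannot measure).
  The gyro is the analytic derivative plus noise (σ = 1 deg/s); the
  accelerometer is the gravity projection of the instantaneous pitch
  plus noise (σ = 0.02 g); a small yaw-rate oscillation keeps the yaw
  feature non-degenerate. With noise switched off, the accelerometer
  angles recover θ(t) exactly and the K = 0.4 fused pitch tracks it
  within 2° after the transient — a tested round trip.

What the generator does **not** emulate: motor-unit physiology
(recruitment, firing statistics, MUAP shapes), fatigue dynamics within or
across trials, co-contraction or compensatory trunk motion, electrode
placement variability, and any real device's noise spectra. Passing tests
therefore demonstrate that the pipeline recovers a monotone,
moderately noisy grade signal of realistic strength from correctly
structured multimodal data — not that it meets any performance bar on
clinical recordings.

## Numerical choices and degenerate inputs

* Degenerate (constant) feature columns normalize to 0 with a warning.
* An all-zero signal has no median frequency (error), and R² is
  undefined for constant actuals (error).
* Non-finite fitness values reject the candidate (pbest unchanged)
  rather than poisoning the swarm.
* Trial CSVs are written at full precision (%.17g) and parsed in
  round-trip mode, making write∘read the identity.
* Streams are aligned by interval intersection on the shared clock;
  overlaps under 0.5 s are rejected as clock faults (a flexion takes
  seconds). sEMG is never resampled to the IMU rate — features are
  computed per stream.

## Problem sizes

The test suite and the acceptance script run the full study at the
2 kHz desk-scale sEMG rate (Nyquist-sufficient for the signal band):
150 simulated trials, a 145 × 21 table, 10 repeated splits of the
four-model protocol, and a five-seed median for the headline PSO-SVR
fit. Unit tests use a 4 × 5-trial study at 1 kHz.

## Limitations

* Grade is modelled as a continuous target; ordinal-aware models are out
  of scope.
* Pooled trial splits inflate absolute metrics relative to
  subject-held-out evaluation (flag available).
* Yaw drifts without a magnetometer; its feature is an excursion over a
  3 s window, where drift is negligible.
* The RM-ANOVA applies no sphericity correction.
* Synthetic results transfer to real recordings only in the qualitative
  sense described above.
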
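# Methods

This note documents the models, parameter choices and numerical
conventions behind `slipsynergy`, and what the synthetic-data validation
does and does not demonstrate.

## Signal model and preprocessing

Surface EMG is treated as a non-negative linear envelope modulating a
zero-mean broadband carrier. The envelope chain is: zero-phase (dual-pass)
Butterworth high-pass, order 2 per pass, at **35 Hz**; full-wave
rectification; zero-phase Butterworth low-pass, order 2 per pass, at
**40 Hz**. "Order 2, dual-pass" means an order-2 design applied forward
and backward (effective order 4, zero phase) — standard EMG practice that
avoids latency bias in onset estimates. Low-pass ringing can produce small
negative excursions; these are clipped to zero because the factorization
requires non-negativity, and a test asserts the clipped mass stays below
1% of the total on generator output.

The analysis window runs from 100 ms before belt onset (BON) to 100 ms
after recovery-foot touchdown (TD), start-inclusive / end-exclusive in
samples. Envelopes are averaged into **10 ms bins** (a sample belongs to
the bin its start time falls in; the trailing partial bin is dropped, not
padded, to avoid a biased last bin). The two trials of a stage are
concatenated end-to-end. Each muscle row is divided by its maximum
activation over **all ten trials of the session** (shared factors keep the
early and late stages on one scale; per-stage factors can be passed
instead), then scaled to unit sample variance (n−1 denominator) so every
muscle weighs equally in the factorization; the variance divisors are
stored and removed from the synergy vectors afterwards.

## Synergy extraction

Lee–Seung multiplicative updates minimize ‖M − WC‖²_F with a 1e-12 floor
on the factors (prevents absorbing zeros, keeps updates well-defined).
Defaults: 20 uniform-random restarts (best residual wins), at most 2000
iterations, convergence when the relative objective decrease falls below
1e-6. Every restart draws from an independent substream of one seeded
generator, so results are bit-reproducible given the seed. A debug flag
asserts the objective is non-increasing at every update.

VAF is **uncentered**: 100·(1 − ‖M − WC‖²/‖M‖²), globally and per muscle
row — the convention of the muscle-synergy literature, where the baseline
level is part of the signal. Dimensionality selection returns the smallest
K with (a) global VAF > 90%, (b) every muscle's VAF > 75%, and (c) a gain
of at most 5 **percentage points** (not relative percent, consistent with
the other point-scale thresholds) in mean per-muscle VAF when moving to
K+1; (c) holds vacuously at the search cap. All candidate factorizations
are cached in the result's diagnostics; if no K satisfies (a) and (b) the
error carries the whole VAF curve.

After extraction, synergy rows are multiplied by the stored unit-variance
scales and each column rescaled to unit maximum, with the reciprocal folded
into the matching activation row so the reconstruction is unchanged.

## Clustering and matching

Unit-max synergy columns from all participants of a stage are pooled and
clustered by k-means on squared Euclidean distance (scikit-learn, random
initialization, 100 restarts, fixed seed). The cluster count is the
smallest k whose mean silhouette exceeds both neighbours over the range
2–8: the silhouette is mathematically undefined at k = 1, so the nominal
1–8 search effectively starts at 2. Centroids are recomputed as arithmetic
means of member vectors, renormalized to unit max. Modes are named
`W_<side>_<muscle>` by the centroid's maximal weight; the side prefix is
dropped when the same muscle on both sides lies within 5% of the top
weight (reproduces mixed names like W_TA deterministically). Modes are
ordered by the peak time of their mean 100-point activation curve.

Early and late modes are matched one-to-one greedily by descending Pearson
r over the 8 weights (with ≤ 8 high-contrast modes greedy equals the
optimal assignment in practice and is easier to audit); pairs with
r > 0.83 — the two-tailed critical Pearson r at α = 0.01 with 6 degrees of
freedom, r* = t*/√(t*²+df) — are classed as the same mode. Within a
matched mode, per-muscle weights are compared by dependent-samples t-test
over participants present in both stages; a participant contributing two
synergies to one mode has them averaged first to preserve pairing.

Note an identifiability limit: member vectors are unit-max normalized, so
a weight change of a mode's *dominant* muscle is absorbed by the
normalization gauge and cannot be detected as such (it surfaces as opposite
changes in the other muscles). Planted reweighting in the validation
therefore targets a strong non-dominant muscle.

## Activation features

Activation curves are linearly resampled to 100 points spanning the full
window (endpoints preserved; idempotent on length-100 input). Features:
peak amplitude; time of peak as percent of span, first index on ties; area
by the trapezoid rule on the 0–100 percent axis (units: activation·%, so a
constant curve of height h has area 100 h — the natural convention when
durations have been normalized away); onset as the first point **strictly**
above 25% of the peak. An all-zero curve has no onset; such pairs are
dropped from the onset comparison only.

## Kinematics

Markers are low-pass filtered at **6 Hz** (effective 4th-order zero-phase
Butterworth) for all outcome variables, and velocities are central
differences of the filtered trajectories. Event detection uses its own
**10 Hz** filter: a ~0.2 s step through a 6 Hz filter smears the 0.05 m/s
threshold crossings by ~3 frames, while at 10 Hz all scripted events are
recovered within ±2 frames. Three further detection conventions: the first
0.5 s of a trial is excluded (zero-phase filtering leaves an edge transient
there, and the protocol never perturbs before 2 s); liftoff/TD are anchored
at the step's velocity-burst peak and walk outward to the threshold
crossings (a naive first-sustained-crossing search can trigger on
zero-phase ringing side lobes); crossings are sub-frame interpolated. Belt
onset requires the 0.05 m/s crossing to hold for 3 consecutive frames, so
single-frame noise spikes are ignored.

The COM model is table-driven: each segment is a proximal/distal marker
pair with a mass fraction and a COM location fraction; fractions must sum
to 1. The bundled 13-segment default uses classic cadaver-study mass
fractions (head 8.1%, trunk+pelvis 49.7% split per side, thigh 10%, shank
4.65%, foot 1.45%, upper arm 2.8%, forearm+hand 2.2%) and is fully
overridable. Step length is the slipping-heel minus recovery-heel AP
distance at TD (positive = backward recovery step); BOS length runs from
the trailing heel to the leading toe (AP ordering resolved at the
evaluation frame), BOS width between the toes. A fall is a peak harness
force **strictly** above 30% of body weight.

## Statistics

Normality: Kolmogorov–Smirnov with estimated parameters via the Lilliefors
correction (a naive KS against a fitted normal is anti-conservative).
Paired comparisons: dependent-samples t with paired Cohen's d
(dz = mean(d)/sd(d)). Dimensionality: paired Wilcoxon signed-rank, zeros
dropped, mid-ranked ties, exact p up to 25 tie-free pairs, normal
approximation with continuity correction otherwise. Trial-level training
effects: one-way within-subject ANOVA, F = MS_cond/MS_cond×subj with
df (c−1, (c−1)(n−1)), no sphericity correction. No multiple-comparison
correction is applied anywhere; reports carry raw p values. All tests are
verified against brute-force oracles (sign-pattern enumeration, explicit
sums of squares, direct formulas) and by null-calibration simulations.

## Synthetic data

The generator inverts the analysis model so that every stage of the
pipeline is exercised end to end:

* **Synergies** — the five-mode template places weight 1 on each mode's
  dominant muscle (both TA for the first mode), sparse sub-dominant
  weights drawn from 0.6·Beta(1, 8), and one strong posterior-chain
  co-activation: recovery BFLH at 0.45–0.6 inside the recovery-GAS mode.
  Sparsity matters: with dense sub-dominant weights a rank-4 fit
  reconstructs every muscle above the 75% criterion and the planted K = 5
  becomes unidentifiable to the VAF rules. Columns must be pairwise
  distinct (cosine < 0.95, by rejection).
* **Activations** — Gaussian bumps at 18/34/50/66/82% of the window,
  widths 5.5–7.5%, ±10% per-trial amplitude jitter, on a 2% resting
  baseline.
* **EMG** — envelope × unit-variance carrier (white noise band-passed
  35–250 Hz), plus truncated-Gaussian envelope noise with sd 10% of the
  in-window mean signal. Demodulating a Gaussian carrier through the
  35/40 Hz chain has irreducible estimator noise (~1 independent sample
  per 10 ms bin at 40 Hz output bandwidth), so per-muscle envelope
  recovery plateaus near r ≈ 0.9 for weakly recruited muscles even at zero
  envelope noise; the headline recovery targets (K, synergy cosines) are
  unaffected.
* **Normalization anchors** — the transition trials S3–S8 (which feed the
  normalization maxima but not the stage matrices) carry one maximal
  co-contraction burst per muscle at a common amplitude 1.25× the
  strongest synergy envelope. Real sessions contain such non-synergy
  maxima; without them, per-muscle max-normalization inflates every
  muscle's strongest synergy weight to 1 and planted weight ratios are
  unrecoverable.
* **Kinematics** — a standing posture scaled to body height; the recovery
  heel/toe/ankle execute a minimum-jerk backward step of scripted length
  between scripted liftoff and TD; the belt marker follows the trapezoidal
  profile (symmetric deceleration, since one acceleration magnitude
  governs both ramps) from the scripted onset; 1 mm additive marker noise.
  Scripted baselines: belt onset uniform in 2–4 s of an 8 s trial,
  initiation 0.25 s, execution 0.18 s, step length 0.17 m, with
  trial-to-trial jitter of 0.02 s / 0.015 m — values typical of reactive
  stepping in young adults. Planted training effects: initiation −0.03 s,
  step length +0.03 m, and synergy reweighting −0.2 (sd 0.1 across
  participants) on recovery BFLH in the W_R_GAS mode.
* **Load cell** — low baseline tension plus a smooth pulse peaking at a
  scripted fraction of body weight (default 10%, far from the 30% fall
  threshold).

Cohorts default to 26 participants with per-participant weight jitter
(sd 0.05) and anthropometric variation. All randomness derives from one
seed via independent substreams; cohorts are byte-reproducible.

## What the validation shows — and what it does not

The validation (tests plus `scripts/acceptance.py`) demonstrates that on
data generated *by the package's own model* the pipeline recovers the
planted dimensionality (K = 5 in ≥ 90% of 52 extractions), synergy shapes
(mean matched cosine ≥ 0.95), the five-mode cluster structure (silhouette
local maximum at 5; a 6-cluster rerun leaves ≥ 4 centroids at r > 0.99),
null behaviour (cross-stage match r > 0.95 with no planted change; paired-t
type-I rate within 0.04–0.06), planted-effect detection with power ≥ 0.8,
and scripted events within ±2 frames / step length within ~1 mm mean
absolute error. This is an inverse-crime check: it validates correctness
of the implementation, not the model's fidelity to real EMG. The generator
omits, among other things, motor-unit physiology, electrode crosstalk and
artifacts, marker occlusions beyond short gaps, inter-muscle noise
correlation, and trial-to-trial synergy structure drift; real-data
performance therefore cannot be inferred from these numbers.

Problem sizes used in validation are the study conditions (n = 26, ten
trials, 600/120 Hz); the test suite exercises the full-cohort path on two
such cohorts and uses smaller cohorts (n = 3–10) for orchestration tests,
with reduced NNMF restarts where the test targets plumbing rather than
recovery. Simulation-based calibration checks use 2000–4000 replicates;
power checks use 100 simulated cohorts at the outcome level (the quantity
under test is the paired comparison, not EMG synthesis).

## Known limitations

* Unit-max normalization makes dominant-muscle reweighting unidentifiable
  (see above); this is inherent to the analysis convention, not the
  implementation.
* The VAF selection rules are threshold-based; cohorts with heavily
  overlapping activations or dense synergy weights can legitimately select
  a smaller K (observed on ~4% of synthetic extractions with unlucky
  weight jitter).
* Step length at TD carries ~1 mm systematic error from the 6 Hz filter's
  step response; per-trial worst case ≈ 2.5 mm with 1 mm marker noise.
* The Wilcoxon exact path requires tie-free absolute differences; ties
  fall back to the corrected normal approximation regardless of n.
* File I/O is plain CSV/YAML by design; C3D and EDF are out of scope.
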
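# Methods

This note documents the models implemented in `myodecode`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Synthetic session generator (`synth`)

The generator emulates a two-phase upper-limb decoding protocol: 7 EMG
channels at 1 kHz; 5 motion classes plus rest; blocked training (10
repetitions per class, 3 s trials, 2 s inter-trial rest) and randomized
testing (20 repetitions per motion class). Signals are built from a planted
synergy model:

    trial signal = A · (s · P_c) + ε,   ε ~ N(0, noise_sd²) i.i.d.

where A (channels × synergies) is the planted basis, P_c the class-specific
activation time course, and s = 1 + rep_variability·z a per-repetition
amplitude scale. Noise is *signed* and added to the raw signal so the
rectify-and-filter preprocessing stage stays meaningful. Rest periods carry
baseline noise only, and rest is generated as its own labeled class because
the online decoder must emit "rest" between motions.

Design of the planted structure:

- **Basis**: group-sparse — each synergy recruits its own channel group
  (round-robin assignment) with strong uniform-random loadings, plus a
  small (5 %) baseline on the remaining channels; columns are unit-norm.
  Dense all-positive random columns are nearly collinear (expected cosine
  ≈ 0.75), which is neither physiological (synergies are co-activations of
  specific muscle groups) nor identifiable — with a collinear basis one
  component explains ~96 % of the uncentered variance and the synergy-count
  rule degenerates to k = 1.
- **Activation time course**: a Tukey (tapered-cosine, α = 0.3) plateau
  spanning the trial — a sustained contraction with smooth onset/offset.
  All synergies of a class share the time course; classes differ by their
  synergy *weight vectors*.
- **Class codes**: class c gets w_c ∝ (1 − separation)·u + separation·v_c,
  with u the uniform code and v_c a one-hot code for the first k classes,
  then the uniform code, then normalized pair sums. The uniform code is the
  fifth direction with the lowest achievable overlap (cosine 1/√k = 0.5)
  with the one-hots inside the non-negative orthant. `separation` (default
  0.85) interpolates between identical classes (0 → chance-level decoding,
  used as a negative control) and near-orthogonal codes; the default gives
  pairwise code cosines ≤ 0.62.

Defaults `noise_sd = 0.05` and `rep_variability = 0.1` (envelope peak ≈ 1
in arbitrary units, i.e. ≈ 5 % additive noise and ≈ 10 % amplitude jitter)
are the generator's picture of a clean, attentive healthy-subject session.
Amplitudes are in arbitrary units throughout; every downstream stage except
the ELM is scale-covariant, and the ELM removes scale via z-scoring with
training statistics.

**What the generator does not emulate**: motion artifacts, electrode shift,
muscle fatigue, co-contraction, within-trial tempo variation, or any user
learning across repetitions. Passing tests on this benchmark therefore
demonstrate correctness and self-consistency of the pipeline, not
performance on real EMG.

## Preprocessing (`preprocess`)

Full-wave rectification then a 4th-order Butterworth low-pass at 10 Hz
(filter family and order are an implementation choice; 4th-order
Butterworth is the standard envelope filter with a maximally flat
passband). Training data use zero-phase forward–backward filtering; the
online simulator uses the causal single-pass variant, since a real-time
loop cannot be zero-phase. Filter undershoot is clipped at zero so
envelopes are valid NMF input.

## Features (`features`)

Sliding window of 100 samples advanced by 10 (90-sample overlap; one
decision per 10 ms at 1 kHz). Per channel and window: MAV and the
*uncentered* variance Σx²/(N−1). The uncentered form (no mean subtraction)
is deliberate — on rectified envelopes it is a signal-power feature and is
kept exactly as defined. Feature layout is all MAVs (channel order) then
all VARs; any consistent order would do, consistency is what matters.
Windows never straddle trial boundaries during training.

## Synergy extraction (`synergy`)

NMF X ≈ AY fitted by alternating non-negative least squares. Each
half-update solves its convex subproblem exactly with an active-set NNLS
that groups columns by passive set (fast combinatorial NNLS), with a 1e-12
ridge on the normal equations for conditioning; the squared-Frobenius
objective is therefore non-increasing across alternations (asserted in
tests). Initialization is seeded uniform; stopping at relative objective
change < 1e-5 or 200 alternations.

Choices made where the definition was open:

- **Explained variance** is uncentered: EV(k) = 1 − ‖X−AY‖²_F / ‖X‖²_F,
  since NMF has no intercept and the data are non-negative (the standard in
  the muscle-synergy literature); a mean-centered variant is a switch.
  The EV profile is reported as a running maximum over k so that a single
  alternating fit landing in a slightly worse local optimum cannot make the
  profile non-monotone.
- **Slope rule**: "change in slope below 5 %" is formalized as the
  successive difference EV(k+1) − EV(k) < 0.05, with EV(p+1) ≡ 1; combined
  with EV(k) ≥ 0.90 the chosen k is the smallest satisfying both.
- **Rest excluded from the fit** (it carries no synergy information) but
  rest windows are still projected and classified.
- **Online projection** uses the Moore–Penrose pseudoinverse of the
  rectangular basis — the least-squares decoder, the only standard meaning
  of inverting a p×k matrix. Projected coefficients are *not* clipped:
  the projection is a plain linear map and may go slightly negative.
- **Windowing of coefficients**: per-window mean (the natural MAV analog
  for non-negative activations); a per-sample passthrough is available.
- The NMF input is decimated by 10 before fitting: a 10 Hz-bandwidth
  envelope sampled at 1 kHz is ~50× oversampled, so this is numerical
  economy with no measurable effect on the factors (config knob).

## Classifier (`elm`)

ELM with triangular-basis hidden units on affine pre-activations
x·r_j + b_j; hidden parameters i.i.d. uniform on [−1, 1] (the convention of
the original ELM literature; RBF and sigmoid units are alternatives).
Because tribas has support only on |v| < 1, inputs are z-scored with
training statistics stored in the model. Output weights solve the ridge
normal equations by Cholesky factorization (pseudoinverse fallback if
λ = 0 makes the system singular); λ defaults to 1e-3 (unreported in the
source experiment; the C-parameterized constrained form is the same
problem with λ = 1/C and is not separately implemented). Ties at the
argmax resolve to the lowest class index. Hidden-layer size via stratified
2-fold CV; the configurable grid defaults to 500–5000 units, while tests
and the acceptance run use ~100–300 units — on the synthetic benchmark
accuracy saturates far below the sizes needed for real EMG, and this is the
scaled-down problem size used throughout.

## Online simulation (`online_sim`)

The decoder sees a 100-sample ring buffer advanced 10 samples per step
(implemented as a vectorized sliding view — step t uses only samples ≤ t,
verified against an explicit ring buffer in tests). State machine choices:

- **Debounce**: a class must persist D = 5 consecutive steps (50 ms) to
  (re)target the arm; D = 1 reproduces raw per-sample behavior.
- **Transition**: fixed 1.0 s minimum-jerk profile per pose change; a new
  sustained command redirects the arm with progress restarting.
- **Movement onset** = first non-rest prediction; **selection time** =
  onset → first prediction of the commanded class; **completion** = pose
  equal to the command held 0.5 s; trials are abandoned at a 30 s timeout
  or stream end (the original protocol had no time limit, which a finite
  simulation cannot honor) and excluded from completion-time and online-
  accuracy averages.

## Metrics (`metrics`)

Offline accuracy is 100·correct/total over held-out windows **of the five
motion classes** (rest is trained and decoded but not part of the accuracy
figure, matching how motion-decoding accuracy is conventionally tabulated;
with rest included, a chance-level decoder would still score 33 % because
rest is trivially detectable by amplitude). The held-out split is a
stratified 50/50 split **of trials**, not windows: windows of one
repetition share its amplitude scale, and splitting windows would leak that
scale across the split (measured effect: a chance-level problem inflates
from ~20 % to ~60 %).

Online accuracy per class is the mean over completed trials of the
per-trial fraction of correct decoder outputs between onset and
completion; classes with no completed trial report missing, never 0. The
learning trend y = a·e^(−bx) + c is fitted by multi-start (3 fixed starts)
trust-region least squares with b ∈ [−5, 5]; near-constant data are
flagged degenerate (amplitude ≈ 0 makes b unidentifiable) rather than
trusted. Raw fitted b is stored; with this parameterization b > 0 means
completion times decay (learning). Variability resamples each repetition
to 200 points on normalized time (linear interpolation) and averages the
across-repetition *population* standard deviation (divisor = number of
repetitions) over channels and time points.

## Orchestration and reproducibility

All randomness derives from one seed split into fixed named substreams
(ground truth / training session / testing session / NMF / ELM / CV /
split), so identical configuration and seed give byte-identical session
bytes and reports. Reports contain no timestamps or paths.

## Known limitations

- The synthetic benchmark is easy by construction at default separation:
  both pathways saturate near 100 %, so it cannot reproduce the *absolute*
  performance gaps seen on real recordings. It does reproduce one
  qualitative phenomenon: under per-repetition amplitude jitter the
  EMG-feature pathway occasionally mis-decodes amplitudes outside the
  training range (bounded-support hidden units extrapolate arbitrarily),
  while the synergy pathway, which classifies a 4-dimensional activation
  code, is markedly more robust — the central motivation for synergy
  features.
- The exponential learning-trend fit is included for completeness but is
  degenerate on synthetic data, which models no user learning.
- NMF is a non-convex factorization solved from a single seeded start per
  k; the running-maximum EV profile absorbs local-optimum noise in the
  synergy-count rule but individual factors remain seed-dependent up to
  permutation and scale.
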
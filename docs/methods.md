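# Methods

## Problem and pipeline

`cryseg` segments continuous audio of crying newborns into expiratory cry
units (EXP), vocalized inspirations (INS), background silence (BKG) and
other acoustic activity (NOR). The pipeline is a cascade: a supervised
frame classifier produces an initial label per 30 ms analysis frame, and a
deterministic post-processing stage corrects those labels and sharpens
segment boundaries using three cheap side features (frame intensity,
zero-crossing count, fundamental frequency). The cascade exists because
statistical classifiers localize classes well but place boundaries poorly,
while threshold logic places boundaries well but cannot distinguish classes;
each stage covers the other's weakness.

## Front end

The signal is converted to mono by channel averaging, high-pass emphasized
with `y[n] = x[n] − 0.97·x[n−1]`, framed, and Hamming-windowed
(`w(n) = 0.54 − 0.46·cos(2πn/(N−1))`).

* **Frame geometry**: 30 ms frames, 21 ms overlap (9 ms hop). A partial
  final frame is dropped rather than zero-padded so per-frame statistics
  are unbiased and frame counts deterministic:
  `n_frames = floor((N − frame_len)/hop) + 1`.
* **Which signal feeds which feature**: cepstra are computed on the
  emphasized signal (standard practice for spectral features); intensity,
  ZCR and F0 are computed on the raw signal, because the post-processing
  thresholds emulate endpoint detection on raw energy and the emphasis
  filter would distort the silence statistics.

## Features

* **Intensity** (dB): `I_t = 10·log₁₀(Σ_n s_t²(n)·w(n) + ε)` with a Hamming
  window and floor `ε = 1e−10` so silent frames stay finite
  (≈ −100 dB re full scale).
* **ZCR** (crossings/frame): sign changes with exact zeros counted as
  positive, on unwindowed frames.
* **F0** (Hz): per-frame normalized autocorrelation `r(τ)/r(0)` of the
  mean-removed frame, maximized over lags in the 75–1000 Hz band; a frame
  is voiced when the peak reaches 0.45. No lag interpolation is performed,
  so estimates are quantized to one lag (≈ 12 Hz at 440 Hz, 16 kHz). Band
  and threshold are configurable; the defaults are ordinary pitch-tracker
  settings wide enough for both cry fundamentals and adult speech.
* **Cepstra**: power spectrum (FFT size = next power of two ≥ frame
  length) → 26 triangular mel filters (`Mel(f) = 2595·log₁₀(1 + f/700)`)
  → natural log → cosine transform `c_n = Σ_k log S_k · cos(πn(k−½)/M)`,
  n = 1..12. Frame log-energy is appended as the 13th static coefficient
  so that static + Δ + ΔΔ = 39 dimensions. Deltas use the regression
  formula with half-width 2 and edge replication.
* **EMD recipe**: the `emd-mfcc` variant decomposes each recording by
  sifting (cubic-spline envelopes through the extrema, mirror-extended by
  two extrema at each boundary) and computes the cepstra on the pointwise
  sum IMF3+IMF4+IMF5 instead of the raw signal. Decomposition is run on
  the whole utterance, not per frame, since framewise sifting would break
  IMF continuity. Sifting stops when the extrema/zero-crossing counts of
  the candidate differ by at most one — the Huang SD statistic
  (threshold 0.2) is tracked but is not sufficient on its own: on
  broadband signals it halts sifting while the count balance is still far
  off. A cap of 100 sifts guards non-convergence (flagged, not fatal).
  Reconstruction `Σ IMFs + residue = input` holds to rounding error by
  construction (telescoping).

## Classifiers

One generative model per class, diagonal covariances throughout
(variance floor 1e−6):

* **GMM bank** (default 40 mixtures/class): fitted by EM with k-means
  initialization from a fixed seed; the EM loop is stepped one iteration
  at a time so the monotone log-likelihood trace is recorded.
  Classification is per-frame argmax of class log-likelihood, with
  optional majority smoothing.
* **HMM bank** (default 4 emitting states × 10 mixtures/state = 40
  Gaussians/class): fitted by Baum–Welch. Decoding runs the Viterbi
  algorithm through a composite network: intra-class transitions follow
  each model's A; from any state the decoder may enter any class's initial
  distribution with uniform inter-class probability minus a configurable
  log-domain switch penalty (default 0).
* Ties in likelihood resolve to the fixed class order EXP < INS < BKG <
  NOR, making decisions reproducible bit-for-bit.

Model fitting is delegated to scikit-learn (EM) and hmmlearn
(Baum–Welch); density scoring and the composite decoder are implemented
in-package, and the decoder is verified against exhaustive path
enumeration on small instances.

## Post-processing

Step order: threshold estimation → voicing indexing → interval
construction → activity re-indexing → composite merge → final relabeling.

* **Dynamic thresholds.** Silence statistics come from the earliest
  250 ms of frames the initial classifier called BKG (fallback: the
  quietest 250 ms window when no BKG exists; recordings shorter than the
  span use all frames, with a warning).
  `ZC_BKG = mean(ZCR_sil) + 2·std(ZCR_sil)`;
  `I1 = 0.03(Imax − Imean) + Imean`, `I2 = 4·Imean`, `ITL = min(I1, I2)`,
  `INT_BKG = 5·ITL`. By default the multiplicative forms are evaluated on
  **linear energy** and the resulting threshold converted back to dB: on
  dB values the forms degenerate (with amplitudes normalized to [−1, 1],
  frame intensities are negative dB and 5·ITL lands far below the whole
  signal; with positive dB it lands far above), whereas on linear energy —
  the scale of the endpoint-detection rules they descend from — they place
  the gate a fixed factor above the silence floor. A config switch
  (`linear_energy: false`) applies the forms to dB directly.
* **Interval construction.** Each frame gets a voicing index (1 iff an F0
  estimate exists). The last frame of every voicing run and every local
  intensity minimum (interior: `I[t] < I[t−1]` and `I[t] ≤ I[t+1]`; the
  first frame when the contour rises away from it) are marked "2"; the
  final frame is always a boundary. Marked frames end intervals, with one
  edge rule: a mark on frame 1 ends the singleton [1,1] only when frame 2
  is also marked — otherwise it opens the first interval, since a
  start-of-signal minimum marks where an utterance begins, not a place to
  cut. Minima detection runs on the raw contour by default; 3-frame
  median smoothing is available.
* **Activity.** An interval is active when its mean intensity **or** mean
  ZCR reaches its threshold (`≥`). OR is chosen over AND so that unvoiced
  high-ZCR cry fractions are not deactivated.
* **Final decision.** Runs of equal composite label (initial class +
  activity index, e.g. `EXP1`) become candidate utterances. Inactive runs
  become BKG. Active EXP/INS runs keep their class. Other active runs are
  relabeled by mean F0: expiration band 250–1000 Hz first, then
  inspiration band 100–800 Hz, else NOR. Two guards keep this rule from
  firing on non-phonated material: the run must be at least 50 % voiced
  (the mean F0 of a few spuriously voiced frames of a noise burst is not
  the run's fundamental), and runs whose F0 min–max span is under 1 Hz
  are beep-like — machine beeps hold a constant fundamental, phonation
  never does — and keep their composite class. Runs with no voiced frame
  fall back to their composite class with a warning. Adjacent equal
  labels merge; boundaries between runs sit midway between the adjacent
  frame centers, so sampling the output track at frame centers recovers
  the run labels exactly.

## Synthetic scenes

The clinical corpora such systems are trained on are not redistributable,
so all tests run on seeded synthetic scenes: harmonic expiratory cries
(linear F0 contour, ~300–600 Hz, 1 % jitter, 5 % shimmer, raised-cosine
envelopes), short vocalized inspirations in a lower band (~170–230 Hz),
adult speech (110–190 Hz with 4 Hz syllabic amplitude modulation),
constant-frequency 1 kHz beeps, gated broadband noise bursts and a white
background floor, rendered at 16 kHz (44.1 kHz available). Identical
(spec, seed) pairs are bit-identical.

These scenes reproduce the contrasts the segmenter exploits — harmonicity,
distinct F0 bands, intensity contrast against silence — but not
reverberation, overlapping sources, channel variation or pathological cry
timbre. Passing tests therefore demonstrate that the algorithms implement
their definitions and that the cascade behaves as designed under those
contrasts; they do not certify clinical-corpus accuracy.

## Evaluation

Frame-level, one class versus rest: TPR = TP/(TP+FN), FPR = FP/(FP+TN),
FNR = FN/(TP+FN) in percent; overall accuracy = correct frames / total
frames. Rates with zero denominators are reported as undefined, not 0.
Ground-truth annotation labels collapse onto the four system classes as
EXP→EXP, INSV→INS, BKG→BKG, everything else→NOR; system-output tracks are
never collapsed (their `INS` is the vocalized-inspiration class, not the
silent-pause annotation label of the same spelling). Cross-validation
folds are assigned by recording, never by frame, to avoid leakage; the
fold count (default 10) and repeat count are configurable.

## Problem sizes in the test suite

Unit tests use seconds-long scenes and model banks of 2–4 mixtures; the
acceptance suite uses 1000 random threshold vectors, 200 enumeration
instances (≤ 8 frames, ≤ 4 composite states), 4096-sample decomposition
signals, 50 simulated sequences of length 200 for parameter recovery, and
50 scenes for the end-to-end false-alarm-reduction property. These sizes
exercise every code path while keeping the whole suite in the
tens-of-seconds range.

## Known limitations

* The F0 tracker has no octave-error correction and no lag interpolation;
  strongly subharmonic phonation may be tracked at half frequency.
* The final relabel rule sees only mean F0 and voicing; a tonal
  interference source inside the cry band with natural-sounding frequency
  modulation would be relabeled EXP.
* The silent-inspiration annotation label (INS) is scored as NOR by
  design: the system's INS class targets vocalized inspirations only.
* EMD is O(N·sifts) with spline fits per sift; on long recordings the
  `emd-mfcc` recipe dominates runtime.
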
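# cryseg

Automatic segmentation of infant cry recordings into expiratory and
inspiratory cry units.

Newborn cry analysis — pathology screening, emotion detection, monitoring —
needs clean cry units as input, but clinical recordings mix crying with
speech, machine beeps, handling noise and silence. `cryseg` locates the two
diagnostically useful unit types in such audio: audible **expirations**
(`EXP`, the main cry phase) and **vocalized inspirations** (`INS`, the
"hiccup" between cries), against background silence (`BKG`) and everything
else (`NOR`).

The system has two stages:

1. **Statistical frame classification.** The mono, pre-emphasized signal is
   framed (30 ms windows, 9 ms hop) and converted into 39-dimensional
   feature vectors: 12 mel-frequency cepstral coefficients `c_1..c_12` plus
   log-energy, with Δ and ΔΔ coefficients appended. Two model banks are
   supported: per-class Gaussian mixture models p(o|λ) = Σ_j w_j N(o; μ_j,
   Σ_j) scored frame-by-frame, or per-class hidden Markov models
   λ = {A, B, π} decoded jointly by the Viterbi algorithm through an
   ergodically connected class network. The cepstra can alternatively be
   computed on the IMF3+IMF4+IMF5 recombination of an empirical mode
   decomposition of the signal (`--recipe emd-mfcc`).
2. **Feature-driven post-processing.** The initial labels are refined using
   intensity I = 10 log₁₀ Σ s²(n)w(n), zero-crossing rate, and an
   autocorrelation F0 track. Dynamic background thresholds are estimated
   from 250 ms of classified silence (ZC_BKG = mean + 2·std of silence ZCR;
   INT_BKG = 5·min(I1, I2) with I1 = 0.03(Imax − Imean) + Imean,
   I2 = 4·Imean). Voicing transitions and intensity minima split the frame
   axis into intervals; intervals failing both thresholds are deactivated to
   background, and the surviving runs are relabeled using their F0
   statistics. This removes false alarms and sharpens segment boundaries.

## Worked example

The private clinical corpora such systems are trained on cannot be shipped,
so the package includes a seeded scene synthesizer producing labeled audio
with the same class structure (harmonic cries, low-pitch speech,
constant-frequency beeps, noise bursts, silence):

```sh
cryseg synth --scenes 6 --seed 42 --outdir corpus
cryseg train   --corpus train --out bank.json --kind gmm --components 4 --seed 0
cryseg segment --wav corpus/scene_005.wav --bank bank.json --out initial.lab
cryseg refine  --wav corpus/scene_005.wav --labels initial.lab --out final.lab
cryseg evaluate --ref corpus/scene_005.lab --hyp final.lab
```

(`train/` holds the first five scene pairs; `scene_005` is held out.)
The refine step logs the thresholds it estimated for this file:

```
[cryseg cfg=4a6b29f319] refined corpus/scene_005.wav: ZC_BKG=251.766 INT_BKG=-11.714 dB, 15 segments -> final.lab
```

ZC_BKG is in crossings per 30 ms frame — white-noise silence crosses zero
roughly every other sample, hence ~252 of 480 — and INT_BKG is the intensity
gate in dB re full scale: intervals quieter than −11.7 dB with ZCR below
threshold are deactivated. Evaluation prints per-class frame-level detection
rates (TPR), false alarm rates (FPR) and miss rates (FNR), in percent:

```
class   TPR%    FPR%    FNR%
EXP     98.64   0.00    1.36
INS     97.73   0.27    2.27
BKG     99.71   0.55    0.29
NOR     100.00  0.48    0.00
accuracy        98.98
```

On this held-out scene 98.6 % of expiration frames and 97.7 % of vocalized
inspiration frames are recovered with sub-percent false alarm rates; the
final label file partitions the recording:

```
0.000000  1.153500  BKG
1.153500  1.171500  NOR
1.171500  2.188500  EXP
2.188500  2.557500  INS
...
```

`cryseg crossval --corpus corpus --k 5` runs the same train/segment/refine
cycle with recording-level k-fold cross-validation.

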
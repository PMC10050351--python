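# Methods

## Paradigm model

The speller grid is the row-major 6×6 alphanumeric layout
(`A–F / G–L / M–R / S–X / Y Z 0 1 2 3 / 4 5 6 7 8 9`), the only layout
consistent with "5" sitting at row 6, column 2. Every 12-dimensional
score or count vector in the package is indexed by a single shared
`flat_index` convention: columns 1–6, rows 7–12.

Columns flicker at 6.0–8.5 Hz and rows at 9.0–11.5 Hz in 0.5 Hz steps,
intensity `(cos(2πft)+1)/2`. A trial flashes each of the 12 lines
exactly once in a uniformly random order ("pseudorandom" is read as an
unconstrained uniform permutation; no adjacency constraint is imposed
because none is defined). Physical timing — 2 s cue, 1 s flash, 0.1 s
inter-flash gap — is carried in event tables; only the first 0.8 s of
each flash carries analyzed data.

## Synthetic EEG generator

Each flash epoch is 13 channels × 200 samples (0.8 s at 250 Hz), in
microvolts:

```
data = pink_noise + is_target · [P300 bump + SSVEP]   (gaze model)
```

- **P300**: a Gaussian-shaped positive deflection, amplitude 5 µV,
  latency 0.30 s with 0.02 s trial-to-trial jitter (sd), width
  (Gaussian sd) 0.05 s, projected onto a fronto-parietal topography
  peaking at Cz/Pz.
- **SSVEP**: three harmonics of the flashed line's frequency, amplitude
  2 µV at the fundamental with decay 0.5 per harmonic, projected onto
  an occipital topography peaking at Oz. 80% of the amplitude is
  phase-locked to stimulus onset (`phase_locking = 0.8`); the remainder
  has a uniform random phase per epoch, so template-based decoders must
  rely on the trial-consistent fraction.
- **Gaze model**: only the fixated (target) line evokes an SSVEP
  (`nontarget_ssvep_gain = 0`); a positive gain is available to
  stress-test the decoders with peripheral-flicker crosstalk.
- **Noise**: independent per-channel 1/f^α noise (α = 1), sd 8 µV per
  sample, generated by spectral shaping of white noise with the DC bin
  removed.

Topography vectors are fixed constants normalized to **unit peak**, so
the profile amplitudes read directly as the evoked amplitude at the
component's peak electrode — the convention used when such amplitudes
are quoted for real recordings (a "5 µV P300" is 5 µV at Cz/Pz). At
these defaults single-flash P300 detection is genuinely hard (binary
flash accuracy ≈ 0.65–0.8), the SSVEP is reliably but not perfectly
decodable from trial-averaged templates, and the hybrid decoder has
headroom over both — the qualitative regime the design targets.

A calibration session is 11 blocks × 12 trials (132 characters, 1,584
flash epochs; 2 target + 10 non-target flashes per trial, 1:5 overall).
Copy-spelling sessions spell a given text one trial per character.

What the generator does *not* emulate: volume-conducted correlated
noise, ocular/muscular artifacts, electrode drift, alpha rhythm,
latency/amplitude non-stationarity across blocks, or the competing
P300×SSVEP suppression seen in real hybrid stimulation. Passing tests
therefore demonstrate correctness of the decoding machinery under the
assumed signal model, not expected accuracy on human EEG; no
published human accuracy is claimed to be reproduced by simulation.

## Preprocessing

Order: 60 Hz notch → linear detrend → 0–800 ms epoching → channel
split. The notch is a second-order IIR (Q = 30) applied
forward-backward (zero phase) with generous padding; detrending removes
the per-channel least-squares line; epochs are samples
`[round(onset·fs), round(onset·fs)+200)`, 0-based half-open. The P300
view is (Fz, Cz, P3, P4, PO7, PO8, Pz, Oz); the SSVEP view is
(PO7, PO8, Pz, Oz, O1, O2, PO3, PO4, POz); the two views share exactly
{PO7, PO8, Pz, Oz}. A second pass of the pipeline is not bit-idempotent:
the notch skirt re-attenuates nearby passband content by up to ~2%,
an inherent property of any IIR notch at this Q.

## P300 detector

Features are the depth-4 Daubechies-4 approximation coefficients of
each 200-sample channel, 13 per channel × 8 channels = 104. The DWT
uses **periodized** extension because it is the only dyadic scheme
whose approximation chain is 200 → 100 → 50 → 25 → 13; its nominal
band (0–7.8 Hz) covers the P300's energy.

Class imbalance (1:5) is handled EasyEnsemble-style: the non-target
samples are randomly split into five disjoint fifths, each paired with
the full target set to train one RBF-kernel SVM (C = 1, bandwidth from
the median heuristic on up to 200 training points; margins squashed to
probabilities by a logistic sigmoid fitted on training margins).
Per-classifier accuracies come from leave-one-block-out cross-validation
over the 11 calibration blocks; ensemble weights are the
chance-corrected simplex weights with chance level P = 0.5 (the
training sets are balanced by construction). Sub-chance classifiers are
clamped to weight 0 and the rest renormalized; if every classifier is
at or below chance the ensemble raises instead of guessing.

## SSVEP detector

Filter bank: 10 Chebyshev-I band-pass filters (order 4, 0.5 dB ripple,
forward-backward), sub-band k spanning `[k·fa − 2, 90]` Hz with
`fa = 8` Hz — chosen so the widened lower edge of sub-band 1 is exactly
6 Hz, the lowest stimulus fundamental. Note the forward-backward
application doubles the passband ripple (troughs ~-1 dB).

TRCA: per frequency and sub-band, the spatial filter is the leading
generalized eigenvector of `(AᵀA, BᵀB)` where A is the trial-averaged
template and B the trial-stacked data; `BᵀB` receives a relative ridge
of `1e-6·trace/N_c` against rank deficiency. Filters are unit-norm with
the largest-magnitude entry made positive (the Rayleigh quotient is
sign- and scale-invariant). Scoring uses the **ensemble** variant: test
epoch and template are both projected through the stacked 12-filter
matrix of the sub-band, flattened, and Pearson-correlated; sub-band
correlations combine as `Σ_k (k^-1.25 + 0.25) · sign(ρ_k) · ρ_k²`, the
established filter-bank convention. Per-frequency (non-ensemble)
filtering is available as a configuration fallback but measured
markedly worse on the synthetic sessions. Within a trial each flashed
line is judged by its own epoch against its own frequency template.

The CCA baseline computes, per frequency, the largest canonical
correlation between the epoch and a sine/cosine reference set (3
harmonics) via rank-revealing orthonormal bases and an SVD, which is
numerically robust to degenerate (zero-variance) epochs.

## Fusion and decision

Calibration character accuracies of the two decoders (both estimated by
the same leave-one-block-out scheme) set the modality weights with
chance level `E = 1/36` — character-level chance, matching the level at
which the accuracies are measured. A modality at or below chance is
clamped to weight 0. Because a probability-like vector and a
correlation vector are not commensurable, each 12-vector is z-scored
and softmaxed before mixing, which also makes the decision invariant to
any affine rescaling of either raw vector; a constant vector maps to
the uniform distribution, leaving the decision to the other modality.
Column = argmax of entries 1–6, row = argmax of 7–12, ties to the
lowest index.

## Evaluation

`ACC = 100·X1/X` over spelled characters. ITR uses the Wolpaw formula
in bits/min with N = 36 and T = 0.16 min per selection (9.6 s — twelve
0.8 s analyzed epochs); this (N, T) pair reproduces every per-subject
ITR of the published ten-subject benchmark from its printed accuracy to
within 0.01 bits/min, which is the package's regression anchor for the
implementation (see `fercbci.benchmarks`). The physical trial length
(2 s cue + 12 × 1.1 s = 15.2 s) is reported alongside but does not
enter the ITR. The 12×12 line confusion matrix places column decisions
in the upper-left 6×6 block and row decisions in the lower-right block;
the off-diagonal blocks are structurally empty because the two axes are
decoded independently.

`run_experiment` chains everything: simulate calibration (11 blocks),
train both decoders and the fusion controller, simulate copy-spelling
of "BCISPELLER" + "HELLOWORLD" + "NEUBMIE" × 3 repetitions (81
characters), and report per-modality ACC/ITR plus the hybrid confusion
matrix. All randomness flows from the single config seed; reports are
byte-identical across reruns. Experiment-scale checks in the test suite
and acceptance script use 10 simulated subjects × 81 characters, sized
to keep a full run in ~1 minute per subject on one CPU while giving
~1.4 pp standard error on mean accuracies.

## Known limitations

- The simulator's stationary, spatially independent noise makes spatial
  filtering easier than on real EEG; absolute accuracies are not
  comparable to human studies.
- Free-spelling, asynchronous (idle-state) operation, and artifact
  handling are out of scope.
- The sigmoid margin calibration is fitted on training margins
  (resubstitution), slightly overconfident; ranks, not calibrated
  probabilities, drive decisions, so the effect on accuracy is nil.
- With very few calibration trials per frequency (< 2) TRCA fitting
  raises rather than degrading silently.
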
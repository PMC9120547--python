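# Methods

## Problem and model

The package estimates three blood-pressure quantities — systolic (SBP),
diastolic (DBP) and mean arterial pressure (MAP = (SBP + 2·DBP)/3) — from
8-s windows of two non-invasive waveforms, ECG and PPG, sampled at 125 Hz.
The invasive ABP waveform supplies reference labels only; it never enters
the model input. All three outputs are produced by one forward pass of a
single network with fully shared weights (hard-parameter-sharing multi-task
regression): the tasks are strongly correlated, sharing regularizes each of
them, and one model replaces three.

The network is a multi-scale 1-D CNN. One shared stem (conv kernel 15 →
non-overlapping max-pool 3) preserves raw morphology while cutting the
temporal rate by 3; three parallel streams then view the same representation
through kernels of 5, 7 and 9 samples — at 41.7 Hz post-pool, receptive
fields of roughly 0.12–0.22 s per layer, compounding over eight conv layers
per stream to beat-to-beat scale. Each stream has four modules of two
convolutions (each conv → batch-norm → ReLU) with 64/128/256/512 filters,
ends in global average pooling and a 512-wide FC, and the three 512-vectors
concatenate to 1536 features → FC-256 → 3 linear outputs.

Training minimizes the joint MSE (sum of the three squared task errors,
averaged over segments) plus an L2 penalty on convolution/FC weight
matrices, with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 100,
150 epochs, initial learning rate 0.01 decayed by a factor γ once every five
epochs: lr = lr₀ · γ^⌊epoch/5⌋ (the floor convention matches "decayed once
every 5 epochs"; within a block the rate is constant).

## Architectural choices that were genuinely open

Several details are not determined by the published table of layers; the
package fixes them as follows, all configurable through `MstNetConfig`:

* **Temporal downsampling** — no strides are listed. The first convolution
  of each module uses stride 2 (the rest stride 1, zero "same"-style
  padding), giving 1000 → 333 → 167 → 84 → 42 → 21 time steps before global
  pooling: a standard halving pyramid that keeps compute flat as channel
  width doubles.
* **"AvgPool1d (1)"** is read as adaptive global average pooling to length
  one. A kernel-1 average pool would be the identity, and only global
  pooling makes the per-stream FC act on exactly 512 channel features,
  consistent with the stated 1536 concatenated features.
* **Shared stem** — the stem rows sit above the stream split in the layer
  table, so there is one stem, not three. Its filter count is unspecified;
  default 32 (8 in the reduced config). The stem conv is followed by
  batch-norm + ReLU like every other convolution here.
* **Weight init** — Kaiming fan-in normal, seeded; biases zero.
* **L2 scope** — the penalty covers conv/FC weight matrices only. Biases
  and batch-norm scale/shift are excluded: shrinking them does not reduce
  model complexity in the relevant sense, and the penalty is written on
  weights.
* **γ and λ** — no published values exist. Defaults are γ = 0.5 and
  λ = 1e-4; both are flagged in `TrainConfig` as package choices. Note
  γ = 0.5 over 150 epochs anneals the rate by 2³⁰; experiments that need a
  live learning rate late in training (e.g. the memorization test, which
  uses γ = 0.93) should set γ accordingly.

## Preprocessing

Records are cut into non-overlapping 8-s windows (trailing partial window
dropped), each window processed independently:

1. **Beat detection on ABP.** Candidate peaks are strict local maxima.
   Candidates closer than 0.6 s to a *higher* retained candidate are removed
   by greedy highest-first suppression — deterministic and
   order-independent. This implements the peak-to-peak time limit that
   rejects dicrotic ("false") peaks, which sit ~0.3 s after the true
   systolic peak. Peaks outside [80, 180] mmHg are then discarded; troughs
   are the minima between consecutive retained peaks; a trough outside
   [60, 130] mmHg discards its beat, iterating until stable. Windows that
   lost any beat to the amplitude rules, or retained none, are rejected.
2. **Labels.** Window SBP = mean of retained peak values, DBP = mean of
   trough values (median available), MAP from the formula. Whether a
   multi-beat window should be summarized by mean, median, or per-beat
   replication is not specified anywhere; the arithmetic mean is the
   unbiased default. Labels outside [60, 180] mmHg reject the window.
3. **Denoising.** ECG and PPG are decomposed with the Daubechies-8 wavelet
   (symmetric extension) to 7 and 8 levels respectively. The level-1 detail
   band — the top dyadic octave, exactly 31.25–62.5 Hz at 125 Hz — and the
   deepest approximation band (0–0.49 Hz at 7 levels, 0–0.24 Hz at 8) are
   zeroed; these exact dyadic bands are implemented rather than the rounded
   printed figures, since the level counts are the operative description.
   Remaining detail levels are soft-thresholded, sign(c)·max(|c|−t, 0), with
   the universal threshold t = σ·√(2 ln N), σ = MAD(level-1 details)/0.6745.
   This estimator assumes the finest band is noise-dominated; a strong
   coherent tone there (which the pipeline zeroes anyway) inflates t and
   will also shrink in-band structure — the in-band-preservation test
   therefore feeds the denoiser signals whose finest band is quiet, which is
   also the situation the pipeline creates. Decomposing a 1000-sample window
   to 7–8 levels exceeds the conventional maximum useful depth (6); the
   deep levels exist purely to isolate the baseline band and their boundary
   effects are accepted.
4. **Normalization.** Each channel of each window is rescaled to
   2·(x−min)/(max−min) − 1, exactly spanning [−1, 1]; constant channels
   reject the window. Denoising runs after cutting by default (the
   alternative order is supported via `dwt_denoise` on whole records); the
   idempotence property normalize(normalize(x)) = normalize(x) holds
   exactly.

A record-level minimum-duration gate (default off; 480 s for bedside data)
mirrors the usual practice of excluding very short recordings.

## The synthetic generator

The generator's job is exact ground truth, not hemodynamic realism. The ABP
pulse is assembled from trough-to-trough beat segments: the diastolic floor
stays flat at beat k's DBP through the systolic peak, then follows a cosine
smoothstep to beat k+1's DBP; a raised-cosine upstroke/decay rides on the
floor with its apex pinned to SBP at an integer sample. Because both the
floor and the pulse shape have zero slope at the beat boundaries, the
sampled value one sample away from a boundary exceeds the boundary value by
(pulse − ΔDBP)·(πh/L)²/4 + O(h⁴) > 0 whenever SBP exceeds the neighbouring
DBPs — so every annotated peak is a strict local maximum and every annotated
trough the exact minimum between its peaks, to machine precision, even with
per-beat label variation. The dicrotic wave is a truncated Gaussian
(σ = 60 ms, 300 ms after the peak, 8% of pulse amplitude) whose support
excludes the peak and trough samples; by default it is a shoulder on the
decay, and `inject_artifacts(false_peak_boost=...)` raises it into a strict
local maximum to stress the detector (boosts around 0.2 of pulse amplitude
create clear false peaks that remain below the systolic peak).

ECG is a triangular R-spike train placed 200 ms before each ABP peak with
small P/T bumps; PPG is a low-pass-filtered, 60-ms-delayed, unit-rescaled
copy of the ABP pulse. Injected corruption goes where the denoiser looks:
baseline drift (sinusoid < 0.5 Hz) and band-limited noise (> 31 Hz) are
added to ECG/PPG; the ABP label channel receives only false-peak boosts,
mirroring the fact that the reference pipeline cleans ABP by amplitude and
timing rules, not by filtering.

`make_dataset` draws per-record heart rate from [60, 90] bpm, DBP from
[60, 105] mmHg and pulse pressure from [30, 60] mmHg, with ~1 mmHg per-beat
jitter — placing all labels inside the SBP [80, 180] / DBP [60, 130] window
that the reference-label distribution occupies. What the generator does
*not* emulate: morphological variability between subjects, respiration
coupling, arrhythmia, sensor artefacts other than the three injected kinds,
and any true physiological PPG/ECG→BP dependence beyond what the shared
pulse geometry provides. Passing tests therefore demonstrate the pipeline's
correctness and trainability, not clinical accuracy on real data.

## Training, validation, evaluation

The training loop shuffles per epoch under the run seed, records the epoch
mean of the joint MSE (the L2 penalty acts on gradients but is not folded
into the reported loss trace), and optionally holds out a fraction
(default 10%) of the training data for a validation-loss trace — the source
protocol plots a validation loss without defining its split. Runs are
bit-reproducible given the seed on a single thread. Cross-validation splits
*segments* (five seeded folds of near-equal size), matching the published
protocol; this lets windows of one subject appear in both train and test
folds, so a stricter subject-grouped mode (`groups=` in `kfold_split` /
`cross_validate`) is provided. The averaged report is the unweighted mean of
fold metrics.

Metrics per task: Pearson r; ME = mean(y − z) (reference minus estimate);
MAE; and SD — implemented as the sample standard deviation (n−1) of the
signed differences about their own mean, the quantity Bland–Altman limits
use. The printed formula this corresponds to mixes the sign conventions of
its two terms; the literal variant is available as `sd(..., literal=True)`
for audit and differs only in pathological cases. AAMI: pass iff
|ME| ≤ 5 mmHg and SD ≤ 8 mmHg (inclusive) with ≥ 85 subjects; margins are
reported per criterion. BHS: cumulative percentages of absolute errors
within 5/10/15 mmHg; a grade requires all three of its thresholds
(A: 60/85/95, B: 50/75/90, C: 40/65/80), with D emitted below C. Error
histograms use 1-mmHg bins over [−20, 20] mmHg.

## Problem sizes and numerical notes

The network runs in pure NumPy (im2col convolutions, hand-derived backward
passes verified against central finite differences at 1e-3 relative
tolerance). Test-suite experiments use the reduced configuration
(stem 8, filters 8/16/32/64, FC 64; ~2.0×10⁵ parameters) and synthetic
datasets of 30–60 segments: the memorization check trains on 32 segments
for 200 epochs (batch 1, lr 0.01, γ = 0.93 — an annealing schedule that
keeps the final rate near 5×10⁻⁴) and the end-to-end cross-validation demo
uses 30 segments × 8 epochs. These sizes were chosen so the whole suite
stays desk-scale; scaling the same code to realistic corpora is a matter of
compute, not of code paths.

Degenerate inputs are rejected loudly rather than coerced: constant
channels, empty beat sets, shape mismatches, non-finite losses, too-short
signals for a wavelet depth (minimum 2^levels samples) and invalid
configurations all raise with the offending quantity named. Ties in the
greedy peak suppression are broken toward the earlier candidate via a stable
sort; equal-valued duplicate peaks beyond the exclusion window are all kept.

## Known limitations

* Published headline accuracies require the external bedside corpus
  (hundreds of subjects, >20k segments) and long training; nothing at desk
  scale speaks to them, and the package makes no claim about them.
* The NumPy engine is single-threaded-friendly but slow compared to a GPU
  framework; the default (unreduced) architecture is practical for
  inference and shape verification, not for large-scale training.
* Batch-norm statistics with batch size 1 reduce to per-channel temporal
  statistics; this is well-defined for the conv layers used here but means
  very small batches change the effective normalization.
* The HDF5/CSV record formats are package-defined; the adapter for the
  public cuff-less BP extract is a stub that maps channel order and checks
  scale, and is never exercised against real data in the tests.
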
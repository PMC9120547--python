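# mstbp — cuff-less continuous blood-pressure estimation from ECG and PPG

Continuous blood-pressure monitoring normally requires an arterial line or a
cuff. A long-studied alternative is to *estimate* pressure from two
non-invasive waveforms that are cheap to record — the electrocardiogram (ECG)
and the photoplethysmogram (PPG) — using the invasive arterial blood pressure
(ABP) waveform only to provide reference labels during training. `mstbp`
implements one such method end to end, for researchers in physiological
signal processing who want a fully inspectable, CPU-only reference pipeline:

* **synthetic data** — a waveform generator producing ECG/PPG/ABP records
  with exactly known per-beat systolic/diastolic pressures, dicrotic waves,
  baseline wander, high-frequency noise, and injectable "false peaks";
* **preprocessing** — 8-s segmentation; constrained ABP beat detection
  (peak-to-peak interval > 0.6 s, SBP ∈ [80, 180] mmHg, DBP ∈ [60, 130] mmHg)
  that rejects dicrotic false peaks and corrupt beats; reference label
  extraction with MAP = (SBP + 2·DBP)/3; Daubechies-8 wavelet denoising
  (7 levels for ECG, 8 for PPG: zero the finest detail band and the deepest
  approximation band, soft-threshold the rest); per-segment rescaling of each
  channel to [−1, 1];
* **model** — a multi-scale, multi-task 1-D CNN: a shared stem
  (conv k=15 → max-pool 3) feeding three streams with kernel sizes 5/7/9,
  each with four modules of two convolutions (batch-norm + ReLU) at
  64/128/256/512 filters, global average pooling and a 512-wide FC per
  stream; the concatenated 1536 features pass through a 256-wide hidden layer
  to a 3-neuron head that emits SBP, DBP and MAP *simultaneously*
  (z<sub>i</sub> = F(x<sub>i</sub>; θ) with fully shared weights);
* **training** — Adam, batch size 100, 150 epochs, initial learning rate
  0.01 decayed every 5 epochs (lr = lr₀·γ^⌊epoch/5⌋), joint loss
  MSE = (1/n) Σᵢ [(yᵢˢᵇᵖ−zᵢˢᵇᵖ)² + (yᵢᵈᵇᵖ−zᵢᵈᵇᵖ)² + (yᵢᵐᵃᵖ−zᵢᵐᵃᵖ)²]
  plus an L2 penalty λ·Σw² on conv/FC weights; five-fold cross-validation;
* **evaluation** — per-task Pearson r, ME = mean(y−z), MAE, SD of the
  errors, Bland–Altman limits, error histograms, and verdicts against the
  AAMI standard (|ME| ≤ 5 mmHg, SD ≤ 8 mmHg, ≥ 85 subjects) and the BHS
  grades (cumulative error percentages at 5/10/15 mmHg).

The network and its backpropagation are implemented in NumPy
(`mstbp.nn`), so the whole pipeline runs on one CPU with no deep-learning
framework. Default architecture: 12,167,587 trainable parameters; the
`MstNetConfig.reduced()` variant (199,483 parameters) is sized for
desk-scale experiments.

## Worked example

Generate synthetic records, preprocess them, and cross-validate a reduced
network (this is deliberately small — 60 segments, 40 epochs — so it runs in
about a minute; accuracy at this scale is nowhere near what the method
achieves with tens of thousands of real segments):

```python
from mstbp import MstNetConfig, TrainConfig, build_segments, make_dataset
from mstbp.training import cross_validate

segments = []
for record, _ann in make_dataset(20, seed=7, duration=24.0):
    segments += build_segments(record)           # 60 accepted segments

cfg = TrainConfig(batch_size=4, epochs=40, lr_base=0.005, gamma=0.95,
                  l2_lambda=1e-4, val_fraction=0.0, seed=0)
reports, avg = cross_validate(segments, MstNetConfig.reduced(), cfg, k=5)
avg.save("out/")     # writes report.csv / report.txt
```

`out/report.txt` from the run above:

```
subjects: 9
AAMI: fail
SBP: r=0.433 ME=-3.633 MAE=14.025 SD=16.226 BHS=D
DBP: r=0.328 ME=-2.205 MAE=10.168 SD=11.975 BHS=D
MAP: r=0.379 ME=-2.583 MAE=11.115 SD=12.934 BHS=D
```

Read: with 48 training segments per fold the network only begins to track
pressure (r ≈ 0.4, MAE 10–14 mmHg), and the AAMI/BHS verdicts correctly
report that this is not a validated device — the evaluation machinery is the
point here, not the score. That the *optimizer* works is checked separately
by a memorization run — a reduced network trained on 32 segments for 200
epochs (`batch_size=1, lr_base=0.01, gamma=0.93`) reaches

```
final training loss: 0.0905 mmHg^2
```

i.e. it fits all three pressures of every segment to well under ±0.2 mmHg.

The same pipeline is scriptable from the shell:

```sh
mstbp generate --n-records 20 --duration 24 --seed 7 --out data/
mstbp preprocess --in data/ --out segs.h5
mstbp train --data segs.h5 --seed 0 --out run/
mstbp evaluate --data segs.h5 --folds 5 --seed 0 --report rep/
```

## Layout

| module | contents |
| --- | --- |
| `mstbp.synthetic` | `PhysioParams`, `generate_record`, `inject_artifacts`, `make_dataset` |
| `mstbp.preprocess` | `segment_record`, `detect_abp_beats`, `extract_labels`, `dwt_denoise`, `soft_threshold`, `layer_normalize`, `build_segments` |
| `mstbp.nn` | NumPy layers (Conv1d, BatchNorm1d, ReLU, pooling, Linear) + Adam |
| `mstbp.model` | `MstNetConfig`, `build_model`, `multitask_mse`, `l2_penalty`, `lr_schedule`, `count_parameters` |
| `mstbp.training` | `train`, `kfold_split`, `cross_validate` |
| `mstbp.evaluation` | metrics, `aami_check`, `bhs_grade`, `bland_altman`, `evaluate` |
| `mstbp.io` / `mstbp.cli` | CSV/HDF5 record and segment formats, run configs, `mstbp` command |

Methodological details, parameter rationale and known limitations are in
[docs/methods.md](docs/methods.md).
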
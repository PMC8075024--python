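# dualecg

Inter-patient heartbeat classification from single-lead ambulatory ECG.

Automatic arrhythmia screening must label every heartbeat of a long Holter
recording as normal (**N**), ventricular ectopic (**VEB**), supraventricular
ectopic (**SVEB**) or fusion (**F**) — the AAMI EC57 classes — and it must do
so for *patients it has never seen*, which is the clinically honest,
inter-patient evaluation setting. `dualecg` implements a complete pipeline
for this task, aimed at biomedical-signal researchers who want a
self-contained, inspectable reference implementation:

1. **Wavelet denoising.** The 360 Hz signal is decomposed 9 levels with the
   Daubechies-6 filter bank; baseline wander is removed by nullifying the
   deepest approximation (0–0.35 Hz) and power-line interference by
   nullifying detail levels 1–2 (45–180 Hz), then reconstructing.
2. **3-beat segmentation.** For each annotated beat *i*, a variable-length
   window from the midpoint of (R<sub>i−2</sub>, R<sub>i−1</sub>) to the
   midpoint of (R<sub>i+1</sub>, R<sub>i+2</sub>) is cut and aligned to
   exactly **1201 samples** with R<sub>i</sub> at the centre (index 600),
   zero-padding or cropping as needed (Input 1).
3. **Spectral features.** A 5-level db6 DWT of each segment; the detail
   coefficients D3‖D4‖D5 (5.625–45 Hz, the QRS energy band) are stacked into
   a **292-sample** vector (Input 2).
4. **Dual-channel separable CNN.** Each input feeds its own branch — one
   standard Conv1D (kernel 5 for the segment, 3 for the spectral vector)
   followed by two *functional units*; a functional unit is two depthwise
   separable convolutions (the second with stride 2), each with batch
   normalization and ELU, doubling channels and halving length. The merged
   branches pass one more functional unit, a max-pool, and four dense layers
   ending in a 4-way softmax. A separable convolution needs
   `k·C_i + C_i·C_o` weights instead of `k·C_i·C_o`
   (ratio `(C_o + k)/(k·C_o)`), and the package ships closed-form
   parameter/operation counters that are audited against the built model.
5. **Training & evaluation.** Class-weighted cross-entropy
   (`w_j = total/(4·n_j)`), SGD with step decay
   `η = η₀·0.1^⌊epoch/30⌋`, early stopping on validation accuracy,
   stratified k-fold CV, and both inter-patient (disjoint patient sets) and
   intra-patient protocols with the full Se/Sp/PPV/Acc/F1/G metric suite.

Because the MIT-BIH corpus cannot be redistributed, the package includes a
first-class synthetic-data module (`dualecg.syndata`) that generates
annotated 360 Hz records with class-separable PQRST morphologies and
controllable baseline-wander/PLI/white noise, so the entire pipeline runs
and is tested without any download. Real WFDB records (`.hea/.dat/.atr`,
format 212) are read natively when present.

## Worked example

```bash
$ dualecg simulate --duration 60 --seed 11 --out demo/syn01
wrote demo/syn01 (77 beats, 60 s)

$ dualecg inspect-record demo/syn01
record syn01: 21600 samples (60.0 s at 360 Hz), lead MLII
  F: 5
  N: 61
  SVEB: 9
  VEB: 2

$ dualecg segment --record demo/syn01 --out demo/segments.npz
73 segments (crop rate 0.00%) -> demo/segments.npz

$ dualecg features --segments demo/segments.npz --out demo/features.npz
features (73, 292) (sections (159, 85, 48)) -> demo/features.npz
```

The 60 s record holds 77 beats drawn from the default 70/10/10/10 class
mix; the first/last two beats lack the neighbours the 3-beat window needs,
and the four excluded edge beats leave 73 aligned 1201-sample segments
(none long enough to be cropped at this heart rate). Each segment's
5-level DWT yields 159 + 85 + 48 = 292 stacked detail coefficients.

From Python, the full inter-patient experiment on a synthetic corpus:

```python
from dualecg import PipelineConfig, run_protocol
from dualecg.syndata import NoiseSpec, generate_corpus

noise = NoiseSpec(baseline_amp=0.15, pli_amp=0.05, white_sigma=0.03, seed=1)
records = generate_corpus(42, 90.0, (0.7, 0.1, 0.1, 0.1), noise, seed=7)
cfg = PipelineConfig(max_epochs=8, patience=6)
report = run_protocol("inter_patient", records, cfg, seed=1, n_folds=2)
print(report.mean_macro_f1)        # 0.998 on held-out synthetic patients
print(report.pooled_confusion.counts)
```

The same run prints the pooled confusion matrix over held-out patients —
with the default templates the four classes are nearly perfectly separated
(a handful of SVEB/N confusions remain, the hardest pair since they share
QRS morphology).

## Layout

| module | role |
|---|---|
| `dualecg.syndata` | synthetic annotated ECG records (templates + noise) |
| `dualecg.record_io` | CSV fixture + WFDB I/O, AAMI symbol map, dataset splits |
| `dualecg.denoise` | 9-level db6 decomposition, band nullification |
| `dualecg.segmenter` | 3-beat extraction, 1201-sample alignment, standardization |
| `dualecg.spectral` | stacked D3–D5 feature vectors |
| `dualecg.network` | architecture spec, parameter counters, model builder |
| `dualecg.nn` | numpy layers with backprop (conv, sepconv, BN, ELU, …) |
| `dualecg.trainer` | weighted loss, SGD schedule, folds, hyperparameter search |
| `dualecg.evaluator` | confusion matrix, metric suite, evaluation protocols |
| `dualecg.cli` / `dualecg.pipeline` | orchestration and the `dualecg` command |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
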
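# chirpff

Bioacoustic detection of soil pests from sub-surface audio. `chirpff`
classifies stridulations of scarab beetle larvae — *Melolontha
hippocastani* (MH) vs *M. melolontha* (MM) — in long, mostly silent soil
recordings, for entomologists and precision-agriculture engineers who need
a cheap, non-invasive monitor of root-feeding pest activity.

The pipeline:

1. **Conditioning** — mono 44.1 kHz WAV, DC removal, 200–5000 Hz zero-phase
   Butterworth band-pass, peak normalisation to −1 dBFS.
2. **Short-time-energy segmentation** — mean-square energy over 10-s
   windows (0 % overlap), normalised per recording; windows with
   normalised STE ≥ 0.2 become the active segments. The retained fraction
   S_g drives the computational saving.
3. **Features** — 13 MFCCs per 25-ms Hamming frame at 50 % overlap
   (799 × 13 per segment), flattened, min–max scaled; the class claim is
   written into the first ten entries as a block one-hot code
   (`1111100000` for MH, `0000011111` for MM).
4. **Forward-forward network** — layers of 500/1000/1000 ReLU units
   trained greedily without backpropagation. Each layer pushes the
   *goodness* of correctly-labelled (positive) inputs above a threshold θ
   and of wrongly-labelled (negative) inputs below it:

       g = √((1/n) Σ_j O_j²)                    RMS goodness
       L = (L⁺ + L⁻)²,  L⁺ = mean softplus(−(g⁺−θ)),  L⁻ = mean softplus(+(g⁻−θ))

   with θ = 3.5, η = 0.1, 500 epochs, seed 1234. Between layers only the
   activity orientation is passed on (length normalisation). At inference
   the input is encoded with each candidate label; the accumulated
   goodness of all but the first layer decides.
5. **Evaluation** — confusion metrics with MH as positive class, rank AUC,
   stratified 5-fold CV, and the complexity index
   CCP = (T_P · S_g / T_D) · 100 (< 1 ⇒ faster than real time).

A synthetic-data module generates stridulation-like two-class recordings
(sparse decaying-sinusoid pulse trains in noise, with ground-truth active
windows) so the whole pipeline runs with no data download, plus noise
tooling: exact-SNR mixing and spectral-subtraction enhancement.

## Worked example

```python
import numpy as np
from chirpff import synthetic, features, evalmetrics

# 100 labelled 10-s segments per class, cut from synthetic recordings
segments = synthetic.make_segment_dataset(100, seed=42)

# stratified 5-fold CV of the default RMS-goodness network
result = evalmetrics.cross_validate(segments, k=5, seed=0)
print(f"mean fold accuracy {result.mean_accuracy:.3f}")
print(f"pooled AUC        {result.pooled.auc:.3f}")
cm = result.pooled.confusion
print(f"confusion tp={cm.tp} tn={cm.tn} fp={cm.fp} fn={cm.fn}")
```

prints (about four minutes on one CPU):

```
mean fold accuracy 1.000
pooled AUC        1.000
confusion tp=100 tn=100 fp=0 fn=0
```

The synthetic classes differ in carrier (900 vs 2200 Hz) and pulse rate
(12 vs 30 pulses/s), so a correct pipeline separates them perfectly; the
interesting checks are the per-layer goodness separation around θ and the
segmentation ground-truth recovery, both covered in `tests/`.

The same flow is available from the shell:

```sh
chirpff simulate --n-per-class 10 --out data/
chirpff segment data/*.wav --out segments/
chirpff featurize --segments segments/ --out feats.npz
chirpff train --features feats.npz --out model.npz
chirpff evaluate --features feats.npz --model model.npz --out metrics.json
chirpff report --metrics metrics.json
```

plus `mix-noise` / `denoise` for SNR robustness studies.

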
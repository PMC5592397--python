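# dcecs

Quantitative evaluation of **temporal sparsity regularizers for
compressed-sensing dynamic contrast-enhanced (DCE) MRI** of the breast.

In DCE-MRI, serial T1-weighted images are acquired while a contrast agent
washes in and out of tissue; fitting the standard Tofts–Kety model

&nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>T</sub>(*t*) = *K*<sup>trans</sup> ∫₀<sup>t</sup> *C*<sub>P</sub>(*s*) e^{*K*<sup>trans</sup>(*s*−*t*)/*v*<sub>e</sub>} d*s*

to each voxel's time course yields the transfer constant *K*<sup>trans</sup>
(1/min) and the extravascular-extracellular volume fraction *v*<sub>e</sub> —
physiological quantities used to characterize tumors. Compressed sensing
accelerates the acquisition by randomly undersampling k-space and
reconstructing via

&nbsp;&nbsp;&nbsp;&nbsp;X̂ = argmin<sub>X</sub> ½‖*A X* − *B*‖²<sub>F</sub> + α *S*(*X*),&nbsp;&nbsp;&nbsp;*A* = *M* ℱ,

solved with FISTA. The choice of the temporal regularizer *S* changes not
just the image error but the *accuracy of the fitted pharmacokinetic
parameters* — the quantity clinicians actually care about, and the two do
not rank methods the same way. `dcecs` implements the full evaluation
pipeline for six options — temporal Fourier (FT) and Haar-wavelet (WT) ℓ1
sparsity, temporal total variation (TV), second-order temporal total
generalized variation (TGV), the Casorati nuclear norm (NN), and the
zero-filled baseline (ZF) — across an ensemble of seeded Cartesian sampling
masks, measuring image SER, concordance (CCC) of the *K*<sup>trans</sup> /
*v*<sub>e</sub> maps against the fully sampled reference, and tumor means.

It is aimed at MR physics / image-reconstruction researchers choosing a
temporal constraint for quantitative DCE protocols, and ships a synthetic
single-slice acquisition with known ground-truth parameter maps so the whole
study design runs self-contained (user-supplied complex k-space drops into
the same pipeline).

## Worked example

```python
import numpy as np
from dcecs import pipeline

cfg = pipeline.ExperimentConfig(n_seeds=10, global_seed=1)
records, summary, pvalues = pipeline.run_experiment(cfg)
cols = ["ser_db_median", "ccc_ktrans_median", "ccc_ve_median",
        "tumor_mean_ktrans_median"]
print(summary[cols].round(3))
```

prints (desk-scale 48×32×30 phantom, 10 masks at target R = 4.5, weights
calibrated per model on a held-out mask):

```
             ser_db_median  ccc_ktrans_median  ccc_ve_median  tumor_mean_ktrans_median
regularizer
ZF                  13.390              0.363          0.109                     0.367
FT                  27.212              0.711          0.213                     0.397
WT                  20.708              0.930          0.191                     0.440
TV                  33.954              0.985          0.779                     0.422
TGV                 29.302              0.893          0.523                     0.443
NN                  28.241              0.372          0.237                     0.381
```

Reading: every CS method beats the zero-filled baseline in image error
(13.4 dB) — but image quality and parameter accuracy rank methods
differently. The nuclear norm produces an excellent *image* (28.2 dB) while
TV/TGV, which preserve each voxel's temporal dynamics rather than the
scene's low-rank structure, recover the pharmacokinetic maps far more
faithfully (CCC 0.89–0.99 vs 0.37 for NN on *K*<sup>trans</sup>) and put
the tumor mean *K*<sup>trans</sup> closest to the ground truth 0.425/min. If the goal
is quantitative parameters rather than pretty images, a temporal-gradient
constraint is the right choice — image SER is a misleading model-selection
criterion for quantitative DCE.

`records` holds one row per (mask seed, regularizer); `pvalues` contains
paired Wilcoxon tests (Holm-adjusted) across seeds.

A thin CLI exposes the stages individually
(`dcecs simulate | mask | recon | fit | run-all | selftest`), e.g.

```bash
dcecs simulate -o sim/ --shape 48 32 -d 30
dcecs recon --input sim/acquisition.h5 --mask-seed 7 --regularizer tv -o tv.nii.gz
dcecs run-all -o results/ --n-seeds 10
```

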
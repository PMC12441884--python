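# mrcyt — MR cytometry for time-dependent diffusion MRI

`mrcyt` implements the quantitative analysis chain used to characterize
breast-tumor microstructure from multi-b, multi-diffusion-time dMRI and to
classify lesions by immunohistochemistry (IHC) factor status and molecular
subtype.  It is aimed at imaging scientists who want a tested, reproducible
reference for cell-size ("MR cytometry") modeling with and without
transcytolemmal water exchange.

## The models

An acquisition protocol combines pulsed-gradient spin echo (PGSE, effective
diffusion time t_d = Δ − δ/3 = 70 ms) with cosine-modulated oscillating
gradients (OGSE) at 25 Hz and 50 Hz (t_d = 1/(4f) = 10 and 5 ms).  Signals
are modeled by two water pools:

* **Intracellular** — diffusion restricted in impermeable spheres of diameter
  *d*, computed with the Gaussian phase approximation over the sampled
  effective gradient waveform g(t):

  ln S_in = −γ² Σₙ Bₙ ∫₀^TE g(t) ∫₀^t g(t′) e^(−D_in (αₙ/R)² (t−t′)) dt′ dt,

  with αₙ the roots of α·j₁′(α) = 0 and Bₙ = 2(R/αₙ)²/(αₙ²−2), R = d/2.
* **Extracellular** — hindered Gaussian diffusion, S_ex = exp(−b·D_ex).

Three composite tissue models are fitted voxelwise by bounded multi-start
nonlinear least squares:

| model    | free parameters            | exchange |
|----------|----------------------------|----------|
| IMPULSED | d, v_in, D_in, D_ex        | none     |
| JOINT    | d, v_in, D_ex, k_in        | Kärger-type, D_in fixed at 1.56 μm²/ms |
| EXCHANGE | d, v_in, D_ex, k_in        | Kärger-type, D_in fixed at 1.56 μm²/ms |

The exchange engine propagates the coupled two-compartment system
dM/dt = A(t)M with instantaneous GPA intracellular and D_ex·q(t)²
extracellular dephasing rates and detailed-balance exchange
(k_out = k_in·v_in/(1−v_in)), using exact 2×2 matrix exponentials per
waveform step.  Mono-exponential ADCs per sequence, their diffusion-time
dependence ΔADC = (ADC_50Hz − ADC_PGSE)/ADC_PGSE, and the cellularity index
2(3v_in/(2π)·100)^(2/3)/d² complete the per-lesion metric set.  A cohort
statistics layer computes rank-sum and Kruskal–Wallis comparisons and
logistic-regression ROC/AUC (with stratified percentile-bootstrap 95% CIs)
for the four IHC factors and one-vs-rest molecular subtypes.

A synthetic-cohort generator reproduces the statistical structure such a
study assumes (90 lesions: 26 Luminal A / 38 Luminal B / 18 TNBC /
8 HER2-enriched, log-normal subtype-conditional microstructure priors,
Rician noise), and a Monte-Carlo random-walk simulator of restricted
diffusion serves as an independent physics oracle.

## Worked example

```python
import numpy as np
from mrcyt import (MicrostructureParams, default_protocol,
                   exchange_signal, fit_voxel)

proto = default_protocol()
truth = MicrostructureParams(d=14.0, v_in=0.58, D_ex=2.3, D_in=1.56, k_in=8.0)
S = exchange_signal(truth, proto)          # noiseless 12-acquisition signal
res = fit_voxel(S, proto, model="EXCHANGE")
print(np.round(S, 4))
print(f"d={res.params.d:.2f} um  v_in={res.params.v_in:.3f}  "
      f"k_in={res.params.k_in:.2f} /s  D_ex={res.params.D_ex:.2f} um2/ms")
```

prints

```
[1.     0.7951 0.6614 0.5085 0.4284 1.     0.6857 0.4873 0.3239 1.
 0.6796 0.4684]
d=14.00 um  v_in=0.580  k_in=8.00 /s  D_ex=2.30 um2/ms
```

— the per-acquisition signal fractions of the three sequences (each block
starts at its b = 0 anchor of 1) and the exact recovery of the generating
parameters from noiseless data.  The command-line pipeline chains the same
stages on NIfTI/CSV files:

```
mrcyt simulate -o run/sim --seed 1
mrcyt fit -i run/sim -o run/fit
mrcyt stats -i run/fit/roi_summary.csv -o run/stats
mrcyt report -i run/stats -o run/report.md
```

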
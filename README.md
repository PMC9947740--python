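# ripenmr

Depth-resolved single-sided NMR relaxometry of ripening soft cheese.

Surface-mold (Camembert-style) cheeses ripen from the rind inward: the
outer layers dry into a skin while the soft centre loses water slowly.
A single-sided (unilateral) NMR sensor can follow this non-invasively —
its permanent field gradient selects a thin sensitive slice whose depth
inside the cheese is controllable, so the same wheel can be measured
daily at several depths without cutting it. `ripenmr` implements the
full analysis pipeline for such longitudinal measurements, plus a
synthetic echo-train generator for validating every step, aimed at
researchers in food physics and time-domain NMR.

## What it computes

Echo trains from three acquisition schemes are modelled and inverted:

* **CPMG** — S(t) = ∫ P(T₂) e^(−t/T₂) dT₂, with echo times t = 2τk;
* **Saturation-recovery CPMG** —
  S(t₁, t) = ∫∫ P(T₁, T₂) [1 − e^(−t₁/T₁)] e^(−t/T₂) dT₁ dT₂;
* **Stimulated-echo CPMG** —
  S(δ, t) = ∫∫ P(D, T₂) e^(−γ²g²δ²D(Δ−δ/3)) e^(−t/T₂) dD dT₂.

The distributions P are recovered by a sparsity-regularized inverse
Laplace transform: minimise ‖KP − S‖² + λ‖P‖₁ over P ≥ 0 with a
monotone accelerated proximal-gradient (FISTA) iteration; 2D kernels are
compressed by truncated SVD first. λ can be set by the discrepancy
principle (residual = √N·σ). Peaks of the resulting T₂, T₁–T₂ and D–T₂
maps are fitted with axis-aligned Gaussians in log₁₀ coordinates and
classified into the pools of a ripening cheese: gel-network water (W),
casein-trapped water (P, T₁:T₂ ≳ 10 from chemical exchange), liquid fat
(F, T₁:T₂ ≈ 1), and in diffusion maps an aqueous pool (WP) plus two fat
pools (F1, F2) whose D values reflect distinct fat-globule sizes.

Because the sensor's gradient is always on, fast-diffusing water shows a
shortened *apparent* T₂ under CPMG:

    1/T₂,app = 1/T₂ + γ²τ²g²D/3

e.g. a 488 ms free-water T₂ appears as ≈36 ms at τ = 100 µs,
g = 7.28 T/m, D = 2·10⁻⁹ m²/s. Depth-resolved ripening metrics — the
fifth-echo intensity S(t = 1 ms), its SNR, and the *drying time* of a
layer (first day its SNR stays below 30) — summarise rind formation.

## Worked example

Simulate one day-1 T₁–T₂ measurement of the soft centre at SNR 500,
invert it and fit the peaks:

```python
import numpy as np
from ripenmr import ilt, models, peaks, profile, synth

mix = synth.default_component_table(day=1, depth=5e-3)
scheme = synth.default_scheme("satrec_cpmg")
sigma = synth.noise_sigma_for_snr(500, mix, scheme)
rng = np.random.default_rng(7197359)
train = models.EchoTrain(
    scheme,
    models.forward_signal(mix, scheme).values
    + rng.normal(0, sigma, scheme.shape),
    noise_sigma=sigma)

rmap = ilt.invert_2d(train, ilt.default_t1t2_grid(48, 64))
print(f"lambda = {rmap.regularization.lam:.3g}, "
      f"residual = {rmap.residual_norm:.4f}")
for f in peaks.fit_peaks(rmap):
    t1, t2 = (v * 1e3 for v in f.center_si)
    print(f"{f.label}: T1 = {t1:6.1f} ms  T2 = {t2:6.2f} ms  "
          f"area = {f.area:.4f}")

series = profile.series_from_trains(
    synth.simulate(synth.RipeningScenario.default(), "cpmg"))
print("drying day at 2 mm:", profile.drying_time(series, 2e-3))
print(f"centre intensity decrease: "
      f"{profile.percent_decrease(series, 5e-3):.1f} %")
```

prints

```
lambda = 0.166, residual = 0.2456
W: T1 =  308.1 ms  T2 =  60.08 ms  area = 0.0040
F: T1 =   88.9 ms  T2 =  70.98 ms  area = 0.0008
P: T1 =  154.1 ms  T2 =   2.34 ms  area = 0.0007
drying day at 2 mm: 8
centre intensity decrease: 32.7 %
```

The three fitted peaks recover the generator's ground truth — water at
(320, 60) ms, casein-trapped water at (160, 2.4) ms with its large
T₁:T₂ ratio, fat at (100, 70) ms — within a few percent (T₁ estimates
carry the larger uncertainty because the recovery curve encodes T₁ with
only 32 points). The skin layer at 2 mm loses its signal on day 8, and
the soft centre's fifth-echo intensity drops by about a third over the
20-day run.

The same steps are available from the shell:

```
ripenmr simulate --out run/          # writes echo-train dataset files
ripenmr invert2d --input run/satrec_cpmg_day01_depth5mm.dat --out map.csv
ripenmr fitpeaks --map map.csv --out peaks.csv
ripenmr report --inputs run/ --out summary.json
```

## Layout

| module | contents |
| --- | --- |
| `ripenmr.models` | acquisition schemes, relaxation/diffusion kernels, apparent-T₂ and displacement arithmetic |
| `ripenmr.synth` | synthetic multi-depth, multi-day ripening-run generator |
| `ripenmr.ilt` | regularized 1D/2D inverse Laplace transforms |
| `ripenmr.peaks` | peak detection, log-space Gaussian fits, classification, trajectories |
| `ripenmr.profile` | fifth-echo intensity, SNR, drying time, percent decrease |
| `ripenmr.io` / `ripenmr.cli` | text file formats and the `ripenmr` command |

See `docs/methods.md` for the modelling assumptions, parameter
defaults and numerical choices.
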
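# Methods

This note documents the models, defaults and numerical choices behind
`ripenmr`, and what validation on synthetic data does and does not show.

## Signal model

All computation is in strict SI units (s, m, T); only I/O and display
layers use ms, mm, µs. The instrument constants default to a unilateral
magnet operating at 13.29 MHz for protons with a 7.28 T/m static
gradient; the proton gyromagnetic ratio is 2.6752218744·10⁸ rad s⁻¹ T⁻¹.

A sample is modelled as a discrete mixture of relaxation pools, each
with an amplitude, T₁, T₂ and self-diffusion coefficient D. Forward
signals are sums of separable kernel products:

* CPMG: `exp(-t/T2)` on the echo-time grid `t = 2·tau·k`, k = 1…n.
* Saturation recovery: the indirect factor `1 - exp(-t1/T1)`. The
  saturation pulse train is modelled as perfect saturation (initial
  magnetization zero); its pulse-level details only serve to null
  magnetization and carry no information.
* Stimulated echo in a constant gradient: the Stejskal–Tanner-form
  attenuation `exp(-gamma^2 g^2 delta^2 D (Delta - delta/3))`. This is
  the standard constant-gradient form; the scheme validator requires
  `Delta - delta/3 > 0` for every delta.

Diffusion in the always-on gradient also shortens the T₂ observed under
CPMG: `1/T2app = 1/T2 + gamma^2 tau^2 g^2 D / 3`. `apparent_t2`
implements this, accepts an infinite-T₂ sentinel for the free-diffusion
limit, and is exposed as an optional weighting inside `forward_signal`
(`apply_gradient_weighting`). The flag defaults to **off** because the
synthetic generator stores pool T₂ values at their *observed*
(already gradient-weighted) positions; turning the flag on is for
studying the correction itself, e.g. how a 488 ms water T₂ collapses to
≈36.6 ms at tau = 100 µs and D = 2·10⁻⁹ m²/s.

## Synthetic ripening runs

The generator emulates a 20-day ripening run of a soft surface-mold
cheese measured at depths of 2, 2.5, 3, 4 and 5 mm. Ground truth per
(day, depth) is a four-pool mixture:

| pool | T₁, T₂ (day 1) | D (day 1) | amplitude share (day 1) |
| --- | --- | --- | --- |
| W (gel water) | 320, 60 ms | 1·10⁻⁹ m²/s | 0.70 |
| P (casein-trapped water) | 160, 2.4 ms | 1·10⁻⁹ m²/s | 0.10 |
| F1 (fat, small globules) | 100, 70 ms | 1·10⁻¹⁰ m²/s | 0.10 |
| F2 (fat, large globules) | 100, 70 ms | 1·10⁻¹¹ m²/s | 0.10 |

The W:P:F = 0.7:0.1:0.2 split is a free parameter of the generator (a
plausible dairy composition), not a measured value. The fat pool is
split evenly over two diffusion pools at 10⁻¹⁰ and 10⁻¹¹ m²/s — D
values chosen inside the reported bounds for two fat-globule size
classes. A separate three-pool table (`day1_t2_mixture`) places the
pools at their *1D-observed* T₂ positions 10/30/100 ms with the middle
pool dominant (0.2/0.6/0.2); the 1D positions differ from the T₁–T₂
ones because the 1D experiment sees a stronger diffusion-weighted blend.

Trajectories between the day-1 anchors and day-20 endpoints are
log-linear in day (progress coordinate `log(day)/log(20)`), reflecting
fast early change and slow late change:

* total amplitude in the centre falls 30% by day 20 (sample "1") or
  13% (sample "2");
* the W amplitude *share* falls 20%, with P and F picking up the slack
  1:2, so their relative integrals grow;
* all T₁/T₂ drift down 30%; the aqueous D drifts down 30%; fat D stays
  constant (stable globule sizes);
* depth factors at day 1: 0.64 / 0.75 / 0.85 / 0.95 / 1.00 from 2 to
  5 mm (the skin starts 36% below the centre);
* drying depths (2, 2.5, 3 mm) decline linearly to zero amplitude at
  their drying day (8, 12, 16); from that day on the layer contributes
  pure noise.

Noise is additive zero-mean Gaussian on every sample point (a
magnitude/Rician option is deliberately not modelled; real-channel data
are assumed phased by the acquisition software). `noise_sigma_for_snr`
calibrates sigma so the measured fifth-echo SNR hits a target in
expectation; the default scenario uses SNR 500 at the day-1 centre. The
default seed is 7197359.

Note two deliberate consequences: the *measured* fifth-echo percent
decrease (≈32.7% / 16.3%) sits a couple of points above the amplitude
anchor (30% / 13%) because the downward T₂ drift and pool
redistribution also depress the 1-ms sample slightly; and at the
2.5/3 mm depths the SNR < 30 rule fires a day before the zero-signal
day because the linear amplitude ramp passes through the SNR threshold
first — the depth *ordering* of drying is what the generator
guarantees. At 2 mm the two definitions coincide (day 8).

What the generator does **not** emulate: spatial continuity between
depths (layers are independent), exchange between pools, B₁/off-
resonance effects of the sensor, temperature drifts, and any
microbiology. Passing tests therefore demonstrate that the *pipeline*
is correct and well-conditioned under realistic noise, not that real
cheese follows these trajectories.

## Inversion

`invert_1d`/`invert_2d` solve

    min_{P >= 0}  ||K P - S||_2^2 + lambda ||P||_1

on log-spaced grids (defaults: T₂ ∈ [0.1, 1000] ms × 128; T₁ ∈
[1, 5000] ms × 100; D ∈ [10⁻¹³, 10⁻⁸] m²/s × 100 — wide enough to
bracket every pool above). The l1 penalty is the default
(sparsity-promoting, fast-ILT style); no smoothness penalty is applied.
Solver facts:

* Monotone FISTA with adaptive restart: a proximal candidate that would
  increase the objective triggers a momentum restart, so the recorded
  objective history is non-increasing and stalls cannot persist.
* Deterministic zero initialization; no randomness anywhere in the
  inversion.
* Stopping rule: relative objective decrease < 10⁻⁸ on three
  consecutive accepted steps; iteration cap 2·10⁵. The cap was sized
  from measured behaviour — realistic noisy 2D problems need
  3–6·10⁴ iterations to reach the 10⁻⁸ tail, so a smaller cap would
  turn legitimate solves into convergence errors. Hitting the cap
  raises an error carrying the last iterate.
* 2D kernels are compressed per axis by truncated SVD (singular values
  ≥ 10⁻⁴ of the largest, at most 24 per axis) before solving; the
  reported residual is always computed in the full data space. On small
  instances the compressed and uncompressed solutions agree to < 1% of
  the peak weight.
* An all-zero input returns a flagged null map rather than an error.

`choose_regularization` implements the discrepancy principle: find
lambda (log-bisection between 10⁻⁶·lambda_max and lambda_max, where
lambda_max is the smallest lambda with an all-zero solution) such that
the residual matches √N·sigma within 10%. Bisection probes run at a
loosened tolerance (10⁻⁷) since only ~10% residual accuracy is needed;
with zero noise the ladder floor is returned. Unattainable targets
return the boundary lambda with a warning flag. Since the residual is
monotone in lambda, the chosen lambda is monotone in sigma.

## Peak quantification

Peaks are local maxima (8-neighbourhood in 2D) above 2% of the global
maximum. Each is fitted with an **axis-aligned Gaussian in log₁₀
coordinates** over a ±5-grid-step window — relaxation peaks are
near-symmetric on log axes, and the axis-aligned form keeps the
parameter count at 5 (2D), stable on small windows. Grid nodes closer
to a competing peak than to the fitted one are masked out of the
window (a nearest-seed partition), otherwise a neighbour's shoulder
drags the fit; this mattered for the fat peak, whose T₂ is only one
grid step from the water peak's. The reported area is the analytic
integral of the fitted Gaussian (√(2π)Aσ in 1D, 2πAσₓσᵧ in 2D), which
matches numerical quadrature of the fitted surface to 10⁻⁶. Sigma is
bounded below at 0.2 grid steps so single-node spikes produced by the
l1 penalty still yield a finite, meaningful fit.

Classification defaults (all configurable): on T₁–T₂ maps a peak with
T₂ > T₁ is an unphysical inversion artifact; T₁:T₂ ≥ 10 is
casein-trapped water (chemical exchange shortens T₂ strongly);
otherwise W if T₂ ≤ 65 ms else F. The W/F boundary is a serviceable
default — the two pools are only 60 vs 70 ms apart in T₂ — their
robust separation comes from T₁ (320 vs 100 ms), which is why peaks
are matched across days by label first and nearest log-distance
second. On D–T₂ maps: D ≥ 3·10⁻¹⁰ m²/s is the aqueous pool (water and
casein-trapped water merge here because exchange is fast on the 5-ms
diffusion delay), and the two fat pools split at 3·10⁻¹¹ m²/s. Labels
follow the D ranges; interpreting which pool is the smaller globule
class (via z = √(2ΔD)) is left to the user.

Cross-day trajectories (`peak_table`) keep, per day and label, the
largest-area peak (or nearest to the label's previous centre when
several compete), skip artifact labels, record absent labels as absent
rather than interpolating, and can normalize areas to the day-1 total.

## Ripening metrics

* Intensity: the fifth CPMG echo, i.e. S(t = 1 ms) at the default
  200 µs echo spacing — late enough to exclude rigid macromolecular
  protons (T₂ ≈ 20–30 µs), early enough to retain all mobile pools.
* SNR: fifth echo divided by the standard deviation of the last 10% of
  echoes after mean removal. The estimator is slightly conservative
  when slow components still decay in the tail; at the SNR ≈ 30
  threshold where it matters the tail is noise-dominated and the bias
  is negligible. A zero-variance tail with signal returns +inf.
* Drying time: first day with SNR below threshold (default 30) such
  that *every* later observed day is also below — the persistence rule
  ignores single-day noise dips. Raising the threshold can only move
  the drying day earlier.
* Percent decrease: 100·(first − last)/first of the intensity at a
  depth, i.e. a day-1 vs day-20 endpoint comparison.

## Validation problem sizes

The validation harness (`scripts/acceptance.py` and
`tests/test_acceptance.py`) uses the acquisition geometry the generator
emulates — 512 echoes at 2τ = 200 µs, 32 log-spaced t₁ in
1–2500 ms, 32 log-spaced δ in 0.1–5 ms with Δ = 5 ms — at SNR 500 over
10 seeds, with inversion grids of 48×64 (T₁–T₂), 64×64 (D–T₂) and 128
(1D T₂): fine enough that one grid step (≈0.06–0.08 decade) is well
inside the ±25% recovery tolerance, small enough that a full 2D
inversion takes ~1–2 s. The discrepancy lambda is chosen on the first
seed and reused, so all seeds see identical regularization.

Typical recovered centres: P at (≈154, ≈2.34) ms, W at (≈308, ≈60) ms,
F at (≈89, ≈70.8) ms, aqueous D ≈ 1.0·10⁻⁹ m²/s — within a few percent
of truth on T₂/D and within ~10% on T₁ (the indirect dimension has
only 32 points). The dominant 1D peak lands at ≈34 ms vs the 30 ms
truth: the l1 inversion partially absorbs the flanking 100 ms pool
into the dominant peak, a known upward bias of sparse multiexponential
inversion when components are ~0.5 decade apart.

## Known limitations

* T₁–T₂–D three-dimensional inversion, uniform-penalty (smoothness)
  regularization and Bayesian inversion are out of scope.
* Rotated (covariant) 2D Gaussians are not fitted; strongly tilted
  ridges will be summarized by their axis-aligned envelope.
* The reproducibility-based artifact criterion used with repeated
  acquisitions cannot be expressed in a single-acquisition pipeline;
  only the T₂ > T₁ physical criterion is automated.
* No reader for proprietary spectrometer formats; data enter through
  the documented text format (`ripenmr.io`).
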
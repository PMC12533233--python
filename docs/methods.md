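# Methods

## The model of a circumnutating dyad

The generator treats each plant as a self-sustained oscillator whose
rhythm is weakly adjusted by its partner — the standard framing for
synchronization of autonomous rhythms. Phases follow the stochastic
Adler/Kuramoto pair

    dφ_i = [ω_i + K_i sin(φ_j − φ_i − Δ_i)] dt + σ_i √dt ξ,   ξ ~ N(0,1),

integrated by Euler–Maruyama at the sampling step (an internal substep
factor exists but the analysis only ever sees the sampled grid). For
noise-free unidirectional coupling the phase difference ψ = φ₁ − φ₂ obeys
the Adler equation ψ̇ = Δω − K sin ψ, which locks at ψ* = arcsin(Δω/K)
whenever |Δω| ≤ K; the test suite verifies this fixed point to 1e-3 rad
over 10⁴ steps. The tendril tip traces a circle of radius A in the
horizontal (x, z) plane — nutation evolves mainly horizontally — with
linear vertical growth g·t on y and i.i.d. Gaussian measurement noise on
all three coordinates.

### Generator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| dt | 180 s | one frame per 3 min (0.0056 Hz acquisition) |
| n_samples | 559 frames | ≈ 1677 min of movement, the study population mean |
| ω | 2π/8000 rad/s | base nutation period 8000 s (~0.125 mHz, the band where coherence concentrates) |
| heterogeneity | 0.24 | relative sd of ω and duration across dyads, matching the duration spread (sd/mean ≈ 397/1677) |
| K | 4·10⁻⁴ rad/s | weak-coupling locking regime: 2K exceeds the typical within-dyad |Δω| at the default heterogeneity |
| σ_phase | 8·10⁻³ rad/√s | phase diffusion strong enough that independent plants decohere over a nutation period (2σ²T ≈ 1 rad² at T = 8000 s) yet weak against the locking rate 2K |
| A | 25 mm | plausible tendril nutation radius for plants ~200 mm tall |
| σ_obs | 1 mm | tracking error at the millimetre scale |
| g | 1.3·10⁻⁴ mm/s | ~200 mm of growth over ~18 days |

These values were fixed once, as the conditions the pipeline is exercised
under; they are calibration knobs of a phenomenological generator, not
estimates of real plants' coupling. What the generator deliberately does
**not** reproduce: amplitude drift and eccentric/irregular nutation orbits,
nonstationary frequency (real nutation slows and accelerates with
temperature and growth phase), asymmetric handler/grasper kinematics, and
any mechanistic coupling pathway (mechanical, chemical or optical).
Passing tests therefore demonstrate that the *pipeline* detects weak phase
coupling against a matched null — not that real pea plants couple this
way.

Onsets are drawn per dyad (members share them, as simultaneously recorded
plants must) so that the pseudo-dyad alignment rule — cut each series at
its own onset, truncate to the shorter post-onset duration — has real work
to do. Pseudo pairings are uniform derangements sampled by rejection:
with 8 dyads a permutation is a derangement with probability ≈ 1/e, so
rejection is cheap and exactly uniform.

## Wavelet choices

- **ω₀ = 6**: the admissibility-friendly Morlet standard; Fourier factor
  FF = 4π/(ω₀ + √(2+ω₀²)) ≈ 1.0330, so scale ≈ period.
- **Grid**: s₀ = 2Δt, dj = 1/12, n_scales = ⌊log₂(NΔt/s₀)/dj⌋ + 1 — the
  conventional dyadic grid reaching the series duration.
- **Transform**: FFT convolution of the mean-removed signal, zero-padded
  past the next power of two so large-scale wavelets cannot wrap around;
  unit-energy normalisation √(2πs/Δt) in the frequency domain.
- **Smoothing**: per-scale Gaussian in time with sd s/(√2 Δt) samples,
  then a boxcar across 0.6 octaves of scale (rounded to an odd window so
  the operator stays centred). Both kernels are normalised with
  reflecting/nearest edges, so constants are preserved and, because the
  same positive weights smooth numerator and denominator, Cauchy–Schwarz
  guarantees R² ≤ 1 up to float noise. Excursions beyond 1 + 1e-9 raise
  rather than clip silently — they indicate a broken kernel.
- **COI**: coi(t) = FF·√2·Δt·min(t + ½, n − ½ − t), the Morlet e-folding
  cone. The mean-WTC statistic averages **all** pixels by default (the
  headline convention); an inside-COI policy is computed alongside as a
  robustness check, and the analysis scripts report both. Statistics on
  the normalized maps do not exclude COI pixels either — a documented
  limitation, since each dyad's COI occupies a different normalized-time
  region.

The FFT path is cross-checked in the tests against a fully independent
brute-force oracle (time-domain convolution, explicit kernel sums); mean
absolute r² disagreement inside the COI is required below 0.05, the slack
covering boundary-handling dialect differences.

## Inference

- **Exact Mann–Whitney U**: U counts pairs with a > b plus half the ties.
  For pooled n ≤ 20 and tie-free data the p-value comes from the exact
  null distribution of U (integer counting recurrence, equivalent to full
  enumeration over all C(m+n, m) labelings — the suite checks equality on
  500+ random cases). Two-sided p doubles the smaller tail, capped at 1;
  with ties or larger samples a tie-corrected normal approximation with
  continuity correction is used and flagged.
- **Sidedness of the headline contrast**: two-sided by default. For
  n = 8 vs 8 this convention reproduces published exact p-values of this
  design from the corresponding δ exactly (δ = 0.71875 ⇒ U = 55 ⇒
  p = 2·95/12870 = 0.014763), which is how the default was fixed;
  `alternative="greater"` is available. The pixel-wise map test is
  hard-wired one-tailed (real > pseudo) — the directional hypothesis.
- **Cliff's delta** uses direct pair counting; for tie-free data
  δ = 2U/(mn) − 1, an identity the tests enforce.
- **Time normalization**: each frequency row is linearly interpolated onto
  n_bins = 100 equally spaced points of 0–100% movement duration, giving
  the percent-of-movement reading used to interpret the averaged map.
  A single global scale grid — sized from the shortest aligned series —
  guarantees all dyads share the frequency axis; longer series simply
  resolve extra low-frequency scales that the shared grid omits.
- **FDR**: Benjamini–Hochberg step-up across *all* map pixels at once
  (one corrected map, not per-row), q < 0.05. The implementation
  delegates to statsmodels after validating p ∈ (0, 1]; a hand-rolled
  step-up oracle pins the arithmetic in the tests.

## Problem sizes in the committed runs

The analysis scripts use the full default series length (559 frames);
replicate power/type-I studies use 512-frame series, 8 dyads per group and
50 replicates per arm, sizes at which the exact 8-vs-8 test and the
0.05-band wavelet cross-checks are all well conditioned. Degenerate
inputs are rejected rather than patched: signals shorter than 4 samples,
aligned overlaps shorter than 2 samples, empty groups, p-values outside
(0, 1], and coherence above 1 + 1e-9 all raise.

## Known limitations

- The exact test's tie handling is a fallback to the normal
  approximation, not a tie-adjusted exact enumeration; coherence values
  are continuous so ties essentially never occur in practice.
- The pixel-wise test treats pixels independently in the BH correction;
  wavelet smoothing induces strong spatial correlation between
  neighbouring pixels, so the FDR guarantee is over the pixel ensemble
  under positive dependence (where BH remains valid) and significant
  regions should be read as clusters, not pixel counts.
- Numerical equality with any particular commercial toolbox's coherence
  matrices is not guaranteed: smoothing-window dialects differ, and the
  smoothing convention here (Gaussian time kernel, 0.6-octave boxcar) is
  pinned and configurable rather than matched to an external binary.
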
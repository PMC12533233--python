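# plantsync

Wavelet-coherence analysis of movement synchrony between paired
circumnutating plants.

Climbing plants explore their surroundings with circumnutation — a slow,
quasi-periodic rotation of the growing tip. When two pea plants are grown
together without a support they intertwine their tendrils, and the question
this package addresses is whether that joint behaviour involves genuine
temporal coordination: do the two plants synchronize their nutation
rhythms, beyond what co-growing but non-interacting plants would show?

The package is for researchers analysing paired movement time series
sampled at slow, fixed rates (here one 3D tendril-tip position every
180 s), and it implements the full inferential chain:

1. **Morlet CWT.** Each position series (x or z, the horizontal axes) is
   transformed with the analytic Morlet wavelet
   `ψ(η) = π^{-1/4} e^{iω₀η} e^{-η²/2}` (ω₀ = 6) on a dyadic scale grid
   `s_j = s₀·2^{j·dj}` with `s₀ = 2Δt`, `dj = 1/12`.
2. **Wavelet coherence (WTC).** The local squared correlation of two
   transforms,

   `R²(s,t) = |S(s⁻¹ W_ab)|² / ( S(s⁻¹|W_a|²) · S(s⁻¹|W_b|²) )`,

   with `W_ab = W_a W_b*` and `S` a smoothing operator (Gaussian in time,
   0.6-octave boxcar in scale). `R² ∈ [0,1]` at every time and scale; the
   cone of influence marks pixels distorted by edge effects.
3. **Dyad statistic and group inference.** Each dyad's synchrony score is
   the mean of its WTC matrix. Real dyads (plants grown and recorded
   together) are compared with pseudo dyads (plants re-paired across dyads
   and aligned from their own movement onsets up to the shorter duration)
   using an **exact Mann–Whitney U test** and **Cliff's delta**
   `δ = (#{a>b} − #{a<b})/(n_a n_b)`.
4. **Where in time and frequency?** Coherence maps are resampled onto a
   common percent-of-movement grid, averaged over real dyads, and compared
   pixel-by-pixel with a one-tailed (real > pseudo) exact Mann–Whitney
   test under Benjamini–Hochberg FDR control across all pixels.

A coupled-oscillator generator (stochastic Adler dynamics: two
self-sustained phase oscillators with weak mutual coupling, phase
diffusion, circular nutation plus vertical growth and measurement noise)
produces populations with the statistical structure the analysis assumes,
so the entire pipeline is testable without any downloaded data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
population of 8 real dyads plus their 8 pseudo shuffles:

```bash
python analysis/01_simulate_dyads.py
python analysis/02_wavelet_coherence.py
python analysis/03_group_comparison.py
python analysis/04_average_map_pixelwise.py
python analysis/05_replicate_power.py
```

Output of the run committed here (seed 2026):

```
movement duration: mean 1692.0 min, sd 412.7 min
axis x (two-sided): U=56, p=0.010412, Cliff's delta=0.75000 (exact)
axis z (two-sided): U=60, p=0.001865, Cliff's delta=0.87500 (exact)
axis x: 1068/9000 pixels significant at q<0.05 (11.9%)
```

Read: out of the 64 (real, pseudo) dyad pairs on the x axis the real dyad
had the higher mean coherence in 60 (U = 56 ⇒ δ = 0.75), an ordering that
extreme in 1.0% of all exact group relabelings — coupled dyads synchronize
detectably above the co-growth baseline, and the map localizes where. The
replicate study (script 05) detects the coupling in 100% of 50 simulated
experiments while flagging 6% false positives when coupling is absent
(nominal 5%).

The same pipeline runs from the command line (`plantsync all --seed 3
--out-dir run/`) or on real trajectory CSVs via a dyad manifest
(`plantsync wtc --manifest ...`); the trajectory CSV layout is documented
in `plantsync.trajectory`. The deposited pea-plant trajectories
(doi:10.5281/zenodo.15606745) can be analysed this way once converted to
that layout.

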
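# Methods

## Measurement model

The simulated instrument is a reflection-mode terahertz time-domain
spectrometer.  A p-polarised single-cycle pulse travels inside a z-cut
quartz window (n_Q = 2.10, α_Q < 1 cm⁻¹) and strikes the upper window
surface at the internal angle θ₁ = asin(sin θ₀ / n_Q) ≈ 20° for θ₀ = 45°
external incidence.  The *reference* trace E₀(t) is the reflection with
air above the window; a *measurement* E₁(t) is the reflection with a
sample (spoof material, overlay, or finger) pressed onto it.  Because both
are defined at the same surface, the window's own propagation and
dispersion cancel and are not modelled.

Reflection is computed per frequency from the p-polarised Fresnel
coefficient written in terms of ε = N² and the normal wavevector
component k_z = (ω/c)·√(N² − N_Q² sin²θ₁):

    r_p(i→j) = (ε_i k_zj − ε_j k_zi) / (ε_i k_zj + ε_j k_zi)

with the principal complex square root (forward-propagating, decaying in
every passive medium).  The sign convention makes r positive going from
the higher index into the lower (quartz→air > 0, quartz→wet tissue < 0)
and reduces to (n_Q − n)/(n_Q + n) at normal incidence; this is the
convention under which the observed pulse polarities come out right.
Time traces are synthesised as E₁ = IFFT[ r̄(ν) · FFT(E₀) ], where
r̄ = r_sam/r_air is the air-referenced relative coefficient and the bar
denotes complex conjugation — the optics is written in the physics
e^{i(kz−ωt)} convention, the DFT analyses with the opposite temporal
sign, and conjugating the transfer function is what keeps echoes causal.

Thin overlays add internal round trips.  With r₀₁ the window/overlay and
r₁b the overlay/backing coefficient, one round trip contributes the
factor φ = exp(2i·(ω/c)·d·N_s cos θ_s); the n-echo truncation is

    r = r₀₁ + (1 − r₀₁²) r₁b φ Σₘ (−r₀₁ r₁b φ)ᵐ,

whose full sum is the Airy formula and agrees with an independent
characteristic-matrix computation to better than 1e−6 (tested).  The
corresponding echo delay is τ = 2 n d cos θ_s / c — the cosine multiplies
because the reference plane wave advances while the ray zigzags — and the
depth estimator inverts exactly this relation,
d = c·τ/(2 n cos θ₁) with c = 299.792 µm/ps.  Two echoes are the default
(`orders=2`); `orders=None` selects the closed-form full series.

A genuine finger is a two-layer stack: stratum corneum (SC) of thickness
0.2–0.6 mm over semi-infinite viable epidermis.  The wetter epidermis has
the higher index, which fixes the sign of the internal echo, and a
`pressure_factor` in (0, 1] scales the overall amplitude the way harder
pressing lowers the measured reflection.

## Material tables

Materials are stored as (ν, n, α) tables in THz and cm⁻¹; the extinction
coefficient follows from α = 4πνκ/c at the query frequency, linear
interpolation between nodes, constant extrapolation outside (avoids
nonphysical negative values).  The built-in library encodes smooth
parametric trends pinned to published anchor values rather than digitised
spectra — acceptance-level behaviour (phase signs, group separations)
depends only on the anchors, not on curve detail:

| material   | n(ν)                              | α(ν) cm⁻¹              | anchors hit |
|------------|-----------------------------------|------------------------|-------------|
| quartz     | 2.10                              | 0.2                    | n ≡ 2.10, α < 1 |
| silicone   | 1.73 − 0.02ν                      | 1.2ν²                  | group I: n 1.4–1.9, α < 10 |
| latex      | 1.55 − 0.015ν                     | 0.8 + 1.8ν^1.5         | 〃 |
| plasticine | 1.87 − 0.03ν                      | 1.5 + 2ν               | 〃 |
| Play-Doh   | 2.25 + 0.25·e^−(ν−0.1)/0.35       | 70ν^1.25               | n(0.1) = 2.5 → ≈2.2; α(1) = 70 |
| water/gelatin | 2.15 + 1.4·e^−ν/0.55           | 220ν/(ν+0.3)           | α(1) ≈ 170 |
| skin (SC)  | 1.98 + 0.6·e^−ν/0.65              | 15 + 15ν + 35ν²        | mean n ≈ 2, crosses 2.10 near 1 THz |
| epidermis  | 2.40 + 0.9·e^−ν/0.6               | 80 + 150ν              | wetter than SC |

Two design points deserve explanation.  The Play-Doh plateau sits at 2.25:
at 2.2 the index contrast against the 2.10 window is so small that the
absorption-driven phase rotation flips the main-peak sign, contradicting
the observed negative phase.  The SC absorption grows superlinearly so
that κ = αc/4πν — and with it the reflectance — *rises* from 1.0 to
1.5 THz; this is what makes the genuine fq₄ feature (see below) robust.

Hybrid "what-if" materials (`compose_artificial`) take n(ν) from one
source and κ(ν) from another (m1 = silicone-n + Play-Doh-κ, m2 the swap),
for probing the classifier against materials outside the library.

## Signal processing

* **Apodization**: 4-term Blackman–Harris taper, asymmetric (independent
  rise/fall spans around a centre), unity in the flat region, endpoint
  value ≈6e−5.
* **Power spectra**: one-sided, Parseval-normalised (weight 2 on interior
  bins), Δν = 1/span = 0.025 THz on the default grid.
* **Reflectance**: pointwise power ratio restricted to the useful
  0.1–2.0 THz band; bins where the reference power falls below 1e−10 of
  its maximum are dropped.  R may exceed 1 because air, not a mirror, is
  the reference.
* **Response function**: rf = IFFT[FFT(filter)·FFT(E₁)/FFT(E₀)] with
  filter(t) = e^{−t²/HF²}/HF − e^{−t²/LF²}/LF, t in sample-index units on
  the wrapped axis (HF = 2048 equals the default trace length, which is
  what identifies the units), LF = 12.  The spectral division is
  regularised by flooring |FFT(E₀)| at 1e−6 of its maximum (phase kept):
  synthetic noise does not guarantee the high SNR that purge-and-average
  acquisition provides.  Delay recovery is exact to ±1 sample with
  amplitude linearity within 5% over delays of 1–100 samples (tested).

## Two-criteria classifier

1. **Time domain.** Find the maximum (t₀, a₀) in the fixed 9–11 ps window
   set by the window-surface position, then the minima a₂ (earlier side)
   and a₁ (later side) within ±2 ps, and q = a₁/a₂ with signed
   amplitudes.  Low-index (Group I) overlays reflect with positive phase
   and a deeper trailing undershoot: q > 0.85 ⇒ spoof.  Negative-phase
   reflections (fingers, Group II) put their deepest minimum *before* the
   rebound maximum, so q ≪ 0.5.  Ties break towards earlier times;
   non-negative "minima" raise a degeneracy error rather than silently
   flipping sign.
2. **Frequency domain** (only for traces that pass the q test).  On the
   max-normalised reflectance: fa₁/fa₃ = max/min on 0.18–0.5 THz, fa₂ =
   R(0.30 THz), fa₄ = R(1.0 THz), fa₅ = R(1.5 THz) (point reads by linear
   interpolation — the 0.025 THz grid does not contain 0.30 exactly), and
   fq₁ = fa₁/fa₂, fq₂ = fa₁/fa₃, fq₃ = fa₂/fa₃, fq₄ = fa₅/fa₄.  A spoof
   is declared only when all four pass: fq₁ > 4.5, fq₂ > 3.5, fq₃ < 1.21,
   fq₄ < 1.1.  All ratios are invariant under positive scaling of R.

Evaluation reports TDR (correctly classified fraction, %) and
FDR = 100 − TDR per truth class, plus count-weighted cumulative rates.

## Synthetic corpus

`generate_dataset` writes a reference trace, 144 genuine and 136 spoof
traces, and a JSON manifest.  Defaults reproduce the study conditions:

* **Reference pulse** — built in the frequency domain: amplitude spectrum
  ν²·e^{−ν/ν_d} (photoconductive-antenna-like: steep roll-off below
  0.2 THz, broad maximum, smooth decay), minimum phase via the
  homomorphic (cepstral) construction, plus a weak advanced replica
  (spectral factor 1 − 0.4·e^{2πiνΔ}) that carves the small leading
  undershoot of real reference traces.  The family is dilated until the
  Hilbert-envelope FWHM measured on the actual grid equals the requested
  0.4 ps.  The minimum-phase fast-attack/ringing-decay shape is not
  cosmetic: it is what keeps the q-minima ordering stable when lossy
  high-index samples rotate the reflection phase by tens of degrees, and
  the suppressed low-frequency content is what prevents water-like media
  from smearing the trace into a pedestal.  In-band spectral power stays
  above −55 dB of the band maximum.
* **Noise** — white Gaussian time-domain noise scaled so the expected
  power-spectral signal-to-noise ratio at 0.6 THz is 55 dB (verified by
  Monte Carlo to ±3 dB); the averaging of repeated acquisitions is
  emulated as a single draw at the post-average SNR.
* **Subjects** — per-(seed, index) draws: SC thickness uniform on
  0.2–0.6 mm, SC absorption scale 0.85–1.15, epidermis contrast 0.25–0.55,
  baseline pressure 0.75–1.0, index offset ±0.015.  The SC/epidermis
  contrast — in index *and* absorption — decays as e^{−ν/0.4 THz}, so the
  internal echo and its interference fringes live below ≈0.8 THz, where
  measured finger spectra show them.  Inter-person variability is thus
  hydration- and thickness-dominated, which is also what keeps the
  noise-free genuine false-rejection rate at exactly zero (verified over
  200 draws): the fringes cannot wander onto the fq₄ feature points.
  Repetition jitter touches only the pressure scale (×0.85–1.0) and a
  ±0.15 ps placement shift.
* **Spoof plan** — 54 Group I traces (per material: 6 thick slabs, 6
  thin-over-air, 6 thin-over-finger at 0.5 mm) and 82 Group II traces
  (gelatin 1–3 mm incl. a fingerprinted cast, Play-Doh 0.5 and 3 mm),
  i.e. the ≈40/60 split of the study.  Generation is fully deterministic:
  per-trace generators are keyed by the trace coordinates, and
  regeneration is byte-identical (tested).

## Numerical choices

* DC and sub-resolution bins evaluate materials at the first positive
  frequency (flat in r); pulses carry no DC power, so this is inert.
* θ₁ is computed once from n_Q at a reference frequency, not
  per-frequency: quartz is nearly dispersion-free and a single angle
  matches the instrument description.
* Echo picking (`find_echoes`) is a greedy max-|amplitude| search with a
  suppression guard and a half-span delay cap (wrap-around mirror).
* Degenerate inputs raise typed errors (`DegenerateSignalError`) instead
  of returning sign-flipped or infinite ratios.

## Limitations

* **Specular plane-wave optics.**  The model reproduces phase signs,
  echo structure, delays and group separations, but measured reflectance
  curves of water-rich media fall much more steeply between 0.18 and
  0.3 THz than any smooth specular Fresnel response can (contact quality,
  beam geometry and diffuse scattering all sharpen measured spectra).
  Consequently the frequency-domain criterion, whose thresholds
  (fq₁ > 4.5) encode that measured steepness, essentially never fires on
  the synthetic corpus: Group II spoofs are labelled genuine, and the
  cumulative detection rate is dominated by the time criterion
  (Group I 100%, genuine 100%, Group II ≈0%).  Passing tests therefore
  demonstrate the correctness of the implemented criteria and the
  Group I/genuine physics, not frequency-domain performance on real
  water-rich spoofs.
* The q statistics of the synthetic corpus preserve the discriminative
  ordering (Group I ≈ 2.3–4.8 > 0.85; Group II and fingers ≈ 0.02–0.11
  < 0.5) but not the absolute means of measured data, which depend on the
  instrument's exact pulse shape.
* Single-index depth inversion of the dispersive SC layer is ~15%
  accurate; the echo is carried by the low end of the band where the
  index is higher than the band mean.
* s-polarisation, focused-beam corrections, sweat-duct resonances,
  fingerprint ridge texture (far below the beam size) and
  humidity/temperature perturbations beyond amplitude jitter are out of
  scope.
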
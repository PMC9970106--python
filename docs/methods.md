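# Methods

This note documents the models implemented in `audspec`, the parameter
choices that matter, the numerical decisions behind them, and what the
synthetic-data generators do and do not emulate.

## Cochlear stage

The cochlear filterbank consists of gammatone filters

    h_k(t) = A t^(n-1) cos(2 pi f_k t) exp(-2 pi b(f_k) t) u(t)

with order `n = 4` (the standard auditory-nerve fit; the order is a
configuration field), ERB bandwidths `b(f) = 24.7 (4.37 f/1000 + 1)` Hz, and
gain `A` normalized numerically so the peak transfer-function magnitude is
exactly 1 for any order.  Characteristic frequencies follow
`CF_k = 100 * 2^(0.01 k)` for `k = 1..664`: the grid starts one 0.01-octave
step above 100 Hz, which is the convention that yields 664 channels between
100 Hz and 10 kHz.  Channel envelopes are Hilbert (analytic-signal)
magnitudes, lowpassed by a synaptic filter modeling hair-cell synaptic
dynamics — a centered cubic B-spline kernel time-scaled so its half-power
point is 750 Hz (the transfer function is `sinc^4(f Delta)` with knot
spacing `Delta ≈ 0.227/750 s`) — and sampled at `env_fs = 2100 Hz`.

**Envelope rate.** 2100 Hz was chosen (rather than a nominal 2000 Hz)
because it divides 44 100 Hz exactly: a 21-sample hop gives an integer-hop
STFT at the same frame rate, so the cochleogram and the Fourier spectrogram
share one modulation-analysis code path.  Its Nyquist (1050 Hz) covers the
750 Hz synaptic cutoff and the 512 Hz top STRF rate; halving the decimation
moves the sub-750 Hz modulation band power by < 0.5 dB (tested).

**Numerics.** Filtering is frequency-domain: the signal is transformed once
and each channel's analytic band (2 x transfer function x positive-frequency
spectrum, evaluated analytically on the DFT grid) is inverted at a reduced
per-channel rate — a zoom FFT covering `CF ± 6 b` (amplitude < 3e-3 of peak
outside) with at least 4x oversampling of the band half-width, and never
below 6300 Hz so the synaptic FIR stays well sampled.  This is exact
band-limited analytic-signal computation, not an approximation, and makes a
90 s, 664-channel cochleogram cost ~30 s on one CPU.  The convolution is
circular; edge transients are confined to roughly one impulse-response
length, and all pipeline statistics drop 50 ms from each end.  Envelopes are
clipped at zero after the synaptic filter (lowpass ringing can undershoot;
downstream statistics treat the cochleogram as a magnitude).  Time-frequency
resolutions are quoted as two-sigma widths of energy densities: the
impulse-response envelope squared (a gamma density, `sigma_t =
sqrt(2n-1)/(4 pi b)`) and the transfer-function magnitude squared.  Under
this convention every gammatone satisfies `Delta_t * Delta_f > 1/pi`
strictly, temporal resolution improves and spectral resolution degrades
monotonically with CF.

## Fourier baseline

Gaussian-window STFTs with `sigma = 1/(sqrt(2) pi Delta_f)` so that the
two-sigma energy widths satisfy `Delta_f = 2 sigma_f` and
`Delta_t * Delta_f = 1/pi` exactly (the minimum-uncertainty case).  Channels
are spaced 10 Hz between 100 Hz and 10 kHz (991 channels; the spacing is not
critical — it cancels in normalized entropy — but 10 Hz puts the
spectral-modulation Nyquist at 50 cyc/kHz, far above the ~18 cyc/kHz
white-noise contour).  Windows are truncated at ±4 sigma and scaled so a
tone at a channel center produces a steady-state magnitude equal to its
amplitude, mirroring the cochlear unity-gain convention.  The measured 3 dB
bandwidths (`sqrt(2 ln 2) Delta_f`) are 35.3, 141.3 and 565.1 Hz for
`Delta_f` = 30, 120, 480 Hz.

## Modulation power spectra

A representation `S(t, x)` is cut into adjacent non-overlapping 1.5 s
segments; each segment is windowed by a separable 2D Kaiser window
(beta = 3.4; temporal extent 1.5 s, spectral extent the full channel range),
2D-FFT'd, magnitude-squared and averaged (Welch).  With the 1.5 s window the
temporal-modulation resolution is ~0.8 Hz (3 dB) and the spectral-modulation
resolution is ~0.11 cyc/kHz (Fourier source, 9.9 kHz extent) or
~0.17 cyc/oct (cochlear source, 6.64 oct extent).  Densities are normalized
so that `sum(P) d_fm d_Omega` equals the windowed mean square of the input
(discrete Parseval), and the negative-`Omega` half-plane is folded onto
`Omega >= 0` (Hermitian symmetry of real inputs).  Units follow the source
axis: cycles/kHz for spectrograms, cycles/octave for cochleograms; the unit
tag is enforced wherever the two could be mixed.

**DC and static structure.** The estimator itself has a documented toggle:
by default each segment's scalar mean is subtracted before transforming
(`remove_segment_mean=True`); the transform-of-`S` form corresponds to
`False`.  For contour and entropy computations the pipeline additionally
zeroes the rows `|f_m| <= 2` bins (`mask_static_band`): modulations slower
than the segment-length resolution measure the segment's static spectral
profile, not resolvable modulation, and their power is orders of magnitude
above the structured-modulation floor (for a cochleogram the per-channel
mean scales as `sqrt(b(f))`, so the `f_m ≈ 0` ridge would otherwise dominate
the unit-sum normalization and drive the entropy far below its whitening
interpretation).  Static spectral structure at `f_m ≈ 0` (e.g. harmonic
stacks) remains visible in the MPS itself; it is only excluded from the
entropy normalization.

The 90% power contour is the bounding box (max `|f_m|`, max `Omega`) of the
super-level set at the smallest threshold containing 90% of total power.
For white noise the cochlear contour extends to ~480 Hz in temporal
modulation (the synaptic lowpass sets this scale) and ~4.5 cyc/oct; the
30 Hz Gabor contour reaches ~51 Hz and ~18 cyc/kHz.

## Midbrain stage

STRFs are Gabor-alpha kernels (alpha envelope in time, causal; Gaussian in
octaves; cosine carrier at `(f_m0, Omega_0)`, phase 0 by default — outputs
based on `|MTF|` depend only weakly on phase).  The secondary parameters are
pinned to the operational constant-Q contract: the measured half-power (3 dB)
modulation bandwidths equal the best modulation frequencies on both axes,
which gives

    tau = sqrt(sqrt(2) - 1) / (pi |f_m0|)      (temporal)
    bw  = 2 sqrt(ln 2) / (pi Omega_0)          (spectral)

Both follow from the closed-form MTF: the alpha-envelope transform is
`e tau / (1 + 2 pi i f tau)^2` and the spectral Gaussian transforms to a
Gaussian.  The amplitude is normalized numerically to unit peak `|MTF|`.
The default grid spans `f_m0 = ±2..512 Hz` in quarter-octave steps (33
magnitudes per sign; the 2 Hz lower edge is a configurable choice — grid
edges are second-order for normalized entropies) and `Omega_0 =
0.1..3.6 cyc/oct` in tenth-octave steps (52 values).

The midbrain MPS — power at each filter output — has two routes. The
modulation-domain route integrates `|MTF|^2` against the cochlear MPS and is
the default for long sounds; the whole 3432-filter grid reduces to a handful
of matrix products because each MTF lobe is separable in `(zeta, gamma)`.
The time-domain route convolves sampled kernels with the cochleogram
(circular convolution, the discrete-exact Parseval partner of the first
route) and is used as its cross-check; the two agree to well under 1% on
stationary periodic fields and within a few percent with linear-convolution
edge effects.  Sampled kernels require at least 8 samples per carrier period
per axis and raise otherwise: at `env_fs = 2100 Hz` filters above ~256 Hz
are only usable through the closed-form route.

Two resolution limits are worth knowing: filters at `Omega_0 = 0.1 cyc/oct`
sit below the spectral-modulation resolution of a 6.64-octave cochleogram
(1/6.64 ≈ 0.15 cyc/oct), so their modulation-domain power is underestimated;
and filters with `|f_m0|` near 512 Hz have MTF lobes partly beyond the
1050 Hz modulation Nyquist.  Both affect only the extreme grid edges.

## Entropy and slopes

Spectral entropy: per-channel time-averaged power (100 Hz–10 kHz), unit-sum
normalized, Shannon entropy divided by `log2 N` (with `0 log 0 = 0`).  The
printed-form of the normalized-entropy equation is implemented with the
normalized distribution inside the logarithm, since the alternative is not
bounded by the capacity.  Modulation entropy: the same construction on the
MPS restricted to `|f_m| <= fm_max`, `Omega <= Omega_max`, with the
denominator `log2` of the restricted bin count; marginal (temporal-only,
spectral-only) versions use the marginal bin counts.  Integration ranges
come from the white-noise 90% contour of the matching representation,
computed from three seeded 90 s noises and averaged; the midbrain range is
capped at 500 Hz and 4 cyc/oct, the physiological limits of midbrain
modulation sensitivity, applied to the filter-center grid.

Spectrum slopes are ordinary least squares on `10 log10` power against the
native axis — kHz for the Fourier bank (dB/kHz), octaves above 100 Hz for
the cochlear bank (dB/oct) — over 0.1–10 kHz.  Ensemble standardization
divides by the sample (n−1) standard deviation.

White-noise benchmarks under these defaults (3 x 90 s, seed-stable to
±0.005): spectral entropy 1.000 (Fourier, Delta_f = 30) and 0.931
(cochlear); modulation entropy 0.956 (Fourier), 0.925 (cochlear), 0.946
(midbrain); cochlear contour ~480 Hz.  The cochlear modulation entropy is
the most sensitive of these to estimator details (the MPS declines toward
its contour, so the value depends mildly on the window and contour
conventions); the others are robust.

## Whitening predictions

The cochlear-spectrum prediction interpolates the Fourier dB spectrum at the
CFs (linear in log-frequency), adds the ERB gain `10 log10 b(f)` (pure
filter-bandwidth gain; the synaptic filter's in-band response is not
included), and aligns by a least-squares additive offset before computing
mean absolute error — the gain is defined only up to a constant.  The
midbrain prediction adds `10 log10(|f_m0| Omega_0)` to the dB cochlear MPS
interpolated at the filter centers; for an MPS proportional to
`1/(f_m Omega)` the gain cancels the trend exactly.  The Greenwood map uses
the canonical human parameters `f(x) = 165.4 (10^(0.06 x) - 0.88)` Hz over
35 mm with 100 hair cells/mm (all configurable): ~83 hair cells in the
lowest octave of hearing (20–40 Hz), ~497 in the highest (10–20 kHz), a
~7.8 dB output-power gain under power summation across receptors.

## Synthetic sounds

The generators reproduce the statistical regularities the analysis is
about, not any particular recording:

- **White noise** — the calibration reference (flat spectrum, slope
  0 dB/kHz).
- **Power-law noise** — frequency-domain synthesis with Gaussian complex
  coefficients shaped to an exact dB/kHz slope (realized slopes match
  requests to ~0.01 dB/kHz at 10 s), optionally multiplied by a log-normal
  slow envelope whose modulation spectrum decays as `f_m^-alpha`
  (modulations band-limited to 0.5–200 Hz, log-amplitude SD 0.7).  The
  modulator itself realizes the exponent exactly; envelope measurements on
  the output mix in the carrier-envelope floor, so fitted output exponents
  are biased toward zero by a few tenths.
- **Harmonic vocalization surrogates** — harmonic stacks at `k f0` with
  amplitudes shaped by second-order formant resonances (default 500, 1500,
  2500 Hz; bandwidth `80 + 0.12 Fc` Hz), random harmonic phases, and
  raised-cosine amplitude modulation at a few Hz.

Per-category modulation exponents are plausible placeholders, not
calibrated to any measured corpus.  What passing tests show is that the
bandwidth-scaling mechanism whitens sounds with these second-order
statistics; they do not show that the specific entropy values of any real
corpus are reproduced — real sounds are non-stationary, non-Gaussian, and
carry category-specific structure (harmonicity, transients, texture) that
these generators only sketch.  The whitening-ordering test ensemble uses
Fourier slopes (−6 to −0.5 dB/kHz) spanning the point where the ERB gain
flattens the cochlear output, so cochlear slopes straddle zero the way
vocalization/background corpora do.

## Problem sizes and tolerances

Calibration runs use 3 x 90 s noises (the minimum ensemble duration the
analysis assumes), 1.5 s MPS segments (60 per noise), and the full 664 x
3432-filter model; a calibration takes ~3 minutes on one CPU.  Property
tests use 4–15 s sounds and filter subsets chosen so every code path
(including the time-domain midbrain route) is exercised.  Tolerances in
tests reflect measured seed-to-seed spread: entropies ±0.02–0.03, contour
extents ±10%, unity gains ±1–2%, constant-Q ±5%.

## Known limitations

- No cochlear nonlinearities (compression, suppression, adaptation) or
  spiking; the model is linear-filter + envelope + lowpass.
- MPS estimation assumes quasi-stationarity within 1.5 s segments.
- The `Omega_0 = 0.1` and `|f_m0| = 512 Hz` grid edges are resolution- and
  Nyquist-limited as described above.
- WAV ingest handles integer and float PCM; exotic encodings are not
  supported.
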
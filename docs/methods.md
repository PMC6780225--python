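# Methods

This note records the models behind `fndtrace`, the parameter values chosen
where the underlying physics fixes only a range, the numerical details of
each estimator, and what the synthetic benchmarks do and do not demonstrate
about real data.

## Magnetically modulated fluorescence

### Forward model

The detected photon rate at wavelength λ and time *t* is

    r(λ, t) = c · B · p_FND(λ)/p_FND(λ_ref) · [1 − m·s(t)]
            + L · p_AF(λ)/p_AF(λ_ref) · [1 + d·sin(2πt/T_d)]

with *c* the FND concentration (µg/mL), *B* the brightness (counts/s per
µg/mL at the reference wavelength), *m* the modulation depth, *s(t)* the
50%-duty square wave (field-off first), *L* the autofluorescence level
(counts/s at λ_ref), and a slow multiplicative drift of amplitude *d* and
period *T_d* on the background only.  Each sample is Poisson-distributed
around r/f_s.  Spectral profiles are unit-integral densities; the FND profile
is a two-Gaussian mixture (zero-phonon line 638 nm, σ 5 nm, weight 0.2;
phonon sideband 685 nm, σ 35 nm, weight 0.8), the autofluorescence a broad
Gaussian centered at 600 nm (σ 100 nm).  The magnetic quench is purely
phenomenological — no spin-Hamiltonian model is attempted — so *m* is a free
parameter rather than a prediction.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| f_mod | 2 Hz | modulation frequency of the reference instrument |
| field | 20 mT | reference field strength (metadata only; the quench is *m*) |
| m | 0.10 | typical NV⁻ quench magnitude at tens of mT; unmeasured, so exposed everywhere |
| f_s | 20 samples/s | 10 samples per period; acquisition electronics unspecified, chosen as a realistic multichannel-analyzer rate |
| duration | 60 s (120 s for calibration) | whole number of periods by construction |
| B | 500 counts/s per (µg/mL) at 685 nm | puts the 5–200 µg/mL calibration range 2–4 decades above shot noise, as a cuvette instrument would be designed to |
| L | 10⁴ counts/s (cuvette), 10× FND rate (digest) | digests are dominated by tissue autofluorescence |
| d, T_d | 5%, 60 s | slow lamp/alignment drift — the disturbance MMF exists to reject |
| λ grid | 550–800 nm, step 2.5 nm | contains 685 nm exactly |

### Demodulation

Amplitudes are one-sided DFT amplitudes 2|X(k)|/N at the bin exactly at
f_mod, converted to counts/s.  Three numerical details matter:

* **Whole periods.** Durations are constrained to an integer number of
  modulation periods, so f_mod falls exactly on the frequency grid and there
  is no spectral leakage from the signal itself.  If a record violates this,
  a Hann window is applied and the result flagged (`windowed=True`), or an
  error is raised on request.
* **One-period moving-average detrend.** Before the FFT, a moving average
  spanning exactly one period is subtracted (when the period is a whole
  number of samples).  That filter's response is identically zero at f_mod
  and all its harmonics, so the modulated amplitude is untouched, while slow
  background drift — whose off-grid frequencies would otherwise leak across
  the spectrum — is suppressed before transforming.  With it, an additive
  background at any frequency below f_mod/10 and 5% amplitude on a 10×
  background perturbs the amplitude by < 0.4% (< 1.6% without).
* **Synchronous-sampling scale.** Sampling a square wave at P = f_s/f_mod
  samples per period aliases its odd harmonics onto the fundamental bin,
  inflating it by π/(P·sin(π/P)) (+1.7% at P = 10).  When P is an even
  integer the reported amplitudes are rescaled by the inverse, so they sit on
  the continuous-waveform scale where the fundamental is exactly 2·m·I₀/π.
  The factor cancels in any calibrated quantification; fixing the scale
  simply makes amplitudes comparable to the analytic value.  Only the
  fundamental is used — harmonics are not summed into the estimate.

The per-wavelength noise floor is the median off-frequency amplitude over
bins at least 3 bins away from k_mod and every one of its harmonics (median,
because the square wave necessarily populates odd harmonics) and away from
the DC/drift region.

### Calibration, LOD, conversions

The calibration is least squares **through the origin**: MMF is
background-free by construction, so a free intercept only inflates variance;
blank replicates instead estimate σ_blank, and LOD = 3.3·σ_blank/slope
(ICH-style).  Quantification divides the amplitude at the reference
wavelength (685 nm, the sideband collection wavelength) by the slope; values
below the LOD are flagged but still returned.  Mass-to-particle conversion
treats particles as spheres of bulk-diamond density (3.52 g/cm³) at 100 nm
diameter; counts are reported exactly and at 2 significant figures.

## Photon decay and time gating

Arrival times are drawn in continuous time from a two-component exponential
mixture — τ_FND = 17 ns (within the >15 ns regime that makes gating work)
and τ_AF = 2.5 ns (inside the 1–4 ns band of common fluorophores) — with
Gaussian IRF jitter (σ 0.5 ns) added to each time, then binned (0.2 ns bins
by default).  Jittered times below zero fall outside the histogram.
Per-component binned counts are kept as provenance so gates can report
ground-truth retention.

Gating retains photons with arrival ≥ t_gate; the straddled bin is split
pro-rata (linear within the bin).  The default gate of 10 ns sits
comfortably past the 1–4 ns background lifetimes while keeping
exp(−10/17) ≈ 56% of FND photons; the SNR gain is defined as FND retention
over background retention.  Lifetimes are estimated by tail-only weighted
log-linear least squares (weights = counts, the inverse variance of
ln counts under Poisson noise) from 8 ns onward — past the IRF — which is
sufficient to support a threshold claim (τ > 15 ns) and deliberately not a
multi-exponential deconvolution.  The fit refuses to run on fewer than 5
non-zero tail bins or fewer than 100 tail photons.

## Image fields

The simulator emulates a 20×-magnification section image: 256 × 256 px at
0.65 µm/px, nuclei as isotropic Gaussian blobs (radius 5 ± 0.4 µm, blob σ =
0.45·r so that blobs at the placement separation remain threshold-separable),
placed by hard-core rejection sampling at ≥ 3 nucleus radii center-to-center;
FND puncta (σ 2 px) confined to the cytoplasmic annulus (1.1–1.9 r) of
labeled cells; an optional diffuse marker halo over a subset of labeled
cells; additive Gaussian read noise clipped at zero.

Counting is the fixed, reproducible operator: Gaussian smoothing at
σ = 0.5·r, global Otsu threshold, connected components, minimum area
π(0.5·r)².  The threshold is data-driven, making the count invariant to
global intensity scaling.  Watershed splitting is available behind a flag
for real images with touching nuclei; it is off by default because the
generator's hard-core placement guarantees separability.

**FND-positive scoring** compares each nucleus's mean perinuclear-annulus
intensity against the image background (pixels outside every perinuclear
region): positive when the mean exceeds background mean + 5 background SDs.
A pixel-level Otsu cut on the FND channel was rejected for this decision:
with sparse puncta the annulus *mean* of a genuinely labeled cell sits below
any pixel-level threshold that separates puncta from background, and on a
signal-free channel Otsu simply bisects the noise — both failure modes
disappear when the test is referenced to the background distribution of the
same image.

**Colocalization** uses Manders split coefficients with per-channel Otsu
thresholds: M1 = ΣA over pixels where both channels exceed their thresholds,
divided by ΣA over A's own above-threshold support (M2 symmetric).  The
metric was chosen for threshold-robustness over Pearson-style correlation,
and a block-scramble control (shuffling 32 px tiles of one channel) is built
in to show that observed overlap reflects spatial correspondence.  Field
summaries follow the six-random-fields-per-section design and stop at
mean ± SEM; group statistics are intentionally out of scope.

## Reproducibility and problem sizes

Every simulator takes one explicit seed; nothing uses global random state.
The pipeline derives per-stage seeds from a master seed via
`numpy.random.SeedSequence`, so a full run is bit-reproducible from its
configuration file alone and each stage can be re-run standalone.

The reference experiments use 100 replicates × 4 concentrations for spike
recovery and 50 seeds for the LOD distribution — sizes at which the reported
means and medians are stable to well under the margins they are compared
against — and the benchmark suites use 50 fields (counting), 100 seeds
(lifetime threshold) and 20 fields (colocalization control).

## What the synthetic benchmarks do not show

The generator reproduces the *statistical* structure the estimators rely on
(square-wave modulation, Poisson shot noise, slow multiplicative drift,
exponential decay mixtures, separable nuclei with perinuclear label), not
instrument- or tissue-specific structure: no wavelength-dependent detector
response, no scattering or depth-dependent attenuation in sections, no
touching/overlapping nuclei, no spatially correlated autofluorescence
texture, and no uptake biology (the dose/time curves in `analysis/03` are a
saturation model used to exercise the measurement chain, not a prediction).
Passing benchmarks therefore demonstrate correctness of the estimators under
their stated assumptions — not performance on any particular microscope or
tissue.  The magnetic quench depth and acquisition electronics of the
original instrument are unpublished; the values here are stated design
choices, and all of them are exposed as parameters.
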
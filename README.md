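# fndtrace

Quantitative analysis for long-term tracking of stem cells labeled with
fluorescent nanodiamonds (FNDs), built for the three measurements that make
FND labels attractive in regenerative-medicine studies: absolute
quantification by **magnetically modulated fluorescence (MMF)**,
**time-gated** imaging that rejects tissue autofluorescence, and
**field-based counting** of labeled cells in histology sections.  Every
analysis stage ships with a forward simulator that records its ground truth,
so the whole pipeline is testable end to end without any instrument data.

## The measurements

**MMF.** The NV⁻ centers in diamond emit far-red fluorescence (600–800 nm)
whose intensity drops by a fraction *m* (the modulation depth) under a
magnetic field.  Square-toggling a ~20 mT field at *f*\_mod = 2 Hz makes the
FND emission — and nothing else in the cuvette — oscillate at *f*\_mod.  For
each wavelength the time trace is Fourier transformed and the one-sided
amplitude at the modulation frequency is taken:

    A(λ) = 2 |X(k_mod)| / N      (scaled to counts/s)

For a rate toggling between *I*₀ and *I*₀(1 − *m*), the square-wave Fourier
series gives the fundamental amplitude *A* = 2 *m I*₀ / π.  Autofluorescence
and drift do not follow the field and contribute nothing at *f*\_mod, so the
demodulated spectrum is background-free.  A through-origin calibration
(slope *s*, limit of detection LOD = 3.3 σ_blank / *s*) converts amplitude to
concentration, and a spherical-particle model (diameter 100 nm, bulk diamond
density 3.52 g/cm³) converts mass to particle count — 49.3 pg/cell is
~2.7 × 10⁴ particles/cell.

**Time gating.** FND lifetimes exceed 15 ns while cell and tissue
autofluorescence decays in 1–4 ns; keeping only photons arriving after a gate
delay *t*\_g retains exp(−*t*\_g/τ) of each component, so a 10 ns gate keeps
~56% of τ = 17 ns FND photons but ~2% of a τ = 2.5 ns background — a ~28×
contrast gain.

**Field quantification.** DAPI nuclei are counted per imaging field
(smooth → Otsu → connected components → area filter), each nucleus is scored
FND-positive from its perinuclear annulus in the gated FND channel, and
channel overlap is summarized by Manders split coefficients M1/M2 with a
block-scramble control.

## Worked example

```sh
python analysis/06_full_pipeline.py
```

runs calibration → spike recovery → digest quantification → gating →
field counting from one seeded configuration and prints:

```
calibration slope : 31.75 counts/s per ug/mL
limit of detection: 0.987 ug/mL
spike recovery    : 109.15 %
per-cell loading  : 22.7 pg (~1.23e+04 particles/cell)
FND lifetime      : 17.10 +- 0.10 ns
10 ns gate        : retained 0.288, SNR gain 28x
fields            : 25.0 nuclei and 12.0 FND-positive cells per field
```

Reading the numbers: the fitted slope sits at the noiseless expectation
2·*m*·*B*/π = 31.83 for *m* = 0.10 and brightness *B* = 500 counts/s per
µg/mL; the detection limit is below 1 µg/mL; a digest of 10⁵ half-labeled
cells at 49.3 pg per labeled cell implies 24.7 pg/cell on average, and the
single-run estimate (22.7 pg) recovers it within the shot-noise error of one
measurement (the spike-recovery figure above is likewise a four-spectrum
single run; the 100-replicate average is computed by
`analysis/02_spike_recovery.py`).  The lifetime fit supports τ > 15 ns, and
the 10 ns gate retains 29% of all photons while boosting FND-to-background
contrast 28-fold.  Machine- and human-readable reports land in
`results/pipeline_run/`.

The other drivers reproduce one analysis each: `01` calibration + LOD
distribution, `02` spike recovery statistics, `03` dose/time uptake and
per-cell loading, `04` gate sweep and lifetime support, `05` two-group field
counting with colocalization controls.  The same functionality is scriptable
through the `fndtrace` CLI (`fndtrace --help`).

## Layout

```
src/fndtrace/      library: synthetic, mmf, timegate, imagequant, pipeline,
                   experiments, io, cli
analysis/          numbered narrative drivers writing tables to results/
scripts/           acceptance.py (headline-results recomputation)
tests/             pytest suite (unit, property and end-to-end)
docs/methods.md    models, parameter choices, numerical details, limitations
```
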
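"""Forward simulators with recorded ground truth.

Every input the analysis stages consume can be generated here, so the whole
pipeline is testable without any downloaded data:

* magnetically modulated emission spectra — NV⁻ far-red emission (zero-phonon
  line near 638 nm plus the phonon sideband near 685 nm) partially quenched
  while a 20 mT field is on, square-modulated at 2 Hz, on top of an
  unmodulated autofluorescence background with slow drift and Poisson shot
  noise;
* photon arrival-time histograms — two-component exponential mixtures
  (nanodiamond tau > 15 ns vs autofluorescence tau ~ 1–4 ns) convolved with a
  Gaussian instrument response;
* histology-like image fields — DAPI nuclei, perinuclear FND puncta and an
  optional marker channel, with ground-truth centers and labels attached.

All randomness flows from one explicit seed per call; no global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imagequant import ImageField
from .mmf import ModulatedSpectrum, ModulationConfig, demodulate
from .timegate import DecayHistogram

__all__ = [
    "SpectrumModel",
    "DecayModel",
    "FieldSpec",
    "simulate_modulated_spectrum",
    "simulate_decay_histogram",
    "simulate_field",
    "simulate_calibration_series",
]


def _gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


@dataclass
class SpectrumModel:
    """Spectral model of the FND + autofluorescence emission.

    ``fnd_profile`` and ``autofluor_profile`` are unit-integral emission
    densities over the wavelength grid.  ``brightness_per_conc`` (counts/s
    per µg/mL) and ``background_level`` (counts/s) are count rates AT the
    reference wavelength (685 nm, the sideband collection wavelength), i.e.
    the per-wavelength rate is scaled by profile(λ)/profile(λ_ref).  Drift is
    a slow multiplicative sinusoid on the autofluorescence only — slow
    background variation is exactly what magnetic modulation rejects.
    """

    wavelengths_nm: np.ndarray
    fnd_profile: np.ndarray
    autofluor_profile: np.ndarray
    brightness_per_conc: float = 500.0
    background_level: float = 1.0e4
    drift_fraction: float = 0.05
    drift_period_s: float = 60.0
    ref_wavelength_nm: float = 685.0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.fnd_profile = np.asarray(self.fnd_profile, dtype=float)
        self.autofluor_profile = np.asarray(self.autofluor_profile, dtype=float)
        for name, prof in (("fnd_profile", self.fnd_profile), ("autofluor_profile", self.autofluor_profile)):
            if prof.shape != self.wavelengths_nm.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(prof < 0):
                raise ValueError(f"invariant violated: {name} must be >= 0")
            integral = np.trapezoid(prof, self.wavelengths_nm)
            if not np.isclose(integral, 1.0, rtol=1e-6):
                raise ValueError(f"invariant violated: {name} must integrate to 1, got {integral:.6g}")
        if self.brightness_per_conc < 0 or self.background_level < 0:
            raise ValueError("invariant violated: all rates must be >= 0")

    @classmethod
    def default(
        cls,
        wl_start_nm: float = 550.0,
        wl_stop_nm: float = 800.0,
        wl_step_nm: float = 2.5,
        **overrides,
    ) -> "SpectrumModel":
        """Default NV⁻ emission model on a uniform wavelength grid.

        FND profile: two-Gaussian mixture — zero-phonon line at 638 nm
        (sigma 5 nm, weight 0.2) plus phonon sideband at 685 nm (sigma 35 nm,
        weight 0.8).  Autofluorescence: a broad Gaussian centered near
        600 nm, essentially featureless over the band.
        """
        wl = np.arange(wl_start_nm, wl_stop_nm + 0.5 * wl_step_nm, wl_step_nm)
        fnd = 0.2 * _gaussian(wl, 638.0, 5.0) + 0.8 * _gaussian(wl, 685.0, 35.0)
        fnd /= np.trapezoid(fnd, wl)
        auto = _gaussian(wl, 600.0, 100.0)
        auto /= np.trapezoid(auto, wl)
        return cls(wavelengths_nm=wl, fnd_profile=fnd, autofluor_profile=auto, **overrides)

    def _at_ref(self, prof: np.ndarray) -> float:
        return float(np.interp(self.ref_wavelength_nm, self.wavelengths_nm, prof))

    def fnd_rate(self, fnd_conc: float) -> np.ndarray:
        """Per-wavelength FND count rate (counts/s) at concentration ``fnd_conc``."""
        return fnd_conc * self.brightness_per_conc * self.fnd_profile / self._at_ref(self.fnd_profile)

    def autofluor_rate(self) -> np.ndarray:
        """Per-wavelength autofluorescence count rate (counts/s), pre-drift."""
        return self.background_level * self.autofluor_profile / self._at_ref(self.autofluor_profile)


def simulate_modulated_spectrum(
    model: SpectrumModel,
    config: ModulationConfig,
    fnd_conc: float,
    seed: int | None = 0,
    shot_noise: bool = True,
) -> ModulatedSpectrum:
    """Simulate a wavelength × time intensity matrix under magnetic modulation.

    The FND component is multiplied by ``(1 - depth_m)`` during field-on
    half-periods; the autofluorescence is time-invariant up to the slow
    drift; each sample is Poisson-distributed around its rate (disable with
    ``shot_noise=False`` for the infinite-photon limit).  Ground truth —
    concentration and the per-wavelength fundamental amplitude
    ``2*depth_m*rate/pi`` — is attached as ``meta``.
    """
    if fnd_conc < 0:
        raise ValueError(f"invariant violated: fnd_conc must be >= 0, got {fnd_conc}")
    t = config.times()
    on = config.field_on(t)
    fnd = model.fnd_rate(fnd_conc)  # (n_wl,)
    auto = model.autofluor_rate()
    mod = 1.0 - config.depth_m * on  # (n_t,)
    drift = 1.0 + model.drift_fraction * np.sin(2.0 * np.pi * t / model.drift_period_s)
    lam = (np.outer(fnd, mod) + np.outer(auto, drift)) / config.sample_rate_hz
    if shot_noise:
        rng = np.random.default_rng(seed)
        intensities = rng.poisson(lam).astype(float)
    else:
        intensities = lam
    meta = {
        "fnd_conc_ug_per_ml": float(fnd_conc),
        "true_amplitude": 2.0 * config.depth_m * fnd / np.pi,
        "seed": seed,
        "shot_noise": shot_noise,
    }
    return ModulatedSpectrum(
        wavelengths_nm=model.wavelengths_nm,
        times_s=t,
        intensities=intensities,
        config=config,
        meta=meta,
    )


@dataclass(frozen=True)
class DecayModel:
    """Two-component photon-decay mixture with Gaussian instrument response.

    Default lifetimes sit inside the bounds the physics dictates: 17 ns for
    the nanodiamond component (above the 15 ns threshold that makes gating
    work) and 2.5 ns for autofluorescence (inside the 1–4 ns range of common
    endogenous fluorophores).
    """

    tau_fnd_ns: float = 17.0
    tau_auto_ns: float = 2.5
    fraction_fnd: float = 0.5
    irf_sigma_ns: float = 0.5
    bin_width_ns: float = 0.2
    n_bins: int = 300
    total_photons: int = 100_000

    def __post_init__(self) -> None:
        if not self.tau_fnd_ns > self.tau_auto_ns > 0:
            raise ValueError(
                "invariant violated: need tau_fnd > tau_auto > 0, got "
                f"{self.tau_fnd_ns} and {self.tau_auto_ns}"
            )
        if self.bin_width_ns <= 0:
            raise ValueError("invariant violated: bin_width must be > 0")
        if not 0.0 <= self.fraction_fnd <= 1.0:
            raise ValueError("fraction_fnd must be in [0, 1]")
        if self.irf_sigma_ns < 0 or self.total_photons < 0 or self.n_bins <= 0:
            raise ValueError("irf_sigma, total_photons, n_bins must be non-negative")


def simulate_decay_histogram(model: DecayModel, seed: int | None = 0) -> DecayHistogram:
    """Draw photon arrival times and bin them.

    Arrival times are exponential (per component) in continuous time, with
    Gaussian IRF jitter added, then binned on ``[0, n_bins*bin_width]``;
    jittered times falling below 0 or past the range are dropped from the
    histogram but kept in the component bookkeeping denominators' spirit:
    per-component binned counts are stored in ``meta['component_counts']``.
    """
    window = model.n_bins * model.bin_width_ns
    if window < 3.0 * model.tau_fnd_ns:
        warnings.warn(
            f"histogram window {window:.1f} ns is shorter than 3*tau_fnd "
            f"({3 * model.tau_fnd_ns:.1f} ns); tail truncation will bias estimates"
        )
    rng = np.random.default_rng(seed)
    edges = np.arange(model.n_bins + 1) * model.bin_width_ns
    n_fnd = rng.binomial(model.total_photons, model.fraction_fnd) if model.total_photons else 0
    n_auto = model.total_photons - n_fnd
    comp: dict[str, np.ndarray] = {}
    for name, n, tau in (("fnd", n_fnd, model.tau_fnd_ns), ("auto", n_auto, model.tau_auto_ns)):
        times = rng.exponential(tau, size=n)
        if model.irf_sigma_ns > 0:
            times = times + rng.normal(0.0, model.irf_sigma_ns, size=n)
        comp[name], _ = np.histogram(times, bins=edges)
    counts = comp["fnd"] + comp["auto"]
    meta = {
        "model": model,
        "component_counts": {k: v.astype(float) for k, v in comp.items()},
        "seed": seed,
    }
    return DecayHistogram(bin_edges_ns=edges, counts=counts.astype(float), meta=meta)


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a simulated histology field.

    Geometry emulates a 20x-magnification section image: Gaussian-profile
    nuclei placed without overlap (hard-core rejection sampling), FND puncta
    confined to the cytoplasmic annulus of labeled cells, and an optional
    diffuse marker channel over a subset of the labeled cells.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.65
    n_nuclei: int = 25
    nucleus_radius_um: float = 5.0
    nucleus_radius_sd_um: float = 0.4
    fnd_labeled_fraction: float = 0.5
    puncta_per_cell: int = 8
    marker_positive_fraction: float = 0.0
    include_marker: bool = False
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.puncta_per_cell < 0:
            raise ValueError("invariant violated: all counts must be >= 0")
        for name in ("fnd_labeled_fraction", "marker_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0 or self.pixel_size_um <= 0:
            raise ValueError("noise_sd must be >= 0 and pixel_size > 0")


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_sep_px: float,
    margin_px: float,
    max_attempts: int = 20_000,
) -> np.ndarray:
    """Hard-core (Poisson-disk style) rejection sampling of nucleus centers."""
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei of separation "
                f"{min_sep_px:.1f} px in a {shape} field after {max_attempts} attempts; "
                "requested density exceeds the non-overlap limit"
            )
        attempts += 1
        c = np.array(
            [
                rng.uniform(margin_px, shape[0] - margin_px),
                rng.uniform(margin_px, shape[1] - margin_px),
            ]
        )
        if all(np.hypot(*(c - prev)) >= min_sep_px for prev in centers):
            centers.append(c)
    return np.array(centers).reshape(n, 2)


def simulate_field(spec: FieldSpec) -> ImageField:
    """Render a multichannel field with ground truth in ``provenance``.

    DAPI: one isotropic Gaussian blob per nucleus.  FND: bright puncta only
    inside the cytoplasmic annulus (1.1–1.9 nucleus radii) of labeled cells.
    Marker (when present): a diffuse cytoplasmic halo on the marker-positive
    subset of labeled cells.  Additive Gaussian read noise, clipped at zero.
    Identical specs (including seed) produce byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    r_px = spec.nucleus_radius_um / spec.pixel_size_um
    min_sep = 3.0 * r_px  # nuclei and their annuli stay resolvable
    margin = 2.2 * r_px
    centers = _place_centers(rng, (h, w), spec.n_nuclei, min_sep, margin)
    radii = np.clip(
        rng.normal(r_px, spec.nucleus_radius_sd_um / spec.pixel_size_um, size=spec.n_nuclei),
        0.5 * r_px,
        1.5 * r_px,
    )

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dapi = np.zeros((h, w))
    # sigma chosen so blobs at the hard-core separation stay Otsu-separable
    for (cy, cx), r in zip(centers, radii):
        sigma = 0.45 * r
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        dapi += 150.0 * np.exp(-0.5 * d2 / sigma**2)

    n_labeled = int(round(spec.fnd_labeled_fraction * spec.n_nuclei))
    labeled_idx = rng.choice(spec.n_nuclei, size=n_labeled, replace=False) if spec.n_nuclei else np.array([], int)
    labeled = np.zeros(spec.n_nuclei, dtype=bool)
    labeled[labeled_idx] = True

    fnd = np.zeros((h, w))
    for i in np.flatnonzero(labeled):
        cy, cx = centers[i]
        r = radii[i]
        for _ in range(spec.puncta_per_cell):
            rho = rng.uniform(1.1 * r, 1.9 * r)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            py, px = cy + rho * np.sin(ang), cx + rho * np.cos(ang)
            d2 = (yy - py) ** 2 + (xx - px) ** 2
            fnd += 300.0 * np.exp(-0.5 * d2 / 2.0**2)

    channels = {"dapi": dapi, "fnd": fnd}
    marker_pos = np.zeros(spec.n_nuclei, dtype=bool)
    if spec.include_marker or spec.marker_positive_fraction > 0:
        n_pos = int(round(spec.marker_positive_fraction * n_labeled))
        pos_idx = rng.choice(labeled_idx, size=n_pos, replace=False) if n_pos else np.array([], int)
        marker_pos[pos_idx] = True
        marker = np.zeros((h, w))
        for i in np.flatnonzero(marker_pos):
            cy, cx = centers[i]
            r = radii[i]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            marker += 90.0 * np.exp(-0.5 * d2 / (1.4 * r) ** 2)
        channels["marker"] = marker

    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, spec.noise_sd, size=(h, w)), 0.0, None
            )

    provenance = {
        "spec": spec,
        "centers_px": centers,
        "radii_px": radii,
        "fnd_labeled": labeled,
        "marker_positive": marker_pos,
    }
    return ImageField(channels=channels, pixel_size_um=spec.pixel_size_um, provenance=provenance)


def simulate_calibration_series(
    model: SpectrumModel,
    config: ModulationConfig,
    concentrations: Sequence[float],
    replicates: int = 1,
    seed: int | None = 0,
    shot_noise: bool = True,
) -> pd.DataFrame:
    """Simulate a calibration series and demodulate each point.

    Returns a table with columns ``concentration_ug_per_ml``, ``amplitude``
    (demodulated fundamental at the model's reference wavelength) and
    ``replicate``.  The series must include at least one blank
    (concentration 0) for noise-floor estimation.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.any(conc == 0):
        raise ValueError("a blank (concentration 0) must be included")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(conc.size * replicates))
    rows = []
    for c in conc:
        for rep in range(replicates):
            child = next(children)
            sub_seed = int(child.generate_state(1)[0] % (2**31)) if shot_noise else None
            spectrum = simulate_modulated_spectrum(
                model, config, float(c), seed=sub_seed, shot_noise=shot_noise
            )
            dem = demodulate(spectrum)
            rows.append(
                {
                    "concentration_ug_per_ml": float(c),
                    "amplitude": dem.amplitude_at(model.ref_wavelength_nm),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
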
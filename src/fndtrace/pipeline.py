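"""End-to-end orchestration: simulate -> demodulate -> calibrate -> quantify
-> gate -> count, from a single serializable configuration.

A run is reproducible from its ``RunConfig`` alone: one master seed
deterministically derives a seed per stage, so each stage can also be re-run
standalone with the same result.  Reports are written both machine-readable
(YAML) and human-readable (Markdown); group-comparison statistics are
deliberately out of scope — summaries stop at mean ± SEM.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .imagequant import (
    FieldQuant,
    colocalization,
    count_nuclei,
    detect_fnd_cells,
    summarize_fields,
)
from .mmf import (
    ModulationConfig,
    ParticleModel,
    demodulate,
    fit_calibration,
    mass_to_particles,
    quantify,
    recovery_rate,
)
from .synthetic import (
    DecayModel,
    FieldSpec,
    SpectrumModel,
    simulate_calibration_series,
    simulate_decay_histogram,
    simulate_field,
    simulate_modulated_spectrum,
)
from .timegate import estimate_lifetime, gate

log = logging.getLogger("fndtrace")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of one pipeline run (fully serializable)."""

    seed: int = 0
    # modulation
    f_mod_hz: float = 2.0
    depth_m: float = 0.10
    sample_rate_hz: float = 20.0
    duration_s: float = 60.0
    # spectral model
    brightness_per_conc: float = 500.0
    wl_step_nm: float = 2.5
    drift_fraction: float = 0.05
    ref_wavelength_nm: float = 685.0
    # calibration series (cuvette: fixed buffer autofluorescence)
    calibration_concentrations: tuple[float, ...] = (0, 0, 0, 0, 0, 5, 10, 50, 100, 200)
    calibration_background: float = 1.0e4
    calibration_duration_s: float = 120.0
    # spike recovery (tissue digest: autofluorescence 10x the FND rate)
    recovery_concentrations: tuple[float, ...] = (5.0, 20.0, 50.0, 100.0)
    background_ratio: float = 10.0
    # per-cell loading experiment
    fnd_per_cell_pg: float = 49.3
    n_cells: float = 1.0e5
    digest_volume_ml: float = 1.0
    particle_diameter_nm: float = 100.0
    particle_density_g_cm3: float = 3.52
    # lifetime / gating
    decay_fraction_fnd: float = 0.5
    t_gate_ns: float = 10.0
    fit_start_ns: float = 8.0
    # image fields
    n_fields: int = 6
    n_nuclei: int = 25
    fnd_labeled_fraction: float = 0.5
    marker_positive_fraction: float = 0.8

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("calibration_concentrations", "recovery_concentrations"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def modulation(self, duration_s: float | None = None) -> ModulationConfig:
        return ModulationConfig(
            f_mod_hz=self.f_mod_hz,
            depth_m=self.depth_m,
            sample_rate_hz=self.sample_rate_hz,
            duration_s=duration_s if duration_s is not None else self.duration_s,
        )


@dataclass
class RunReport:
    """Machine-readable pipeline outcome; every number traces to a stage
    output file listed in ``outputs``."""

    config: RunConfig
    calibration_slope: float
    lod_ug_per_ml: float
    recovery_rate_pct: float
    loading_conc_ug_per_ml: float
    loading_below_detection: bool
    per_cell_pg: float
    particles_per_cell: float
    lifetime_ns: float
    lifetime_se_ns: float
    gate_retained_fraction: float
    snr_gain: float | None
    nuclei_mean: float
    nuclei_sem: float
    fnd_positive_mean: float
    fnd_positive_sem: float
    coloc_m1_mean: float
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["config"] = dataclasses.asdict(self.config)
        return d

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        ypath = out_dir / "report.yaml"
        ypath.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        mpath = out_dir / "report.md"
        lines = [
            "# FND tracking pipeline report",
            "",
            f"- calibration slope: {self.calibration_slope:.4g} counts/s per ug/mL",
            f"- limit of detection: {self.lod_ug_per_ml:.4g} ug/mL",
            f"- spike recovery: {self.recovery_rate_pct:.2f} %",
            f"- quantified digest concentration: {self.loading_conc_ug_per_ml:.4g} ug/mL"
            + (" (below detection)" if self.loading_below_detection else ""),
            f"- per-cell loading: {self.per_cell_pg:.3g} pg/cell"
            f" (~{self.particles_per_cell:.3g} particles/cell)",
            f"- FND lifetime: {self.lifetime_ns:.2f} +- {self.lifetime_se_ns:.2f} ns",
            f"- gate at {self.config.t_gate_ns:g} ns: retained fraction "
            f"{self.gate_retained_fraction:.3f}, SNR gain "
            + (f"{self.snr_gain:.1f}" if self.snr_gain is not None else "n/a"),
            f"- nuclei per field: {self.nuclei_mean:.2f} +- {self.nuclei_sem:.2f} (SEM)",
            f"- FND-positive per field: {self.fnd_positive_mean:.2f} +- {self.fnd_positive_sem:.2f} (SEM)",
            f"- mean Manders M1 (fnd vs marker): {self.coloc_m1_mean:.3f}",
            "",
            "## Stage outputs",
            "",
        ]
        lines += [f"- {k}: `{v}`" for k, v in sorted(self.outputs.items())]
        mpath.write_text("\n".join(lines) + "\n")
        return ypath, mpath


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages in order, writing stage outputs and the report.

    Any stage failure aborts with the stage name prefixed to the violated
    contract's message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(("calibration", "recovery", "loading", "decay", "fields"), ss.spawn(5))}
    outputs: dict[str, str] = {}
    config.to_yaml(out_dir / "run_config.yaml")
    outputs["run_config"] = "run_config.yaml"

    def stage(name):
        log.info("stage %s", name)
        return seeds[name]

    # --- calibration -----------------------------------------------------
    try:
        s = stage("calibration")
        cal_model = SpectrumModel.default(
            wl_step_nm=config.wl_step_nm,
            brightness_per_conc=config.brightness_per_conc,
            background_level=config.calibration_background,
            drift_fraction=config.drift_fraction,
            ref_wavelength_nm=config.ref_wavelength_nm,
        )
        table = simulate_calibration_series(
            cal_model,
            config.modulation(config.calibration_duration_s),
            config.calibration_concentrations,
            replicates=1,
            seed=_child_seed(s),
        )
        fio.write_calibration_table(table, out_dir / "calibration.csv")
        cal = fit_calibration(table)
        fio.write_calibration_curve(cal, out_dir / "calibration_curve.yaml")
        outputs["calibration_table"] = "calibration.csv"
        outputs["calibration_curve"] = "calibration_curve.yaml"
    except Exception as e:
        raise RuntimeError(f"stage 'calibration' failed: {e}") from e

    # --- spike recovery --------------------------------------------------
    try:
        s = stage("recovery")
        children = s.spawn(len(config.recovery_concentrations))
        true_conc, est_conc = [], []
        rows = []
        for conc, child in zip(config.recovery_concentrations, children):
            model = SpectrumModel.default(
                wl_step_nm=config.wl_step_nm,
                brightness_per_conc=config.brightness_per_conc,
                background_level=config.background_ratio * conc * config.brightness_per_conc,
                drift_fraction=config.drift_fraction,
                ref_wavelength_nm=config.ref_wavelength_nm,
            )
            spectrum = simulate_modulated_spectrum(model, config.modulation(), conc, seed=_child_seed(child))
            dem = demodulate(spectrum)
            q = quantify(dem, cal, config.ref_wavelength_nm)
            true_conc.append(conc)
            est_conc.append(q.concentration_ug_per_ml)
            rows.append({"true_ug_per_ml": conc, "estimated_ug_per_ml": q.concentration_ug_per_ml})
        rec = recovery_rate(true_conc, est_conc)
        pd.DataFrame(rows).to_csv(out_dir / "recovery.csv", index=False)
        outputs["recovery_table"] = "recovery.csv"
    except Exception as e:
        raise RuntimeError(f"stage 'recovery' failed: {e}") from e

    # --- per-cell loading ------------------------------------------------
    try:
        s = stage("loading")
        conc_true = (
            config.fnd_per_cell_pg
            * config.fnd_labeled_fraction
            * config.n_cells
            / config.digest_volume_ml
            / 1e6  # pg/mL -> ug/mL
        )
        model = SpectrumModel.default(
            wl_step_nm=config.wl_step_nm,
            brightness_per_conc=config.brightness_per_conc,
            background_level=config.calibration_background,
            drift_fraction=config.drift_fraction,
            ref_wavelength_nm=config.ref_wavelength_nm,
        )
        spectrum = simulate_modulated_spectrum(model, config.modulation(), conc_true, seed=_child_seed(s))
        dem = demodulate(spectrum)
        fio.write_demodulated(dem, out_dir / "digest_demodulated.csv")
        q = quantify(dem, cal, config.ref_wavelength_nm)
        total_mass_pg = q.concentration_ug_per_ml * config.digest_volume_ml * 1e6
        per_cell = total_mass_pg / config.n_cells
        particle = ParticleModel(config.particle_diameter_nm, config.particle_density_g_cm3)
        particles = mass_to_particles(max(per_cell, 0.0), particle)
        outputs["digest_demodulated"] = "digest_demodulated.csv"
    except Exception as e:
        raise RuntimeError(f"stage 'loading' failed: {e}") from e

    # --- lifetime and gating ---------------------------------------------
    try:
        s = stage("decay")
        s_mixed, s_pure = s.spawn(2)
        mixed = simulate_decay_histogram(
            DecayModel(fraction_fnd=config.decay_fraction_fnd), seed=_child_seed(s_mixed)
        )
        fio.write_histogram(mixed, out_dir / "decay_mixed.csv")
        g = gate(mixed, config.t_gate_ns)
        pure = simulate_decay_histogram(DecayModel(fraction_fnd=1.0), seed=_child_seed(s_pure))
        tau, tau_se = estimate_lifetime(pure, config.fit_start_ns)
        outputs["decay_histogram"] = "decay_mixed.csv"
    except Exception as e:
        raise RuntimeError(f"stage 'decay' failed: {e}") from e

    # --- image fields ----------------------------------------------------
    try:
        s = stage("fields")
        children = s.spawn(config.n_fields)
        quants = []
        for i, child in enumerate(children):
            spec = FieldSpec(
                n_nuclei=config.n_nuclei,
                fnd_labeled_fraction=config.fnd_labeled_fraction,
                marker_positive_fraction=config.marker_positive_fraction,
                include_marker=True,
                seed=_child_seed(child),
            )
            fieldimg = simulate_field(spec)
            n, labels = count_nuclei(fieldimg, spec.nucleus_radius_um)
            n_pos, _ = detect_fnd_cells(fieldimg, labels, spec.nucleus_radius_um)
            m1, m2 = colocalization(fieldimg, "fnd", "marker")
            quants.append(
                FieldQuant(
                    field_id=f"field{i}",
                    n_nuclei=n,
                    n_fnd_positive=min(n_pos, n),
                    coloc_m1=m1,
                    coloc_m2=m2,
                )
            )
        summary = summarize_fields(quants, n_fields=config.n_fields)
        summary["table"].to_csv(out_dir / "fields.csv", index=False)
        outputs["fields_table"] = "fields.csv"
    except Exception as e:
        raise RuntimeError(f"stage 'fields' failed: {e}") from e

    m1_vals = summary["table"]["coloc_m1"].to_numpy(dtype=float)
    report = RunReport(
        config=config,
        calibration_slope=cal.slope,
        lod_ug_per_ml=cal.lod,
        recovery_rate_pct=rec,
        loading_conc_ug_per_ml=q.concentration_ug_per_ml,
        loading_below_detection=q.below_detection,
        per_cell_pg=per_cell,
        particles_per_cell=particles.count,
        lifetime_ns=tau,
        lifetime_se_ns=tau_se,
        gate_retained_fraction=g.retained_fraction,
        snr_gain=g.snr_gain,
        nuclei_mean=summary["n_nuclei_mean"],
        nuclei_sem=summary["n_nuclei_sem"],
        fnd_positive_mean=summary["n_fnd_positive_mean"],
        fnd_positive_sem=summary["n_fnd_positive_sem"],
        coloc_m1_mean=float(np.nanmean(m1_vals)),
        outputs=outputs,
    )
    report.write(out_dir)
    return report


def make_fixtures(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write a small deterministic bundle exercising every file dialect.

    Contents: one modulated spectrum (TSV + YAML sidecar), one calibration
    series (CSV), one decay histogram (CSV), one per-pixel decay stack
    (TIFF + YAML), and two image fields (TIFF).  Byte-identical for a fixed
    seed; total size well under the fixture budget.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_spec, s_cal, s_decay, s_stack, s_f1, s_f2 = ss.spawn(6)

    model = SpectrumModel.default(wl_step_nm=10.0)
    cfg = ModulationConfig(duration_s=10.0)
    paths: dict[str, Path] = {}

    spectrum = simulate_modulated_spectrum(model, cfg, 50.0, seed=_child_seed(s_spec))
    paths["spectrum"] = fio.write_spectrum(spectrum, out_dir / "spectrum.tsv")

    table = simulate_calibration_series(model, cfg, (0, 0, 5, 50, 200), seed=_child_seed(s_cal))
    paths["calibration"] = fio.write_calibration_table(table, out_dir / "calibration.csv")

    hist = simulate_decay_histogram(DecayModel(total_photons=20_000), seed=_child_seed(s_decay))
    paths["decay"] = fio.write_histogram(hist, out_dir / "decay.csv")

    rng = np.random.default_rng(_child_seed(s_stack))
    edges = np.arange(61) * 1.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    lam = np.ones((8, 8)) * 2.0
    lam[3:5, 3:5] = 20.0
    decay = np.exp(-centers / 17.0)
    decay /= decay.sum()
    stack = rng.poisson(lam[None, :, :] * decay[:, None, None] * 50.0).astype(float)
    paths["stack"] = fio.write_stack(stack, edges, out_dir / "stack.tiff")

    for name, s in (("field_a", s_f1), ("field_b", s_f2)):
        spec = FieldSpec(
            image_shape=(128, 128),
            n_nuclei=8,
            fnd_labeled_fraction=0.5,
            marker_positive_fraction=0.5,
            include_marker=True,
            seed=_child_seed(s),
        )
        paths[name] = fio.write_field(simulate_field(spec), out_dir / f"{name}.tiff")
    return paths
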
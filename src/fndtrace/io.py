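"""Readers and writers for the pipeline's file dialects.

* modulated spectrum: TSV (first column ``wavelength_nm``, remaining columns
  time points) plus a YAML sidecar holding the modulation configuration;
* demodulated spectrum: CSV ``wavelength_nm,amplitude,noise_floor``;
* calibration table: CSV ``concentration_ug_per_ml,amplitude,replicate``;
* calibration curve: YAML;
* decay histogram: CSV ``bin_start_ns,bin_end_ns,counts``;
* image fields: multi-page TIFF, one page per channel, channel names and
  pixel size in the image description; per-pixel decay stacks: 3-D TIFF with
  a YAML sidecar for the bin edges.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imagequant import ImageField
from .mmf import CalibrationCurve, DemodulatedSpectrum, ModulatedSpectrum, ModulationConfig
from .timegate import DecayHistogram

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_demodulated",
    "read_demodulated",
    "write_calibration_table",
    "read_calibration_table",
    "write_calibration_curve",
    "read_calibration_curve",
    "write_histogram",
    "read_histogram",
    "write_field",
    "read_field",
    "write_stack",
    "read_stack",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_spectrum(spectrum: ModulatedSpectrum, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        spectrum.intensities,
        index=pd.Index(spectrum.wavelengths_nm, name="wavelength_nm"),
        columns=[f"{t:.6f}" for t in spectrum.times_s],
    )
    df.to_csv(path, sep="\t")
    cfg = spectrum.config
    meta = {
        "config": {
            "f_mod_hz": cfg.f_mod_hz,
            "field_strength_mt": cfg.field_strength_mt,
            "depth_m": cfg.depth_m,
            "sample_rate_hz": cfg.sample_rate_hz,
            "duration_s": cfg.duration_s,
            "phase": cfg.phase,
        },
        "fnd_conc_ug_per_ml": spectrum.meta.get("fnd_conc_ug_per_ml"),
        "seed": spectrum.meta.get("seed"),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_spectrum(path: str | Path) -> ModulatedSpectrum:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = yaml.safe_load(_sidecar(path).read_text())
    config = ModulationConfig(**meta["config"])
    times = np.array([float(c) for c in df.columns])
    return ModulatedSpectrum(
        wavelengths_nm=df.index.to_numpy(dtype=float),
        times_s=times,
        intensities=df.to_numpy(dtype=float),
        config=config,
        meta={k: v for k, v in meta.items() if k != "config"},
    )


def write_demodulated(dem: DemodulatedSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "wavelength_nm": dem.wavelengths_nm,
            "amplitude": dem.amplitudes,
            "noise_floor": dem.noise_floor,
        }
    ).to_csv(path, index=False)
    return path


def read_demodulated(path: str | Path, f_mod_hz: float = 2.0) -> DemodulatedSpectrum:
    df = pd.read_csv(path)
    return DemodulatedSpectrum(
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        amplitudes=df["amplitude"].to_numpy(),
        noise_floor=df["noise_floor"].to_numpy(),
        f_mod_hz=f_mod_hz,
    )


def write_calibration_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_calibration_curve(cal: CalibrationCurve, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "slope": cal.slope,
        "intercept": cal.intercept,
        "residual_sd": cal.residual_sd,
        "blank_sd": cal.blank_sd,
        "lod": cal.lod,
        "n_points": cal.n_points,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_calibration_curve(path: str | Path) -> CalibrationCurve:
    payload = yaml.safe_load(Path(path).read_text())
    return CalibrationCurve(**payload)


def write_histogram(hist: DecayHistogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "bin_start_ns": hist.bin_edges_ns[:-1],
            "bin_end_ns": hist.bin_edges_ns[1:],
            "counts": hist.counts,
        }
    ).to_csv(path, index=False)
    return path


def read_histogram(path: str | Path) -> DecayHistogram:
    df = pd.read_csv(path)
    edges = np.append(df["bin_start_ns"].to_numpy(), df["bin_end_ns"].to_numpy()[-1])
    return DecayHistogram(bin_edges_ns=edges, counts=df["counts"].to_numpy(dtype=float))


def write_field(fieldimg: ImageField, path: str | Path) -> Path:
    path = Path(path)
    names = sorted(fieldimg.channels)
    stack = np.stack([fieldimg.channels[n] for n in names]).astype(np.float32)
    desc = json.dumps({"channels": names, "pixel_size_um": fieldimg.pixel_size_um})
    tifffile.imwrite(path, stack, description=desc)
    return path


def read_field(path: str | Path) -> ImageField:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    names = meta.get("channels", [f"channel{i}" for i in range(stack.shape[0])])
    return ImageField(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


def write_stack(stack: np.ndarray, bin_edges_ns: np.ndarray, path: str | Path) -> Path:
    """3-D decay stack as TIFF (time bins as pages) with a YAML bin sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    _sidecar(path).write_text(
        yaml.safe_dump({"bin_edges_ns": [float(e) for e in np.asarray(bin_edges_ns)]})
    )
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    meta = yaml.safe_load(_sidecar(path).read_text())
    return stack, np.asarray(meta["bin_edges_ns"], dtype=float)
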
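"""Readers and writers for the pipeline's on-disk formats.

Images and videos travel as multi-page TIFF with a JSON sidecar carrying
physical metadata (pixel pitch, frame rate, units); PSF grids and phantoms
as HDF5; trial tables as CSV; configuration and stimulus protocols as YAML;
run provenance as JSON.  Conventions: object-plane coordinates in mm,
PSF/sensor pitch in μm, 0-based pixel indexing with origin top-left, y down.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .forward import MeasurementStack, PSFGrid
from .maskdesign import ContourPattern, PhaseMask
from .phantom import CortexPhantom, StimulusProtocol

__all__ = [
    "write_stack",
    "read_stack",
    "save_psf_grid",
    "load_psf_grid",
    "load_psf_grid_tiffs",
    "save_phantom",
    "load_phantom",
    "save_pattern",
    "save_phase_mask",
    "load_phase_mask",
    "read_trial_table",
    "write_provenance",
    "save_protocol",
    "load_protocol",
    "save_composite_png",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, frames: np.ndarray, pixel_pitch: float = 2.4,
                frame_rate: float = 20.0, **meta):
    """Write frames as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = np.asarray(frames)
    tifffile.imwrite(path, frames if frames.ndim > 2 else frames[None])
    meta = {"pixel_pitch_um": pixel_pitch, "frame_rate_hz": frame_rate, **meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> MeasurementStack:
    """Read a TIFF stack (or 2D HDF5 dataset ``/frames``) with metadata."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            frames = f["frames"][...]
            meta = dict(f["frames"].attrs)
    else:
        frames = tifffile.imread(path)
        sc = _sidecar(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
        else:
            meta = {}
            warnings.warn(f"no metadata sidecar for {path.name}; using defaults")
    if frames.ndim == 2:
        frames = frames[None]
    bit_depth = 8 if frames.dtype == np.uint8 else 16 if frames.dtype == np.uint16 else 32
    return MeasurementStack(
        frames,
        bit_depth=bit_depth,
        frame_rate=float(meta.get("frame_rate_hz", 20.0)),
        pixel_pitch=float(meta.get("pixel_pitch_um", 2.4)),
    )


def save_psf_grid(path, grid: PSFGrid):
    with h5py.File(path, "w") as f:
        d = f.create_dataset("psfs", data=grid.psfs)
        f.create_dataset("depths", data=grid.depths)
        f.create_dataset("grid_coords_y", data=grid.grid_coords_y)
        f.create_dataset("grid_coords_x", data=grid.grid_coords_x)
        d.attrs["pixel_pitch_um"] = grid.pixel_pitch
        d.attrs["units"] = "depths: mm; grid_coords: mm; pitch: um"


def load_psf_grid(path) -> PSFGrid:
    with h5py.File(path, "r") as f:
        return PSFGrid(
            f["psfs"][...],
            f["depths"][...],
            grid_coords_y=f["grid_coords_y"][...],
            grid_coords_x=f["grid_coords_x"][...],
            pixel_pitch=float(f["psfs"].attrs.get("pixel_pitch_um", 2.4)),
        )


def load_psf_grid_tiffs(index_csv, root=None) -> PSFGrid:
    """Import a PSFGrid from per-position TIFFs listed in a CSV index.

    Columns: filename, depth_mm, grid_row, grid_col[, y_mm, x_mm].
    PSFs are normalized to unit sum on load.
    """
    index_csv = Path(index_csv)
    root = index_csv.parent if root is None else Path(root)
    tab = pd.read_csv(index_csv)
    depths = np.sort(tab["depth_mm"].unique())
    nr = int(tab["grid_row"].max()) + 1
    nc = int(tab["grid_col"].max()) + 1
    sample = tifffile.imread(root / tab.iloc[0]["filename"])
    psfs = np.zeros((len(depths), nr, nc) + sample.shape)
    for _, row in tab.iterrows():
        img = tifffile.imread(root / row["filename"]).astype(float)
        di = int(np.searchsorted(depths, row["depth_mm"]))
        psfs[di, int(row["grid_row"]), int(row["grid_col"])] = img / img.sum()
    return PSFGrid(psfs, depths)


def save_phantom(path, ph: CortexPhantom):
    with h5py.File(path, "w") as f:
        for name in ("pref_map", "tuning_amp", "baseline", "vasculature"):
            f.create_dataset(name, data=getattr(ph, name))
        f.attrs["column_periodicity_cpmm"] = ph.column_periodicity
        f.attrs["pixel_pitch_obj_um"] = ph.pixel_pitch_obj


def load_phantom(path) -> CortexPhantom:
    with h5py.File(path, "r") as f:
        return CortexPhantom(
            pref_map=f["pref_map"][...],
            tuning_amp=f["tuning_amp"][...],
            baseline=f["baseline"][...],
            vasculature=f["vasculature"][...].astype(bool),
            column_periodicity=float(f.attrs["column_periodicity_cpmm"]),
            pixel_pitch_obj=float(f.attrs["pixel_pitch_obj_um"]),
        )


def save_pattern(path, pattern: ContourPattern):
    """Contour pattern as 1-bit-style uint8 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, pattern.mask.astype(np.uint8))
    _sidecar(path).write_text(json.dumps({
        "pixel_pitch_um": pattern.pixel_pitch,
        "pattern_width_um": pattern.pattern_width,
    }, indent=1))


def save_phase_mask(path, mask: PhaseMask):
    """Height map as 16-bit TIFF in nm + JSON sidecar with geometry."""
    path = Path(path)
    tifffile.imwrite(path, mask.heights.astype(np.uint16))
    _sidecar(path).write_text(json.dumps({
        "pixel_pitch_um": mask.pixel_pitch,
        "height_step_nm": mask.height_step,
        "max_height_nm": mask.max_height,
        "extent_mm": list(mask.extent),
        "design_wavelength_nm": mask.design_wavelength,
        "mask_to_sensor_distance_mm": mask.mask_to_sensor_distance,
        "refractive_index_contrast": mask.refractive_index_contrast,
    }, indent=1))


def load_phase_mask(path) -> PhaseMask:
    path = Path(path)
    heights = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return PhaseMask(
        heights,
        pixel_pitch=meta["pixel_pitch_um"],
        height_step=meta["height_step_nm"],
        max_height=meta["max_height_nm"],
        extent=tuple(meta["extent_mm"]),
        design_wavelength=meta["design_wavelength_nm"],
        mask_to_sensor_distance=meta["mask_to_sensor_distance_mm"],
        refractive_index_contrast=meta.get("refractive_index_contrast", 0.55),
    )


def read_trial_table(path) -> pd.DataFrame:
    """Trial table CSV with columns trial_id, condition, onset_frame."""
    tab = pd.read_csv(path)
    missing = {"trial_id", "condition", "onset_frame"} - set(tab.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return tab


def save_protocol(path, protocol: StimulusProtocol):
    import dataclasses

    d = dataclasses.asdict(protocol)
    d["orientations"] = list(d["orientations"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_protocol(path) -> StimulusProtocol:
    d = yaml.safe_load(Path(path).read_text())
    d["orientations"] = tuple(d["orientations"])
    return StimulusProtocol(**d)


def save_composite_png(path, pref_map: np.ndarray, magnitude_map: np.ndarray):
    """Composite orientation map as an HSV-encoded PNG.

    Hue encodes preferred orientation (0–180° → full color circle),
    saturation the tuning strength; value is constant.  The raw float maps
    should be written alongside as TIFF — the PNG is for viewing.
    """
    from skimage import color
    import imageio.v3 as iio

    h = np.mod(np.asarray(pref_map, dtype=float), 180.0) / 180.0
    mag = np.asarray(magnitude_map, dtype=float)
    s = np.clip(mag / max(mag.max(), 1e-12), 0.0, 1.0)
    hsv = np.stack([h, s, np.ones_like(h)], axis=-1)
    rgb = (color.hsv2rgb(hsv) * 255).astype(np.uint8)
    iio.imwrite(Path(path), rgb)


def write_provenance(path, **fields):
    """Machine-readable provenance JSON (config hash, seeds, versions...)."""
    import contourscope

    payload = {"contourscope_version": contourscope.__version__,
               "numpy_version": np.__version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
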
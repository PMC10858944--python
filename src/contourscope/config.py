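"""Run configuration and the end-to-end pipeline driver.

A :class:`RunConfig` gathers per-stage settings (mask design, PSF
simulation, phantom generation, trial simulation, reconstruction, analysis)
under one global seed, serializes losslessly to/from YAML, and rejects
unknown keys by name.  :func:`run_pipeline` executes the requested stages in
order, writing every artifact with a provenance JSON sufficient to
regenerate it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("contourscope")

__all__ = ["RunConfig", "run_pipeline"]


def _from_dict(cls, data: dict, path=""):
    import typing

    hints = typing.get_type_hints(cls)
    names = {f.name for f in dataclasses.fields(cls)}
    out = {}
    for k, v in data.items():
        if k not in names:
            raise ValueError(f"unknown config key {path + k!r}")
        t = hints.get(k)
        if dataclasses.is_dataclass(t) and isinstance(v, dict):
            v = _from_dict(t, v, path=f"{path}{k}.")
        out[k] = v
    return cls(**out)


@dataclass
class MaskStage:
    shape: int = 128
    feature_scale_um: float = 24.0
    pattern_width_um: float = 6.0
    pixel_pitch_um: float = 1.0
    distance_mm: float = 3.5
    wavelength_nm: float = 530.0
    n_iter: int = 30


@dataclass
class SimulateStage:
    depth_mm: float = 3.0
    grid_shape: int = 3
    grid_extent_mm: float = 0.02
    psf_crop: int = 64
    photon_scale: float = 1000.0
    read_sigma: float = 0.001


@dataclass
class PhantomStage:
    shape: int = 64
    pixel_pitch_obj_um: float = 31.25
    periodicity_cpmm: float = 1.2
    dff_amp: float = 0.03
    trials_per_condition: int = 3
    blank_trials: int = 3
    heartbeat_amp: float = 0.0


@dataclass
class ReconstructStage:
    model: str = "shift_variant"
    gamma: float | None = None
    max_iter: int = 30
    dct_keep: int = 5
    tol: float = 1e-5
    single_precision: bool = True
    wiener_init: bool = True


@dataclass
class AnalyzeStage:
    stim_freq_hz: float = 4.0
    band_low_cpmm: float = 0.8
    band_high_cpmm: float = 2.5
    threshold_frac: float = 0.3333333333333333


@dataclass
class RunConfig:
    """Umbrella configuration; every random draw traces to ``seed``."""

    seed: int = 0
    out_dir: str = "contourscope_run"
    log_level: str = "INFO"
    stages: tuple = ("mask", "simulate", "phantom", "reconstruct", "analyze")
    mask: MaskStage = field(default_factory=MaskStage)
    simulate: SimulateStage = field(default_factory=SimulateStage)
    phantom: PhantomStage = field(default_factory=PhantomStage)
    reconstruct: ReconstructStage = field(default_factory=ReconstructStage)
    analyze: AnalyzeStage = field(default_factory=AnalyzeStage)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = _from_dict(cls, data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end to end; returns a summary dict.

    Any stage failure propagates after partial outputs are retained on disk;
    the failing stage is named in the log and in the raised error.
    """
    from . import analysis, forward, io, maskdesign, phantom, recon

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    seeds = {s: int(c.generate_state(1)[0] % (2**31)) for s, c in
             zip(("mask", "simulate", "phantom", "noise", "shuffle"),
                 rng_root.spawn(5))}
    summary: dict = {"config_digest": config.digest(), "seeds": seeds, "timings": {}}
    state: dict = {}

    def stage(name):
        return name in config.stages

    try:
        if stage("mask"):
            t0 = time.perf_counter()
            noise = maskdesign.generate_perlin_noise(
                config.mask.shape, config.mask.pixel_pitch_um,
                config.mask.feature_scale_um, seeds["mask"])
            pattern = maskdesign.contour_from_noise(
                noise, pattern_width=config.mask.pattern_width_um)
            design = maskdesign.design_phase_mask(
                pattern, config.mask.distance_mm, config.mask.wavelength_nm,
                n_iter=config.mask.n_iter, seed=seeds["mask"])
            io.save_pattern(out / "pattern.tif", pattern)
            io.save_phase_mask(out / "mask.tif", design.mask)
            state["mask"] = design.mask
            summary["mask_fidelity"] = design.final_fidelity
            summary["timings"]["mask"] = time.perf_counter() - t0

        if stage("simulate"):
            t0 = time.perf_counter()
            if "mask" not in state:
                raise RuntimeError("simulate stage requires the mask stage")
            g = config.simulate.grid_shape
            grid = forward.simulate_psf_grid(
                state["mask"], [config.simulate.depth_mm], (g, g),
                grid_extent_mm=config.simulate.grid_extent_mm,
                crop=config.simulate.psf_crop)
            io.save_psf_grid(out / "psf_grid.h5", grid)
            state["grid"] = grid
            summary["timings"]["simulate"] = time.perf_counter() - t0

        if stage("phantom"):
            t0 = time.perf_counter()
            ph = phantom.make_cortex_phantom(
                shape=(config.phantom.shape, config.phantom.shape),
                pixel_pitch_obj=config.phantom.pixel_pitch_obj_um,
                periodicity=config.phantom.periodicity_cpmm,
                dff_amp=config.phantom.dff_amp,
                seed=seeds["phantom"])
            io.save_phantom(out / "phantom.h5", ph)
            state["phantom"] = ph
            summary["timings"]["phantom"] = time.perf_counter() - t0

        if stage("reconstruct") or stage("analyze"):
            t0 = time.perf_counter()
            ph = state["phantom"]
            protocol = phantom.StimulusProtocol(
                trials_per_condition=config.phantom.trials_per_condition,
                blank_trials=config.phantom.blank_trials,
                seed=seeds["phantom"])
            grid = state.get("grid")
            videos, labels = [], []
            trial_list = [c for c in protocol.orientations
                          for _ in range(protocol.trials_per_condition)]
            trial_list += ["blank"] * protocol.blank_trials
            noise = {"heartbeat_amp": config.phantom.heartbeat_amp}
            cfg = recon.ReconConfig(
                model=config.reconstruct.model, gamma=config.reconstruct.gamma,
                max_iter=config.reconstruct.max_iter,
                tol=config.reconstruct.tol,
                dct_keep=config.reconstruct.dct_keep)
            dtype = np.float32 if config.reconstruct.single_precision else np.float64
            op = lip = central_psf = full_scale = None
            if grid is not None:
                shp = (config.phantom.shape, config.phantom.shape)
                op = forward.ShiftVariantOperator(
                    grid, shp, config.simulate.depth_mm, dtype=dtype)
                lip = 2.0 * op.norm_estimate() ** 2 + (
                    cfg.gamma if cfg.gamma is not None
                    else recon.default_gamma(grid.psfs[0, grid.psfs.shape[1] // 2,
                                                       grid.psfs.shape[2] // 2]))
                central_psf = grid.at_depth(config.simulate.depth_mm)
                central_psf = central_psf[central_psf.shape[0] // 2,
                                          central_psf.shape[1] // 2]
            for k, cond in enumerate(trial_list):
                vid = phantom.generate_trial_video(
                    ph, protocol, cond, noise=noise, seed=seeds["noise"] + k)
                if grid is not None:
                    meas = op.apply(vid.astype(dtype))
                    if full_scale is None:
                        # fix the digitizer full scale on the first trial so
                        # every frame shares one quantization grid
                        full_scale = 1.05 * float(meas.max())
                    counts = forward.add_sensor_noise(
                        meas, config.simulate.photon_scale,
                        config.simulate.read_sigma,
                        seed=seeds["noise"] + 10_000 + k, full_scale=full_scale)
                    b = counts.astype(dtype) / (2**8 - 1) * full_scale
                    if stage("reconstruct"):
                        gam = cfg.gamma if cfg.gamma is not None else \
                            recon.default_gamma(central_psf)
                        x0 = None
                        if config.reconstruct.wiener_init:
                            x0 = np.clip(np.stack([
                                recon.wiener_reconstruct(f, central_psf, gam)
                                for f in b]), 0, None).astype(dtype)
                        est = recon.fista_reconstruct(
                            b, grid, cfg, depth=config.simulate.depth_mm,
                            x0=x0, operator=op, lipschitz=lip, dtype=dtype)
                        vid = est.image
                    else:
                        vid = b
                videos.append(vid)
                labels.append(cond)
            trials = analysis.TrialSet(
                np.stack(videos), labels, frame_rate=protocol.frame_rate,
                onset_frame=protocol.onset_frame,
                pixel_pitch_obj=ph.pixel_pitch_obj)
            summary["timings"]["reconstruct"] = time.perf_counter() - t0

            if stage("analyze"):
                t0 = time.perf_counter()
                maps = analysis.orientation_pipeline(
                    trials, stim_freq=config.analyze.stim_freq_hz,
                    band=(config.analyze.band_low_cpmm, config.analyze.band_high_cpmm),
                    threshold_frac=config.analyze.threshold_frac)
                io.write_stack(out / "pref_map.tif",
                               maps.pref_map.astype(np.float32),
                               pixel_pitch=ph.pixel_pitch_obj, frame_rate=0.0)
                r = analysis.compare_maps(maps.pref_map, ph.pref_map, maps.roi_mask)
                summary["pref_map_vs_planted_r"] = r
                summary["corr_curve"] = dict(
                    zip(maps.corr_deltas.tolist(), maps.corr_curve.tolist()))
                summary["timings"]["analyze"] = time.perf_counter() - t0
                # in-memory handles for callers (not serialized)
                summary["_maps"] = maps
                summary["_phantom"] = ph
    except Exception as err:
        log.error("pipeline failed: %s", err)
        raise

    io.write_provenance(out / "provenance.json", config=config.to_dict(),
                        **{k: v for k, v in summary.items()
                           if not k.startswith("_")})
    summary["out_dir"] = str(out)
    return summary
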
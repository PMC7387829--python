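"""Seeded end-to-end pipelines and run manifests.

Each pipeline stage consumes the :class:`~blurfield.config.RunConfig`,
derives its own independent random stream from the single global seed
(so changing one stage's draw count cannot shift another's), writes its
artifacts under the output directory and records them in a manifest.
Re-running with the same configuration reproduces identical CSV/JSON
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .blur import BlurProfile, compose_spatially_varying, ring_table
from .config import RunConfig
from .eye import build_eye
from .io import imwrite_gray
from .isoplanatism import (corner_perturbations, isoplanatic_pupil,
                           sample_perturbations)
from .psychophysics import (FitError, SimulatedObserver, compare_zonal_global,
                            fit_gumbel, run_session, trials_to_frame)
from .stimulus import amplitude_slope, generate_binary_noise

__all__ = ["RunManifest", "run_pipeline", "PIPELINES", "stage_seeds"]

log = logging.getLogger("blurfield")

PIPELINES = ("isoplanatism", "stimulus", "blur", "experiment", "fit", "all")

#: fixed observer thresholds used by the simulated-observer stages: zonal
#: thresholds rise with eccentricity, global thresholds (peak a) fall with K
#: (steep profiles concentrate blur peripherally and tolerate a higher peak)
_DEFAULT_ZONAL_ALPHA = {1.5: 1.6, 3.0: 1.8, 4.5: 2.2, 6.0: 2.8, 7.5: 3.4}
_DEFAULT_GLOBAL_ALPHA = {-0.8: 1.8, -0.53: 2.0, 1.1: 2.6, 4.0: 3.2, 16.7: 3.8}


def stage_seeds(seed: int) -> dict:
    """Expand the global seed into independent per-stage integer seeds."""
    names = ("isoplanatism", "stimulus", "blur", "experiment", "fit")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    artifacts: list = dc_field(default_factory=list)
    version: str = _version
    stages_completed: list = dc_field(default_factory=list)
    stages_failed: dict = dc_field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_isoplanatism(config: RunConfig, outdir: Path, seed: int) -> list:
    eye = build_eye(config.wavelength_nm)
    ens = sample_perturbations(config.mc_draws, config.tip_tilt_bound_deg,
                               config.decenter_bound_mm, seed)
    ens = ens.extended(corner_perturbations(config.tip_tilt_bound_deg,
                                            config.decenter_bound_mm))
    report = isoplanatic_pupil(eye, config.extent_deg,
                               config.pupil_grid_mm, ens,
                               criterion=config.strehl_criterion,
                               pupil_samples=config.pupil_samples,
                               eccentricities_deg=config.eccentricities_deg)
    out = outdir / "isoplanatism_report.json"
    report.save(out)
    rows = [{"pupil_mm": p, "worst_strehl": wc.strehl, "worst_rms_um": wc.rms_um,
             "ecc_deg": wc.argmin_field.eccentricity_deg,
             "meridian_deg": wc.argmin_field.meridian_deg,
             "tip": wc.argmin_perturbation.tip_deg,
             "tilt": wc.argmin_perturbation.tilt_deg,
             "dx": wc.argmin_perturbation.decenter_x_mm,
             "dy": wc.argmin_perturbation.decenter_y_mm,
             "exhaustive": wc.exhaustive}
            for p, wc in report.per_pupil.items()]
    csv = outdir / "isoplanatism_worst_cases.csv"
    pd.DataFrame(rows).to_csv(csv, index=False, float_format="%.6g")
    return [str(out), str(csv)]


def _stage_stimulus(config: RunConfig, outdir: Path, seed: int) -> list:
    stim = generate_binary_noise(seed=seed, size_px=config.display_size_px,
                                 scale_arcmin=config.pixel_scale_arcmin,
                                 e2_deg=config.magnification_e2_deg,
                                 n_bands=config.n_rings,
                                 extent_deg=config.blur_extent_deg,
                                 central_cutoff_cpd=config.stimulus_central_cutoff_cpd)
    png = outdir / "stimulus.png"
    imwrite_gray(png, stim.pixels)
    fit = amplitude_slope(stim)
    sidecar = outdir / "stimulus.json"
    with open(sidecar, "w") as fh:
        json.dump({"seed": seed, "size_px": config.display_size_px,
                   "pixel_scale_arcmin": config.pixel_scale_arcmin,
                   "magnification_e2_deg": config.magnification_e2_deg,
                   "central_cutoff_cpd": config.stimulus_central_cutoff_cpd,
                   "spectral_slope": fit.slope,
                   "slope_r_squared": fit.r_squared}, fh, indent=2)
    return [str(png), str(sidecar)]


def _stage_blur(config: RunConfig, outdir: Path, seed: int) -> list:
    stim = generate_binary_noise(seed=seed, size_px=config.display_size_px,
                                 scale_arcmin=config.pixel_scale_arcmin,
                                 e2_deg=config.magnification_e2_deg,
                                 n_bands=config.n_rings,
                                 extent_deg=config.blur_extent_deg,
                                 central_cutoff_cpd=config.stimulus_central_cutoff_cpd)
    artifacts = []
    for K in config.profile_k_list:
        profile = BlurProfile(K=K, peak_a_D=config.profile_peak_a_D,
                              extent_deg=config.blur_extent_deg,
                              n_rings=config.n_rings)
        blurred, table = compose_spatially_varying(
            stim.pixels.astype(float), profile,
            scale_arcmin=config.pixel_scale_arcmin)
        png = outdir / f"blurred_K{K:g}.png"
        imwrite_gray(png, blurred / 255.0)
        csv = outdir / f"rings_K{K:g}.csv"
        table.to_csv(csv, index=False, float_format="%.6g")
        artifacts += [str(png), str(csv)]
    return artifacts


def _observer(config: RunConfig, seed: int) -> SimulatedObserver:
    alphas = {**{str(z): a for z, a in _DEFAULT_ZONAL_ALPHA.items()},
              **{f"K={k:g}": a for k, a in _DEFAULT_GLOBAL_ALPHA.items()}}
    return SimulatedObserver(alphas, true_beta=config.observer_beta, seed=seed)


def _stage_experiment(config: RunConfig, outdir: Path, seed: int) -> list:
    obs = _observer(config, seed + 1)
    zonal = [str(z) for z in config.zone_outer_deg]
    glob = [f"K={k:g}" for k in config.profile_k_list]
    starts = {**{c: config.start_level_zonal_D for c in zonal},
              **{c: config.start_level_global_D for c in glob}}
    records = run_session(zonal + glob, obs, config.trials_per_condition,
                          seed=seed, start_levels=starts)
    csv = outdir / "trials.csv"
    trials_to_frame(records).to_csv(csv, index=False, float_format="%.6g")
    return [str(csv)]


def _stage_fit(config: RunConfig, outdir: Path, seed: int) -> list:
    trials = pd.read_csv(outdir / "trials.csv")
    records = [type("R", (), {"trial_index": r.trial, "condition_id": str(r.condition),
                              "level_D": r.level_D, "bothersome": bool(r.bothersome)})()
               for r in trials.itertuples()]
    fits = {}
    for i, cond in enumerate(sorted(set(r.condition_id for r in records))):
        try:
            fit = fit_gumbel(records, cond)
            fit.bootstrap_se(n_boot=config.n_boot, seed=seed + i)
            fits[cond] = fit
        except FitError as exc:
            log.warning("condition %s not fittable (%s); skipped", cond, exc)
    out = outdir / "fits.json"
    with open(out, "w") as fh:
        json.dump({c: f.to_json_dict() for c, f in fits.items()}, fh, indent=2)
    artifacts = [str(out)]
    zonal = {float(c): f.threshold_D for c, f in fits.items()
             if not c.startswith("K=")}
    glob = {float(c[2:]): f.threshold_D for c, f in fits.items()
            if c.startswith("K=")}
    all_conditions_fit = len(fits) == len(set(r.condition_id for r in records))
    if zonal and glob and all_conditions_fit:
        comparison = compare_zonal_global(zonal, glob,
                                          extent_deg=config.blur_extent_deg,
                                          n_rings=config.n_rings,
                                          zone_width_deg=config.zone_width_deg)
        csv = outdir / "zonal_global_differences.csv"
        comparison.differences.to_csv(csv, float_format="%.6g")
        artifacts.append(str(csv))
    return artifacts


_STAGES = {"isoplanatism": _stage_isoplanatism, "stimulus": _stage_stimulus,
           "blur": _stage_blur, "experiment": _stage_experiment,
           "fit": _stage_fit}


def run_pipeline(config: RunConfig, pipeline_name: str,
                 output_dir=None) -> RunManifest:
    """Execute one named stage (or ``all``) and write a run manifest."""
    if pipeline_name not in PIPELINES:
        raise ValueError(f"unknown pipeline '{pipeline_name}'; "
                         f"choose from {PIPELINES}")
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(config_hash=_config_hash(config), seeds=seeds)
    names = list(_STAGES) if pipeline_name == "all" else [pipeline_name]
    for name in names:
        t0 = time.time()
        log.info("stage=%s seed=%d starting", name, seeds[name])
        try:
            manifest.artifacts += _STAGES[name](config, outdir, seeds[name])
            manifest.stages_completed.append(name)
            log.info("stage=%s runtime=%.1fs done", name, time.time() - t0)
        except Exception as exc:   # record partial completion
            manifest.stages_failed[name] = repr(exc)
            log.error("stage=%s failed: %r", name, exc)
            if pipeline_name != "all":
                manifest.save(outdir / "manifest.json")
                raise
    manifest.save(outdir / "manifest.json")
    return manifest
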
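"""End-to-end purification-QC pipeline with machine-readable reports.

Mirrors the analysis sequence of an RZC purification experiment: AFM height
maps (before and after purification) -> mixture-CDF staple quantification
and staple-reduction fold -> particle census with half-subset bootstrap SEs
-> gradient-profile reproducibility. Runs either on synthetic scenes
(specs in the config) or on user-supplied files; identical config + seed
produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from . import io as oqio
from .census import analyze_map
from .gradient import classify_profile, mean_absolute_deviation
from .mixture import HeightMap, MixtureFit, fit_height_mixture, staple_reduction
from .resampling import half_subset_se
from .synthetic import SceneSpec, generate_afm_scene, generate_gradient_replicates

__all__ = ["PipelineConfig", "PurityReport", "run_pipeline", "demo_config"]

logger = logging.getLogger("origamiqc")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full QC run.

    In synthetic mode, ``scene_before``/``scene_after`` describe the AFM
    scenes and the gradient block describes the simulated tubes; in user
    mode the ``*_path`` fields point at existing files written in the
    formats of :mod:`origamiqc.io`.
    """

    mode: str = "synthetic"  # "synthetic" | "user"
    outdir: str = "origamiqc_out"
    seed: int = 0
    log_level: str = "INFO"
    # stage toggles
    run_mixture: bool = True
    run_census: bool = True
    run_gradient: bool = True
    # synthetic mode
    scene_before: Optional[SceneSpec] = None
    scene_after: Optional[SceneSpec] = None
    gradient_n_replicates: int = 20
    gradient_shape: str = "linear"
    gradient_n_points: int = 100
    gradient_noise_sd: float = 0.02
    # user mode
    map_before_path: Optional[str] = None
    map_after_path: Optional[str] = None
    profiles_path: Optional[str] = None
    # analysis parameters
    mixture_restarts: int = 3
    census_threshold_nm: Optional[float] = None
    census_min_area_px: int = 6
    bootstrap_resamples: int = 10_000

    def validate(self) -> None:
        if self.mode not in ("synthetic", "user"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.run_mixture or self.run_census or self.run_gradient):
            raise ValueError("all stages are disabled; nothing to do")
        if self.mode == "synthetic":
            if (self.run_mixture or self.run_census) and (
                    self.scene_before is None or self.scene_after is None):
                raise ValueError("synthetic mode requires scene_before and scene_after")
        else:
            if self.run_mixture or self.run_census:
                for name in ("map_before_path", "map_after_path"):
                    p = getattr(self, name)
                    if p is None or not Path(p).exists():
                        raise ValueError(f"user mode requires existing {name}")
            if self.run_gradient and (self.profiles_path is None
                                      or not Path(self.profiles_path).exists()):
                raise ValueError("user mode requires an existing profiles_path")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PurityReport:
    """Aggregated pipeline results; every stochastic number carries its seed."""

    provenance: dict[str, Any]
    mixture: Optional[dict[str, Any]] = None
    census: Optional[dict[str, Any]] = None
    gradient: Optional[dict[str, Any]] = None
    manifest: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def demo_config(outdir: str, seed: int = 1) -> PipelineConfig:
    """A small synthetic demo: a staple-crowded scene before purification,
    a cleaner one after."""
    before = SceneSpec(width_px=384, height_px=384, n_staples=7000,
                       n_monomers=5, n_dimers=2, seed=seed)
    after = SceneSpec(width_px=384, height_px=384, n_staples=1400,
                      n_monomers=2, n_dimers=4, seed=seed + 1)
    return PipelineConfig(mode="synthetic", outdir=outdir, seed=seed,
                          scene_before=before, scene_after=after)


def _fit_section(fit: MixtureFit) -> dict[str, Any]:
    return json.loads(fit.to_json())


def _census_section(cfg: PipelineConfig, hm: HeightMap, threshold: float,
                    seed: int, outdir: Path, tag: str) -> dict[str, Any]:
    particles, cen = analyze_map(hm, threshold, cfg.census_min_area_px)
    oqio.write_particles(outdir / f"particles_{tag}.csv", particles)
    section: dict[str, Any] = {
        "n_monomer": cen.n_monomer, "n_dimer": cen.n_dimer, "n_other": cen.n_other,
        "monomer_fraction": cen.monomer_fraction,
        "dimer_fraction": cen.dimer_fraction,
    }
    n_counted = cen.n_monomer + cen.n_dimer
    if n_counted >= 2:
        binary = [1] * cen.n_dimer + [0] * cen.n_monomer
        boot = half_subset_se(binary, n_resamples=cfg.bootstrap_resamples, seed=seed)
        section["bootstrap"] = dataclasses.asdict(boot)
    return section


def run_pipeline(config: PipelineConfig) -> PurityReport:
    """Execute the enabled stages, writing per-stage artifacts and report.json.

    Any stage failure aborts with a stage-named error; artifacts of
    completed stages remain on disk together with a MANIFEST.json.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = PurityReport(provenance={
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "origamiqc_version": __version__,
    })

    def finish_stage(name: str) -> None:
        report.manifest.append(name)
        (outdir / "MANIFEST.json").write_text(json.dumps(report.manifest, indent=2))

    # -- inputs ------------------------------------------------------------
    stage = "inputs"
    try:
        if config.mode == "synthetic":
            hm_before = hm_after = None
            if config.run_mixture or config.run_census:
                hm_before, _ = generate_afm_scene(config.scene_before)
                hm_after, _ = generate_afm_scene(config.scene_after)
                oqio.write_height_map(outdir / "map_before.tif", hm_before)
                oqio.write_height_map(outdir / "map_after.tif", hm_after)
            profiles = None
            if config.run_gradient:
                profiles = generate_gradient_replicates(
                    config.gradient_n_replicates, config.gradient_shape,
                    config.gradient_n_points, config.gradient_noise_sd,
                    seed=config.seed + 101)
                oqio.write_profiles(outdir / "profiles.csv", profiles)
        else:
            hm_before = hm_after = profiles = None
            if config.run_mixture or config.run_census:
                hm_before = oqio.read_height_map(config.map_before_path)
                hm_after = oqio.read_height_map(config.map_after_path)
            if config.run_gradient:
                profiles = oqio.read_profiles(config.profiles_path)
        finish_stage(stage)

        if config.run_mixture:
            stage = "mixture"
            logger.info("fitting height mixtures")
            fit_before = fit_height_mixture(hm_before, n_restarts=config.mixture_restarts,
                                            seed=config.seed + 11)
            fit_after = fit_height_mixture(hm_after, n_restarts=config.mixture_restarts,
                                           seed=config.seed + 12)
            (outdir / "fit_before.json").write_text(fit_before.to_json())
            (outdir / "fit_after.json").write_text(fit_after.to_json())
            report.mixture = {
                "before": _fit_section(fit_before),
                "after": _fit_section(fit_after),
                "staple_reduction_fold": staple_reduction(fit_before, fit_after),
            }
            finish_stage(stage)

        if config.run_census:
            stage = "census"
            logger.info("running particle census")
            if config.census_threshold_nm is not None:
                threshold = config.census_threshold_nm
            elif config.mode == "synthetic":
                # midway between background and origami: high enough to drop
                # staple blobs (with the area filter), low enough that pixel
                # noise cannot cut a thin tube
                spec = config.scene_before
                threshold = 0.5 * (spec.mica_mu + spec.origami_mu)
            else:
                raise ValueError("census_threshold_nm is required in user mode")
            report.census = {
                "threshold_nm": threshold,
                "before": _census_section(config, hm_before, threshold,
                                          config.seed + 21, outdir, "before"),
                "after": _census_section(config, hm_after, threshold,
                                         config.seed + 22, outdir, "after"),
            }
            finish_stage(stage)

        if config.run_gradient:
            stage = "gradient"
            logger.info("gradient QC")
            repro = mean_absolute_deviation(profiles)
            report.gradient = {
                "shapes": [classify_profile(p) for p in profiles],
                "per_replicate_mad_pct": repro.per_replicate_mad,
                "mean_mad_pct": repro.mean_mad,
                "sd_mad_pct": repro.sd_mad,
                "n_replicates": repro.n_replicates,
            }
            finish_stage(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str))
    return report
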
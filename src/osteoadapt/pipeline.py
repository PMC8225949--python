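"""Run orchestration: forward simulation, fitting and validation from a
single YAML configuration, with provenance.

Every run writes its artifacts plus a ``provenance.json`` recording the
resolved configuration, its hash, the seed, package versions and per-stage
wall times — enough to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .fitting import FitResult
from .image import GrayImage, read_image, write_image
from .imageproc import binarize
from .microfe import LoadCase, Material
from .model import BoneAdaptationModel
from .morphometry import densitometrics, make_partition, second_moments
from .phantom import PhantomSpec, evolve_phantom, make_phantom
from .remodeling import Calibration, RemodelingParams, step

__all__ = ["RunConfig", "run_forward", "run_fit", "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Declarative description of a run.

    Exactly one input mode: either ``phantom`` (an inline
    :class:`PhantomSpec` description) or ``baseline_path`` (+
    ``followup_path`` for fitting).  Defaults mirror the experimental
    configuration: E = 14.8 GPa, nu = 0.3, 12 N axial peak,
    0.01355/0.00289 N/g physiological coefficients, 10 sections, one 2-week
    step.
    """

    output_dir: str = "runs/out"
    seed: int = 0
    phantom: dict | None = None
    baseline_path: str | None = None
    followup_path: str | None = None
    load: dict = field(default_factory=lambda: {"kind": "combined", "bw": 22.0})
    material: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    n_sections: int = 10
    threshold: float | None = None
    params: dict | None = None  # forward-run remodeling parameters
    steps: int = 1
    fit: dict = field(default_factory=dict)  # n_starts, seed, bounds, n_presample, ...

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, need_followup: bool = False) -> None:
        modes = sum([self.phantom is not None, self.baseline_path is not None])
        if modes != 1:
            raise ConfigError("exactly one of 'phantom' or 'baseline_path' is required")
        if self.baseline_path is not None and not Path(self.baseline_path).exists():
            raise ConfigError(f"baseline_path does not exist: {self.baseline_path}")
        if need_followup and self.phantom is None:
            if self.followup_path is None:
                raise ConfigError("fitting requires a followup_path (or a phantom)")
            if not Path(self.followup_path).exists():
                raise ConfigError(f"followup_path does not exist: {self.followup_path}")

    # -- constructors for the domain objects ---------------------------------
    def load_case(self) -> LoadCase:
        return LoadCase(**self.load)

    def material_obj(self) -> Material:
        return Material(**self.material)

    def calibration_obj(self) -> Calibration:
        return Calibration(**self.calibration)

    def params_obj(self) -> RemodelingParams:
        if self.params is None:
            raise ConfigError("forward run requires remodeling 'params'")
        return RemodelingParams(**self.params)

    def phantom_spec(self) -> PhantomSpec:
        assert self.phantom is not None
        d = dict(self.phantom)
        d.setdefault("seed", self.seed)
        if "calibration" in d:
            d["calibration"] = Calibration(**d["calibration"])
        else:
            d["calibration"] = self.calibration_obj()
        d["grid_shape"] = tuple(d["grid_shape"])
        return PhantomSpec(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig, stages: dict[str, float], extra: dict) -> dict:
    return {
        "package": "osteoadapt",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_wall_times_s": stages,
        **extra,
    }


class _StageTimer:
    def __init__(self) -> None:
        self.times: dict[str, float] = {}

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        dt = time.perf_counter() - t0
        self.times[name] = round(dt, 3)
        logger.info("stage %-12s %8.2f s", name, dt)
        return out


def _ingest_baseline(config: RunConfig) -> GrayImage:
    if config.phantom is not None:
        image, _ = make_phantom(config.phantom_spec())
        return image
    assert config.baseline_path is not None
    return read_image(config.baseline_path)


def run_forward(config: RunConfig) -> dict[str, Path]:
    """Forward simulation: baseline -> pseudo-CT follow-up(s) + morphometry
    + SED volume, with provenance."""
    config.validate()
    params = config.params_obj()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timer = _StageTimer()

    baseline = timer.run("ingest", _ingest_baseline, config)
    load = config.load_case()
    calib = config.calibration_obj()
    material = config.material_obj()

    def _one_step(img: GrayImage):
        return step(
            img, params, load, calib, material=material,
            threshold=config.threshold, return_info=True,
        )

    current = baseline
    info = None
    for i in range(config.steps):
        current, info = timer.run(f"step_{i}", _one_step, current)
    assert info is not None

    paths: dict[str, Path] = {}
    paths["baseline"] = out / "baseline.mha"
    paths["pseudo_ct"] = out / "pseudo_ct.mha"
    paths["sed"] = out / "sed.mha"
    write_image(baseline, paths["baseline"])
    write_image(current, paths["pseudo_ct"])
    if info.sed is not None:
        write_image(info.sed.as_image(), paths["sed"])

    def _morpho():
        partition = make_partition(current.n_slices, config.n_sections)
        mask = binarize(current, info.threshold)
        dens = densitometrics(current, mask, calib, partition)
        mom = second_moments(mask, partition)
        return dens, mom

    dens, mom = timer.run("morphometry", _morpho)
    paths["densitometrics"] = out / "densitometrics.csv"
    paths["second_moments"] = out / "second_moments.csv"
    dens.to_csv(paths["densitometrics"])
    mom.to_csv(paths["second_moments"])

    prov = _provenance(
        config, timer.times,
        {
            "threshold": info.threshold,
            "solver_residual": info.solver_residual,
            "n_elements": int(info.mask.voxel_count),
        },
    )
    paths["provenance"] = out / "provenance.json"
    paths["provenance"].write_text(json.dumps(prov, indent=2))
    return paths


def run_fit(config: RunConfig) -> tuple[FitResult, dict[str, Path]]:
    """Fit the remodeling parameters and emit the full validation report."""
    config.validate(need_followup=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timer = _StageTimer()

    if config.phantom is not None:
        # self-generated pair: evolve the phantom with the configured params
        spec = config.phantom_spec()
        baseline, _ = timer.run("phantom", make_phantom, spec)
        followup = timer.run(
            "evolve", evolve_phantom,
            baseline, config.params_obj(), config.load_case(),
            spec.calibration, config.steps, config.material_obj(), config.threshold,
        )
        calib = spec.calibration
    else:
        baseline = timer.run("ingest", read_image, config.baseline_path)
        followup = timer.run("ingest_followup", read_image, config.followup_path)
        calib = config.calibration_obj()

    model = BoneAdaptationModel(
        baseline, followup, config.load_case(), calib,
        material=config.material_obj(), n_sections=config.n_sections,
        threshold=config.threshold,
    )
    fit_kwargs = dict(config.fit)
    fit_kwargs.setdefault("seed", config.seed)
    results = timer.run("fit", model.fit, **fit_kwargs)

    paths: dict[str, Path] = {}
    paths["fit_report"] = out / "fit_report.json"
    paths["residuals"] = out / "moment_residuals.csv"
    paths["scoreboard"] = out / "scoreboard.csv"
    paths["densitometrics"] = out / "densitometrics.csv"
    paths["summary"] = out / "summary.txt"

    fr = results.fit_result
    paths["fit_report"].write_text(
        json.dumps(
            {
                "params": {
                    "apposition_rate": fr.params.apposition_rate,
                    "resorption_rate": fr.params.resorption_rate,
                    "sed_threshold": fr.params.sed_threshold,
                },
                "objective": fr.objective,
                "start_objectives": list(fr.start_objectives),
                "start_points": [list(p) for p in fr.start_points],
                "bounds": [list(b) for b in fr.bounds],
                "seed": fr.seed,
                "converged": fr.converged,
            },
            indent=2,
        )
    )
    fr.residuals.to_csv(paths["residuals"])
    timer.run("validate", lambda: results.scoreboard().to_csv(paths["scoreboard"], index=False))
    timer.run("densitometrics", lambda: results.densitometrics().to_csv(paths["densitometrics"]))
    paths["summary"].write_text(results.summary() + "\n")

    prov = _provenance(config, timer.times, {"objective": fr.objective})
    paths["provenance"] = out / "provenance.json"
    paths["provenance"].write_text(json.dumps(prov, indent=2))
    return fr, paths
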
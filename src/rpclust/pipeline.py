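"""End-to-end orchestration: simulate (or preprocess) -> fit -> summarize,
driven by a YAML/dict configuration, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ConsumptionMatrix
from .model import MCMCConfig, PosteriorSamples, PriorSpec, run_mcmc
from .postprocess import prune_and_relabel
from .preprocessing import categorize, fit_categorization
from .synthetic import generate_dataset, nhanes_like_spec


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


_KNOWN_STAGES = ("simulate", "preprocess", "fit", "summarize")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "stages" not in cfg:
        raise ConfigError("config must be a mapping with a 'stages' section")
    unknown = [s for s in cfg["stages"] if s not in _KNOWN_STAGES]
    if unknown:
        raise ConfigError(
            f"unknown stages {unknown}; known stages: {list(_KNOWN_STAGES)}")
    if "simulate" in cfg["stages"] and "preprocess" in cfg["stages"]:
        raise ConfigError("choose either 'simulate' or 'preprocess', not both")
    return cfg


def run_pipeline(config, outdir) -> RunManifest:
    """Execute the configured stages in order; a stage failure aborts with
    the stage name while earlier outputs stay on disk."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(config=cfg, seed=seed)
    stages = cfg["stages"]

    data: ConsumptionMatrix | None = None
    samples: PosteriorSamples | None = None
    try:
        if "simulate" in stages:
            sim = stages["simulate"] or {}
            spec = nhanes_like_spec(sim.get("preset", "tiny"),
                                    size_factor=sim.get("size_factor", 1.0),
                                    seed=sim.get("seed", seed))
            data, truth = generate_dataset(spec)
            data.to_csv(outdir / "data.csv")
            truth.to_json(outdir / "truth.json")
            manifest.outputs["data"] = str(outdir / "data.csv")
            manifest.outputs["truth"] = str(outdir / "truth.json")
            manifest.stages.append("simulate")
        if "preprocess" in stages:
            pp = stages["preprocess"] or {}
            if "amounts" not in pp:
                raise ConfigError("preprocess stage needs an 'amounts' CSV")
            amounts = pd.read_csv(pp["amounts"], index_col=0)
            manifest.input_hashes[pp["amounts"]] = _sha256(pp["amounts"])
            sub = None
            if "subgroup_col" in pp:
                sub_raw = amounts.pop(pp["subgroup_col"])
                codes, _ = pd.factorize(sub_raw)
                sub = codes + 1
            rule = fit_categorization(amounts, d=pp.get("d", 4))
            rule.to_json(outdir / "categorization_rule.json")
            data = categorize(amounts, rule, subgroup=sub)
            data.to_csv(outdir / "data.csv")
            manifest.outputs["data"] = str(outdir / "data.csv")
            manifest.outputs["rule"] = str(outdir / "categorization_rule.json")
            manifest.stages.append("preprocess")
        if "fit" in stages:
            if data is None:
                fit_cfg = stages["fit"] or {}
                if "data" not in fit_cfg:
                    raise PipelineError(
                        "fit stage: no upstream data stage and no 'data' "
                        "path given")
                data = ConsumptionMatrix.from_csv(fit_cfg["data"])
                manifest.input_hashes[fit_cfg["data"]] = _sha256(
                    fit_cfg["data"])
            fit_cfg = stages["fit"] or {}
            mcfg = MCMCConfig(
                n_iter=fit_cfg.get("n_iter", 2000),
                k0_max=fit_cfg.get("k0", 30),
                ks_max=fit_cfg.get("ks", 30),
                burn_in=fit_cfg.get("burn_in"),
                thin=fit_cfg.get("thin", 5),
                seed=fit_cfg.get("seed", seed),
                nu_fixed=fit_cfg.get("nu_fixed"),
            )
            samples = run_mcmc(data, mcfg, PriorSpec())
            samples.save(outdir / "draws")
            manifest.outputs["draws"] = str(outdir / "draws")
            manifest.stages.append("fit")
        if "summarize" in stages:
            if samples is None:
                sm = stages["summarize"] or {}
                draws_dir = sm.get("draws", manifest.outputs.get("draws"))
                if draws_dir is None or not Path(draws_dir).exists():
                    raise PipelineError(
                        "summarize stage: no fitted draws available; run "
                        "the fit stage or point 'draws' at an existing run")
                samples = PosteriorSamples.load(draws_dir)
            sm = stages["summarize"] or {}
            summary = prune_and_relabel(
                samples, occupancy_threshold=sm.get("threshold", 0.05))
            summary.modal_global_frame().to_csv(
                outdir / "modal_global.csv", index=False)
            summary.modal_local_frame().to_csv(
                outdir / "modal_local.csv", index=False)
            summary.heatmap_frame().to_csv(
                outdir / "allocation_heatmap.csv", index=False)
            if sm.get("figures", False):
                from . import plots
                plots.plot_modal_patterns(summary,
                                          outdir / "modal_global.png")
                plots.plot_allocation_heatmap(
                    summary, outdir / "allocation_heatmap.png")
                plots.plot_local_patterns(summary,
                                          outdir / "local_patterns.png")
            for key in ("modal_global", "modal_local", "allocation_heatmap"):
                manifest.outputs[key] = str(outdir / f"{key}.csv")
            manifest.stages.append("summarize")
    except (ConfigError, PipelineError):
        raise
    except Exception as exc:  # annotate with the failing stage
        done = set(manifest.stages)
        current = next((s for s in _KNOWN_STAGES
                        if s in stages and s not in done), "?")
        raise PipelineError(f"stage '{current}' failed: {exc}") from exc

    manifest.to_json(outdir / "manifest.json")
    return manifest
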
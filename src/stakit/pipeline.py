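"""End-to-end pipeline driver: simulate → align → classify → modes →
curvature, with a versioned YAML configuration and provenance-stamped
products.

All randomness flows from the single global seed through named per-stage
substreams (``numpy.random.SeedSequence``); a rerun with the same config
and seed is bit-reproducible for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .align import AlignmentConfig, SubtomogramAlignment
from .classify import (
    ClassificationConfig,
    MultireferenceClassification,
    prune_classes,
)
from .curvature import CurvatureConfig, MembraneCurvatureModel
from .modes import EigenvolumeAnalysis, align_class_averages, mode_halfmaps
from .phantom import ClassDeformation, EnsembleSpec, PhantomSpec, simulate_ensemble

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1
DEFAULT_STAGES = ["simulate", "align", "classify", "modes", "curvature"]

_STAGE_SEED_NAMES = {name: i for i, name in enumerate(DEFAULT_STAGES)}


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return validate_config(config)


def validate_config(config: dict) -> dict:
    config = dict(config or {})
    config.setdefault("version", CONFIG_VERSION)
    if config["version"] != CONFIG_VERSION:
        raise PipelineError(f"unsupported config version {config['version']}")
    config.setdefault("seed", 0)
    config.setdefault("stages", list(DEFAULT_STAGES))
    unknown = [s for s in config["stages"] if s not in DEFAULT_STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _STAGE_SEED_NAMES[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _build_specs(config: dict):
    sim = dict(config.get("simulate", {}))
    deformations = tuple(
        ClassDeformation(**d) for d in sim.pop("deformations", [{"name": "base"}])
    )
    occupancies = tuple(sim.pop("class_occupancies", [1.0]))
    ens_keys = {
        "n_particles",
        "tilt_sigma_deg",
        "tilt_max_deg",
        "shift_max_a",
        "init_pose_error_deg",
    }
    ens_kw = {k: sim.pop(k) for k in list(sim) if k in ens_keys}
    if "box" in sim:
        pspec = PhantomSpec.scaled(
            sim.pop("box"), sim.pop("voxel_size", 5.4), **sim
        )
    else:
        pspec = PhantomSpec(**sim)
    espec = EnsembleSpec(
        class_occupancies=occupancies,
        class_deformations=deformations,
        seed=_stage_seed(config["seed"], "simulate"),
        **ens_kw,
    )
    return pspec, espec


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the results directory.

    Every product directory carries ``provenance.yaml`` with the config
    hash, the global seed, the package version and a per-stage log.  A
    stage failure halts the run with a stage-scoped error; products of
    completed stages are kept.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = validate_config(config)
    outdir = Path(output_dir or config.get("output_dir", "sta_results"))
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("stakit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage_log: list[dict] = []
    state: dict = {}
    try:
        for stage in config["stages"]:
            t0 = time.time()
            logger.info("stage %s starting", stage)
            try:
                _STAGE_FUNCS[stage](config, state, outdir)
            except Exception as exc:
                raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
            stage_log.append(
                {"stage": stage, "seconds": round(time.time() - t0, 2)}
            )
            logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    finally:
        provenance = {
            "config_hash": config_hash(config),
            "seed": config["seed"],
            "stakit_version": __version__,
            "stages_completed": stage_log,
            "config": config,
        }
        with open(outdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(provenance, fh, sort_keys=False)
        root.removeHandler(handler)
        handler.close()
    return outdir


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: dict, state: dict, outdir: Path) -> None:
    pspec, espec = _build_specs(config)
    ens = simulate_ensemble(espec, pspec)
    state["ensemble"] = ens
    ens.truth.write(outdir / "truth.tsv")
    ens.working.write(outdir / "particles.tsv")
    sio.write_volume(ens.class_volumes[0], outdir / "ground_truth_class0.mrc")
    logger.info(
        "simulated %d particles, %d classes, box %d, snr %.2f",
        len(ens.volumes),
        len(ens.class_volumes),
        pspec.box,
        pspec.snr,
    )


def _stage_align(config: dict, state: dict, outdir: Path) -> None:
    ens = state.get("ensemble")
    if ens is None:
        raise PipelineError("align requires the simulate stage")
    kw = dict(config.get("align", {}))
    kw.setdefault("seed", _stage_seed(config["seed"], "align"))
    cfg = AlignmentConfig(**kw)
    logger.info("align config: %s", asdict(cfg))
    model = SubtomogramAlignment(
        ens.volumes,
        ens.working,
        wedge=ens.wedge,
        tilt_scheme=ens.phantom_spec.tilt_scheme,
        config=cfg,
    )
    results = model.fit("auto")
    state["alignment"] = results
    results.save(outdir)
    with open(outdir / "alignment_summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")


def _stage_classify(config: dict, state: dict, outdir: Path) -> None:
    ens = state.get("ensemble")
    align_res = state.get("alignment")
    if ens is None or align_res is None:
        raise PipelineError("classify requires simulate and align stages")
    kw = dict(config.get("classify", {}))
    k = kw.pop("k", 4)
    min_fraction = kw.pop("min_fraction", 0.01)
    exclude = kw.pop("exclude_classes", [])
    kw.setdefault("seed", _stage_seed(config["seed"], "classify"))
    cfg = ClassificationConfig(**kw)
    model = MultireferenceClassification(
        ens.volumes,
        align_res.particles,
        k,
        ens.wedge,
        ens.phantom_spec.tilt_scheme,
        global_average=align_res.average,
        config=cfg,
    )
    results = prune_classes(model.fit(), min_fraction, exclude)
    state["classification"] = results
    cls_dir = outdir / "classes"
    results.save(cls_dir)
    with open(outdir / "classification_summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")


def _stage_modes(config: dict, state: dict, outdir: Path) -> None:
    cls = state.get("classification")
    if cls is None:
        raise PipelineError("modes requires the classify stage")
    kw = dict(config.get("modes", {}))
    n_modes = kw.pop("n_modes", 3)
    averages = [cls.class_averages[c] for c in cls.retained if cls.class_averages[c] is not None]
    if len(averages) < 3:
        logger.warning("fewer than 3 class averages; skipping mode analysis")
        return
    aligned, _, _ = align_class_averages(averages)
    decomposition = EigenvolumeAnalysis(aligned).fit()
    state["modes"] = decomposition
    mode_dir = outdir / "modes"
    mode_dir.mkdir(exist_ok=True)
    decomposition.informativity_table().to_csv(
        mode_dir / "informativity.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        decomposition.eigencoefficients,
        columns=[f"mode_{m+1}" for m in range(decomposition.n_modes)],
    ).to_csv(mode_dir / "eigencoefficients.tsv", sep="\t", index=False)
    for m in range(min(n_modes, decomposition.n_modes)):
        sio.write_volume(decomposition.eigenvolumes[m], mode_dir / f"eigenvolume_{m+1}.mrc")
        if decomposition.n_inputs >= 4:
            lo, hi = mode_halfmaps(decomposition, m + 1)
            sio.write_volume(lo, mode_dir / f"mode_{m+1}_low.mrc")
            sio.write_volume(hi, mode_dir / f"mode_{m+1}_high.mrc")
    with open(mode_dir / "summary.txt", "w") as fh:
        fh.write(decomposition.summary() + "\n")


def _stage_curvature(config: dict, state: dict, outdir: Path) -> None:
    align_res = state.get("alignment")
    if align_res is None:
        raise PipelineError("curvature requires the align stage")
    kw = dict(config.get("curvature", {}))
    cfg = CurvatureConfig(**kw)
    fit = MembraneCurvatureModel(align_res.average, cfg).fit()
    state["curvature"] = fit
    fit.scores.to_csv(outdir / "curvature_profile.tsv", sep="\t", index=False)
    with open(outdir / "curvature_summary.txt", "w") as fh:
        fh.write(fit.summary() + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "align": _stage_align,
    "classify": _stage_classify,
    "modes": _stage_modes,
    "curvature": _stage_curvature,
}
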
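"""Configuration-driven experiment runner.

``run_experiment`` ties generation -> training -> evaluation -> time-step
sweep -> RSA -> activation clustering into one reproducible run directory;
``render_report`` consolidates the stage artifacts into a single JSON/CSV
bundle. Every stage seed derives from one master seed, and the resolved
configuration is written into the run directory so runs are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activations import cluster_activation_maps, extract_activation_maps, midline_activation
from .estimators import ConvLSTMClassifier, DilatedConvClassifier, _SymmetryNetClassifier
from .evaluation import cross_dataset_eval, timestep_sweep
from .exceptions import InvalidSpecError, StageDependencyError
from .rsa import compute_rdm, extract_representations, prototype_correlation_report
from .stimuli import FamilySpec, generate_family, make_training_corpus, save_family
from .training import PRESETS, TrainConfig, grid_search

log = logging.getLogger("mirrornet")

#: held-out test families of the study
TEST_BAND_SIZES = (2, 6, 14, 16, 18)
STRIPE_XS = (2, 4, 6, 8, 10)
SWEEP_STEPS = (5, 10, 20, 30, 50)
STAGES = ("generate", "train", "evaluate", "sweep", "rsa", "activations", "report")


def test_family_specs() -> list[FamilySpec]:
    specs = [FamilySpec("band", band_size=b) for b in TEST_BAND_SIZES]
    specs.append(FamilySpec("band", band_size=4, brightness="dark"))
    specs += [FamilySpec("stripe", stripe_x=x) for x in STRIPE_XS]
    return specs


@dataclass
class ExperimentConfig:
    """Resolved configuration of one run."""

    preset: str = "scaled_down"
    seed: int = 0
    out_dir: str = "runs/run0"
    stages: tuple[str, ...] = STAGES
    archs: tuple[str, ...] = ("lstm3", "dilated")
    overrides: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        if self.preset not in PRESETS:
            raise InvalidSpecError(f"unknown preset {self.preset!r}")
        cfg = dict(PRESETS[self.preset])
        cfg.update(self.overrides)
        return cfg

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence((self.seed, STAGES.index(stage))).generate_state(1)[0]
            % 2**31
        )


def _save_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str))


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Stage outputs live at stable relative paths (``families/``, ``train/``,
    ``eval/``, ``sweep/``, ``rsa/``, ``activations/``, ``report.json``).
    """
    cfg = config.resolved()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save_json(
        {"config": dataclasses.asdict(config), "resolved": cfg}, out / "config.json"
    )
    n_eval = cfg["n_eval"]

    if "generate" in config.stages:
        t0 = time.time()
        gseed = config.stage_seed("generate")
        for i, spec in enumerate(test_family_specs()):
            fam = generate_family(spec, n_eval, gseed + i)
            save_family(fam, out / "families" / spec.name)
        log.info("generate: %d families in %.1fs", len(test_family_specs()), time.time() - t0)

    models: dict[str, _SymmetryNetClassifier] = {}
    if "train" in config.stages:
        tseed = config.stage_seed("train")
        corpus = make_training_corpus(cfg["n_total"], cfg["split_fraction"], tseed)
        (out / "train").mkdir(exist_ok=True)
        for arch in config.archs:
            t0 = time.time()
            base = TrainConfig(
                arch=arch,
                n_channels=cfg["n_channels"],
                max_epochs=cfg["max_epochs"],
                patience=cfg["patience"],
                seed=tseed + 1,
            )
            gs = grid_search(corpus, base, cfg["lr_grid"], cfg["step_grid"])
            gs.table.to_csv(out / "train" / f"{arch}_grid.csv", index=False)
            pd.DataFrame(gs.winner.history).to_csv(
                out / "train" / f"{arch}_history.csv", index=False
            )
            gs.winner.model.save(out / "train" / f"{arch}.npz")
            models[arch] = gs.winner.model
            log.info(
                "train %s: val acc %.4f in %.1fs",
                arch, gs.winner.best_validation_accuracy, time.time() - t0,
            )

    def _model(arch: str) -> _SymmetryNetClassifier:
        if arch in models:
            return models[arch]
        ckpt = out / "train" / f"{arch}.npz"
        if not ckpt.exists():
            raise StageDependencyError(f"missing checkpoint {ckpt}; run the train stage")
        models[arch] = _SymmetryNetClassifier.load(ckpt)
        return models[arch]

    def _families(kind=None):
        from .stimuli import load_family

        fams = []
        for spec in test_family_specs():
            if kind and spec.kind != kind:
                continue
            path = out / "families" / spec.name
            if not path.with_suffix(".npz").exists():
                raise StageDependencyError(f"missing family archive {path}; run generate")
            fams.append(load_family(path))
        return fams

    if "evaluate" in config.stages:
        frames = [
            cross_dataset_eval(_model(a), _families(), model_id=a) for a in config.archs
        ]
        (out / "eval").mkdir(exist_ok=True)
        pd.concat(frames).to_csv(out / "eval" / "accuracy.csv", index=False)

    if "sweep" in config.stages and "lstm3" in config.archs:
        frames = [
            timestep_sweep(_model("lstm3"), fam, list(SWEEP_STEPS))
            for fam in _families(kind="stripe")
        ]
        (out / "sweep").mkdir(exist_ok=True)
        pd.concat(frames).to_csv(out / "sweep" / "steps.csv", index=False)

    if "rsa" in config.stages:
        rseed = config.stage_seed("rsa")
        per_family = cfg.get("rsa_per_family", max(20, n_eval // 20))
        frames = []
        (out / "rsa").mkdir(exist_ok=True)
        for arch in config.archs:
            reps = extract_representations(_model(arch), per_family, rseed)
            rdm = compute_rdm(reps)
            np.savetxt(out / "rsa" / f"rdm_{arch}.csv", rdm.values, delimiter=",")
            _save_json(
                {"family_index": rdm.family_index.tolist(),
                 "design": [s.to_dict() for s in rdm.design],
                 "rescale": [rdm.rescale_min, rdm.rescale_max]},
                out / "rsa" / f"rdm_{arch}_blocks.json",
            )
            frames.append(prototype_correlation_report(rdm, model_id=arch))
        pd.concat(frames).to_csv(out / "rsa" / "correlations.csv", index=False)

    if "activations" in config.stages and "lstm3" in config.archs:
        aseed = config.stage_seed("activations")
        model = _model("lstm3")
        fam = generate_family(
            FamilySpec("band", band_size=6), min(n_eval, 200), aseed
        )
        steps = sorted({10, max(1, model.unroll_steps // 2), model.unroll_steps})
        steps = [s for s in steps if s <= model.unroll_steps]
        rows = []
        (out / "activations").mkdir(exist_ok=True)
        for cls in (1, 0):
            for s in steps:
                maps = extract_activation_maps(model, fam, s, cls)
                cs = cluster_activation_maps(maps, k=10, seed=aseed)
                np.savez_compressed(
                    out / "activations" / f"centroids_c{cls}_t{s}.npz",
                    centroids=cs.centroids,
                )
                cs.trace_frame().to_csv(
                    out / "activations" / f"trace_c{cls}_t{s}.csv", index=False
                )
                rows.append(
                    dict(class_label=cls, timestep=s,
                         midline_activation=midline_activation(cs.centroids),
                         inertia=cs.inertia)
                )
        pd.DataFrame(rows).to_csv(out / "activations" / "midline.csv", index=False)

    if "report" in config.stages:
        render_report(out)
    return out


def render_report(run_dir: str | Path) -> dict:
    """Consolidate stage artifacts into ``report.json``/``report.csv``.

    Every number in the report records the stage artifact file it came
    from. Missing stages produce a partial report with a warning entry.
    """
    run_dir = Path(run_dir)
    if not (run_dir / "config.json").exists():
        raise StageDependencyError(f"{run_dir} has no config.json; not a run directory")
    report: dict = {"run_dir": str(run_dir), "warnings": []}
    sections = {
        "accuracy_by_family": run_dir / "eval" / "accuracy.csv",
        "timestep_sweep": run_dir / "sweep" / "steps.csv",
        "rsa_correlations": run_dir / "rsa" / "correlations.csv",
        "activation_midline": run_dir / "activations" / "midline.csv",
    }
    frames = {}
    for name, path in sections.items():
        if path.exists():
            df = pd.read_csv(path)
            report[name] = {"source": str(path), "rows": df.to_dict(orient="records")}
            frames[name] = df
        else:
            report["warnings"].append(f"stage artifact missing: {path}")
    _save_json(report, run_dir / "report.json")
    if frames:
        flat = pd.concat(
            [df.assign(section=name) for name, df in frames.items()], ignore_index=True
        )
        flat.to_csv(run_dir / "report.csv", index=False)
    return report
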
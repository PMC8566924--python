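"""End-to-end orchestration: dataset → model comparison → sensitivity →
optimization → report.

Per trait the pipeline Box-Cox-normalizes the target, min–max scales the
inputs, cross-validates the three surrogate families (hyperparameters
selected on a separate single-repeat fold plan), selects the family with
the highest mean CV test R² (ties broken by lowest test RMSE), refits it on
all data, ranks input importance by VSR (with the CV test RMSE as the
denominator, since a near-interpolating GRNN has ~0 resubstitution error),
and maximizes the refitted surrogate with all four metaheuristics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from cultivopt.dataset import (
    INPUT_BOUNDS,
    INPUT_NAMES,
    GrowthDataset,
    load_table1,
    read_csv,
    trait_matrix,
)
from cultivopt.models import (
    CVReport,
    evaluate_cv,
    fit_family,
    select_hidden_size,
    select_sigma,
)
from cultivopt.optimizers import (
    default_configs,
    optimize_all,
    results_table,
)
from cultivopt.preprocessing import make_folds, pca_outlier_flags
from cultivopt.sensitivity import rank_inputs, replicate_vsr

_pkg_version = "0.1.0"

logger = logging.getLogger("cultivopt")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a bit-reproducible run."""

    dataset: str = "fixture"  # "fixture" or a CSV path
    traits: tuple[str, ...] | None = None  # None → all traits in the dataset
    families: tuple[str, ...] = ("grnn", "mlp", "anfis")
    cv_k: int = 5
    cv_repeats: int = 10
    selection_repeats: int = 1  # fold repeats for hyperparameter selection
    seed: int = 7
    use_boxcox: bool = True
    sigma_grid: tuple[float, ...] | None = None
    hidden_candidates: tuple[int, ...] = (2, 4, 8, 12)
    anfis_mf: int = 3
    anfis_epochs: int = 10
    population: int = 200
    generations: int = 1000
    test_profile: bool = False  # shrink to population 50 / 200 generations
    sensitivity_level: str = "replicates"  # or "means"
    sensitivity_reconstructions: int = 5

    def optimizer_budget(self) -> tuple[int, int]:
        if self.test_profile:
            return min(self.population, 50), min(self.generations, 200)
        return self.population, self.generations

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("traits", "families", "sigma_grid", "hidden_candidates"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    cv_table: pd.DataFrame
    sensitivity_table: pd.DataFrame
    optimization_table: pd.DataFrame
    chosen_family: dict[str, str]
    provenance: dict
    errors: dict[str, str] = field(default_factory=dict)


def _load(config: PipelineConfig) -> GrowthDataset:
    if config.dataset == "fixture":
        return load_table1()
    return read_csv(config.dataset)


def run_pipeline(
    config: PipelineConfig, dataset: GrowthDataset | None = None
) -> PipelineReport:
    """Run the full analysis described in the module docstring.

    A failure in one trait is recorded in ``report.errors`` and the run
    continues with the remaining traits.
    """
    t0 = time.time()
    ds = dataset if dataset is not None else _load(config)
    traits = tuple(config.traits or ds.traits)
    unknown = set(traits) - set(ds.traits)
    if unknown:
        raise PipelineError(f"unknown traits requested: {sorted(unknown)}")

    X_all, _ = trait_matrix(ds, traits[0])
    n_flagged = int(pca_outlier_flags(X_all).sum())
    logger.info("outlier screen on inputs: %d rows flagged", n_flagged)

    pop, gens = config.optimizer_budget()
    cv_frames, sens_frames, opt_frames = [], [], []
    chosen: dict[str, str] = {}
    errors: dict[str, str] = {}

    for trait in traits:
        try:
            X, y = trait_matrix(ds, trait)
            sel_plan = make_folds(
                len(y), config.cv_k, config.selection_repeats, config.seed
            )
            eval_plan = make_folds(
                len(y), config.cv_k, config.cv_repeats, config.seed
            )
            params: dict[str, dict] = {}
            if "grnn" in config.families:
                sigma = select_sigma(
                    X, y, sel_plan,
                    grid=config.sigma_grid or np.geomspace(0.02, 2.0, 20),
                    use_boxcox=config.use_boxcox,
                )
                params["grnn"] = {"sigma": sigma}
            if "mlp" in config.families:
                hidden = select_hidden_size(
                    X, y, sel_plan, config.hidden_candidates,
                    use_boxcox=config.use_boxcox,
                )
                params["mlp"] = {"hidden_size": hidden, "seed": config.seed}
            if "anfis" in config.families:
                params["anfis"] = {
                    "mf_per_input": config.anfis_mf,
                    "epochs": config.anfis_epochs,
                }

            reports: dict[str, CVReport] = {}
            for fam in config.families:
                rep = evaluate_cv(
                    fam, X, y, eval_plan, params[fam],
                    use_boxcox=config.use_boxcox,
                )
                reports[fam] = rep
                frame = rep.frame.copy()
                frame.insert(0, "trait", trait)
                frame.insert(1, "model", fam)
                cv_frames.append(frame)

            best = max(
                reports,
                key=lambda f: (
                    reports[f].mean("r2", "test"),
                    -reports[f].mean("rmse", "test"),
                ),
            )
            chosen[trait] = best
            logger.info(
                "%s: selected %s (test R² %.3f)",
                trait, best, reports[best].mean("r2", "test"),
            )

            model = fit_family(
                best, X, y, {**params[best], "use_boxcox": config.use_boxcox}
            )
            if config.sensitivity_level == "replicates" and best == "grnn":
                sens = replicate_vsr(
                    ds, trait,
                    seed=config.seed,
                    n_reconstructions=config.sensitivity_reconstructions,
                )
            else:
                sens = rank_inputs(
                    model, X, y,
                    trait=trait,
                    rmse_full=reports[best].mean("rmse", "test"),
                )
            sf = sens.to_frame().reset_index()
            sf.insert(0, "trait", trait)
            sf.insert(1, "model", best)
            sens_frames.append(sf)

            from cultivopt.optimizers import Problem

            problem = Problem.from_model(model, INPUT_BOUNDS)
            configs = default_configs(pop, gens, config.seed)
            results = optimize_all(problem, configs)
            opt_frames.append(
                results_table(results, INPUT_NAMES, trait=trait)
            )
        except Exception as exc:  # noqa: BLE001 - per-trait isolation
            logger.exception("trait %s failed", trait)
            errors[trait] = f"{type(exc).__name__}: {exc}"

    provenance = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": _pkg_version,
        "n_records": len(ds),
        "outliers_flagged": n_flagged,
        "optimizer_population": pop,
        "optimizer_generations": gens,
        "runtime_s": round(time.time() - t0, 3),
    }
    return PipelineReport(
        cv_table=pd.concat(cv_frames, ignore_index=True)
        if cv_frames else pd.DataFrame(),
        sensitivity_table=pd.concat(sens_frames, ignore_index=True)
        if sens_frames else pd.DataFrame(),
        optimization_table=pd.concat(opt_frames, ignore_index=True)
        if opt_frames else pd.DataFrame(),
        chosen_family=chosen,
        provenance=provenance,
        errors=errors,
    )


_FILES = {
    "cv_table": "cv_report.csv",
    "sensitivity_table": "sensitivity_report.csv",
    "optimization_table": "optimization_report.csv",
}


def write_report(report: PipelineReport, outdir: str | Path) -> None:
    """Write CSV tables + JSON summary atomically (temp-then-rename)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory(dir=outdir) as tmp:
        tmp = Path(tmp)
        for attr, fname in _FILES.items():
            getattr(report, attr).to_csv(tmp / fname, index=False)
        summary = {
            "chosen_family": report.chosen_family,
            "provenance": report.provenance,
            "errors": report.errors,
        }
        (tmp / "summary.json").write_text(json.dumps(summary, indent=2))
        for fname in [*_FILES.values(), "summary.json"]:
            os.replace(tmp / fname, outdir / fname)
    # runtime provenance, not part of the loadable report
    runtime_s = report.provenance.get("runtime_s")
    (outdir / "run.log").write_text(
        f"cultivopt {_pkg_version} run {report.provenance['config_digest']} "
        f"seed={report.provenance['seed']} runtime={runtime_s}s\n"
    )


def load_report(outdir: str | Path) -> PipelineReport:
    outdir = Path(outdir)
    summary = json.loads((outdir / "summary.json").read_text())
    return PipelineReport(
        cv_table=pd.read_csv(outdir / _FILES["cv_table"]),
        sensitivity_table=pd.read_csv(outdir / _FILES["sensitivity_table"]),
        optimization_table=pd.read_csv(outdir / _FILES["optimization_table"]),
        chosen_family=summary["chosen_family"],
        provenance=summary["provenance"],
        errors=summary.get("errors", {}),
    )
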
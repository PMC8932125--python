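"""End-to-end orchestration: generate/load -> battery -> CHAID -> trajectories.

One :func:`run_pipeline` call reproduces the whole analysis from a config:
it materialises a cohort (synthetic, or loaded from CSV), runs the
univariate battery, selects the CHAID covariables (by default the
battery-significant symptoms), grows and cross-validates the tree, writes
per-group trajectory tables and figures, and records everything in a
manifest so the run can be repeated bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import Cohort, Diagnosis, read_cohort, write_cohort
from .chaid import ChaidParams, cross_validate, grow, render_tree, resubstitution_report
from .simulate import GeneratorSpec, generate_cohort
from .trajectory import plot_trajectory, trajectory_summary
from .univariate import ALPHA, run_battery

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage.  Earlier outputs are
    left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Everything one run needs.  Exactly one of ``generator`` /
    ``cohort_path`` must be given (``cohort_path`` needs ``catalog_path``)."""

    outdir: str | Path = "run"
    generator: GeneratorSpec | None = None
    cohort_path: str | Path | None = None
    catalog_path: str | Path | None = None
    alpha: float = ALPHA
    chaid: ChaidParams = field(default_factory=ChaidParams)
    trajectory_threshold: float = 1 / 3
    selection: str = "battery"  # battery | all | explicit
    covariables: list[str] | None = None  # for selection == "explicit"
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ValueError(
                "exactly one of generator / cohort_path must be provided"
            )
        if self.cohort_path is not None and self.catalog_path is None:
            raise ValueError("cohort_path requires catalog_path")
        if self.selection not in ("battery", "all", "explicit"):
            raise ValueError(f"unknown selection mode: {self.selection!r}")
        if self.selection == "explicit" and not self.covariables:
            raise ValueError("selection='explicit' requires covariables")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


@_stage("cohort")
def _get_cohort(config: RunConfig, outdir: Path) -> Cohort:
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        write_cohort(cohort, outdir / "cohort.csv", outdir / "catalog.csv")
    else:
        cohort = read_cohort(config.cohort_path, config.catalog_path)
    n_sz, n_msd = cohort.group_sizes
    log.info("cohort: %d patients (SZ %d, MSD %d), %d symptoms",
             len(cohort), n_sz, n_msd, len(cohort.catalog))
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _get_cohort(config, outdir)

    @_stage("battery")
    def battery_stage():
        report = run_battery(cohort, alpha=config.alpha)
        frame = report.to_frame()
        with open(outdir / "battery.csv", "w") as fh:
            fh.write(f"# {report.note}\n")
            frame.to_csv(fh, index=False)
        log.info("battery: %d/%d symptoms significant at alpha=%g (unadjusted)",
                 report.n_significant, len(report.presence), config.alpha)
        return report

    battery = battery_stage()

    @_stage("chaid")
    def chaid_stage():
        if config.selection == "battery":
            covariables = battery.significant_symptoms
        elif config.selection == "explicit":
            covariables = list(config.covariables or [])
        else:
            covariables = cohort.catalog.names
        if not covariables:
            raise ValueError(
                "no covariables selected for CHAID (battery found no "
                "significant symptoms)"
            )
        tree = grow(cohort, config.chaid, covariables)
        (outdir / "tree.txt").write_text(render_tree(tree, "plain"))
        (outdir / "tree.dot").write_text(render_tree(tree, "dot"))
        report = resubstitution_report(tree, cohort)
        try:
            cv_risk = cross_validate(cohort, config.chaid, covariables)
        except ValueError as exc:
            log.warning("cross-validation skipped: %s", exc)
            cv_risk = None
        report.cv_risk = cv_risk
        payload = {
            "covariables": covariables,
            "n_nodes": len(tree.nodes()),
            "n_leaves": tree.n_leaves,
            "root_split": None if tree.root.split is None else tree.root.split.predictor,
            "confusion": {f"{t}->{p}": c for (t, p), c in report.confusion().items()},
            "percent_correct_sz": report.percent_correct_sz,
            "percent_correct_msd": report.percent_correct_msd,
            "overall_percent_correct": report.overall_percent_correct,
            "cv_risk": cv_risk,
        }
        (outdir / "classification.json").write_text(
            json.dumps(payload, indent=2) + "\n"
        )
        log.info("chaid: %d nodes, overall %.1f%% correct, cv risk %s",
                 len(tree.nodes()), report.overall_percent_correct, cv_risk)
        return covariables, tree, report

    covariables, tree, cls_report = chaid_stage()

    @_stage("trajectory")
    def trajectory_stage():
        out = {}
        for group in (Diagnosis.SZ, Diagnosis.MSD):
            entries = trajectory_summary(
                cohort, group, config.trajectory_threshold
            )
            out[group.value] = entries
            lines = ["symptom,n_patients,prevalence,mean_onset,sd_onset,rank"]
            for e in entries:
                name = '"' + e.symptom.replace('"', '""') + '"'
                lines.append(
                    f"{name},{e.n_patients},{e.prevalence!r},"
                    f"{e.mean_onset!r},{e.sd_onset!r},{e.rank}"
                )
            (outdir / f"trajectory_{group.value.lower()}.csv").write_text(
                "\n".join(lines) + "\n"
            )
            if config.make_figures and entries:
                plot_trajectory(
                    entries, outdir / f"trajectory_{group.value.lower()}.svg"
                )
        return out

    trajectories = trajectory_stage()

    n_sz, n_msd = cohort.group_sizes
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "trajectory_threshold": config.trajectory_threshold,
        "selection": config.selection,
        "generator": None
        if config.generator is None
        else {
            "n_sz": config.generator.n_sz,
            "n_msd": config.generator.n_msd,
            "dependence": config.generator.dependence,
            "onset_floor": config.generator.onset_floor,
            "onset_ceiling": config.generator.onset_ceiling,
            "seed": config.generator.seed,
            "n_symptoms": len(config.generator.catalog),
        },
        "cohort_path": None if config.cohort_path is None else str(config.cohort_path),
        "chaid": {
            "alpha_split": config.chaid.alpha_split,
            "alpha_merge": config.chaid.alpha_merge,
            "bonferroni": config.chaid.bonferroni,
            "min_parent": config.chaid.min_parent,
            "min_child": config.chaid.min_child,
            "max_depth": config.chaid.max_depth,
            "cv_folds": config.chaid.cv_folds,
            "seed": config.chaid.seed,
        },
        "results": {
            "n_patients": len(cohort),
            "n_sz": n_sz,
            "n_msd": n_msd,
            "n_significant": battery.n_significant,
            "covariables": covariables,
            "root_split": None if tree.root.split is None else tree.root.split.predictor,
            "overall_percent_correct": cls_report.overall_percent_correct,
            "cv_risk": cls_report.cv_risk,
            "trajectory_lengths": {g: len(v) for g, v in trajectories.items()},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
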
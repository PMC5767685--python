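"""End-to-end orchestration: simulate → estimate → similarity → weights → classify.

The pipeline follows the two-branch analysis flow: GLM beta patterns feed
the pattern-similarity and weight analyses, while z-scored stimulus volumes
feed the classification analysis.  A single master seed fans out into
independent per-stage substreams, so changing e.g. only the classification
seed leaves the similarity and weight outputs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import CATEGORIES, DesignSpec, ScenarioConfig, config_hash
from .classify import classify_dataset, group_test_and_fdr, zscore_patterns
from .errors import ConfigurationError, PartWholeError
from .glm import DEFAULT_SHIFT_S, estimate_betas, extract_condition_volumes
from .similarity import category_emotion_anova, correlation_table
from .simulate import generate_condition_patterns, generate_timeseries
from .weights import emotion_roi_anova, fit_optimal_weights


@dataclass(frozen=True)
class RunConfig:
    """Fully declarative configuration of one pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    design: DesignSpec = field(default_factory=DesignSpec)
    ts_noise_sd: float = 0.5
    nuisance_scale: float = 0.3
    shift_s: float = DEFAULT_SHIFT_S
    feature_p_threshold: float = 0.05
    fdr_q: float = 0.05
    svm_c: float = 1.0
    anova_rois: tuple[str, ...] = ("OFA", "EBA", "STS", "FG")
    seed: int = 0
    classifier_seed: int | None = None

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("patterns", "timeseries", "classification")
        children = ss.spawn(len(names))
        seeds = {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }
        if self.classifier_seed is not None:
            seeds["classification"] = self.classifier_seed
        return seeds

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict()
        d["design"] = self.design.to_dict()
        d["anova_rois"] = list(self.anova_rois)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        d["design"] = DesignSpec.from_dict(d["design"])
        if "anova_rois" in d:
            d["anova_rois"] = tuple(d["anova_rois"])
        return cls(**d)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def validate_config(config: RunConfig) -> list[str]:
    """Collect every out-of-range field (the dataclasses already raise on
    construction; this re-checks cross-field consistency for loaded configs)."""
    problems = []
    for roi in config.anova_rois:
        if roi not in config.scenario.roi_names:
            problems.append(f"anova_rois entry {roi!r} not in scenario.roi_names")
    if config.ts_noise_sd < 0:
        problems.append("ts_noise_sd must be >= 0")
    if not (0 < config.feature_p_threshold <= 1):
        problems.append("feature_p_threshold must lie in (0, 1]")
    if not (0 < config.fdr_q < 1):
        problems.append("fdr_q must lie in (0, 1)")
    if config.svm_c <= 0:
        problems.append("svm_c must be > 0")
    if config.shift_s < 0:
        problems.append("shift_s must be >= 0")
    return problems


@dataclass
class ReportBundle:
    """All result tables of one pipeline run, traceable to the config hash."""

    correlations: pd.DataFrame
    group_rsm: pd.DataFrame
    similarity_anovas: pd.DataFrame
    weight_curves: pd.DataFrame
    weight_optima: pd.DataFrame
    weight_tests: pd.DataFrame
    weight_anova: pd.DataFrame
    accuracies: pd.DataFrame
    group_classification: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            name: getattr(self, name)
            for name in (
                "correlations",
                "group_rsm",
                "similarity_anovas",
                "weight_curves",
                "weight_optima",
                "weight_tests",
                "weight_anova",
                "accuracies",
                "group_classification",
            )
        }


class StageError(PartWholeError):
    def __init__(self, stage: str, cfg_hash: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for config {cfg_hash}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, log=print) -> ReportBundle:
    """Execute both MVPA branches end to end on a synthetic cohort."""
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    seeds = config.stage_seeds()
    h = config.hash
    log(f"[{h}] generating patterns: scenario={config.scenario.scenario} "
        f"subjects={config.scenario.n_subjects} voxels={config.scenario.n_voxels}")

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, h, e) from e

    scenario = dataclasses.replace(config.scenario, seed=seeds["patterns"])
    patterns = _stage("simulate_patterns", lambda: generate_condition_patterns(scenario))
    ts = _stage(
        "simulate_timeseries",
        lambda: generate_timeseries(
            patterns,
            config.design,
            noise_sd=config.ts_noise_sd,
            seed=seeds["timeseries"],
            nuisance_scale=config.nuisance_scale,
        ),
    )
    log(f"[{h}] time series: {len(ts.volumes)} run×ROI matrices of shape "
        f"{next(iter(ts.volumes.values())).shape}")

    # branch 1: GLM betas -> similarity + weights
    betas = _stage("estimate_betas", lambda: estimate_betas(ts))
    corr = _stage("similarity", lambda: correlation_table(betas))
    group_rsm = (
        corr.groupby(["roi", "emotion", "cat_a", "cat_b"])["z"].mean().reset_index()
    )
    anova_rows = []
    for roi in config.anova_rois:
        for contrast in ("person_face_vs_synthetic", "person_body_vs_synthetic"):
            tab = _stage(
                "similarity_anova", lambda: category_emotion_anova(corr, roi, contrast)
            )
            tab.insert(0, "roi", roi)
            tab.insert(1, "contrast", contrast)
            anova_rows.append(tab)
    similarity_anovas = pd.concat(anova_rows, ignore_index=True)

    curves, optima = _stage("weights", lambda: fit_optimal_weights(betas))
    test_rows = []
    from .weights import test_alpha_vs_half

    from .errors import DegenerateDataError

    for (roi, emo), cell in optima.groupby(["roi", "emotion"]):
        betas = cell["beta_hat"].to_numpy()
        try:
            res = test_alpha_vs_half(betas)
            res["degenerate"] = False
        except DegenerateDataError:
            # the grid can make every subject's optimum identical at small n
            res = {"t": np.nan, "p": np.nan, "df": len(betas) - 1,
                   "mean": float(betas.mean()), "degenerate": True}
        test_rows.append({"roi": roi, "emotion": emo, "weight": "body", **res})
    weight_tests = pd.DataFrame(test_rows)
    weight_anova = _stage(
        "weight_anova", lambda: emotion_roi_anova(optima, config.anova_rois)
    )["anova"]

    # branch 2: volume extraction -> classification
    vols = _stage(
        "extract_volumes", lambda: extract_condition_volumes(ts, shift_s=config.shift_s)
    )
    zvols = _stage("zscore", lambda: zscore_patterns(vols))
    accs = _stage(
        "classify",
        lambda: classify_dataset(
            zvols, alphas=optima, p_threshold=config.feature_p_threshold
        ),
    )
    group_class = _stage(
        "group_fdr", lambda: group_test_and_fdr(accs, q=config.fdr_q)
    )
    log(f"[{h}] classification: {group_class.shape[0]} group tests "
        f"({accs['roi'].nunique()} ROIs x {accs['training_type'].nunique()} types)")

    return ReportBundle(
        correlations=corr,
        group_rsm=group_rsm,
        similarity_anovas=similarity_anovas,
        weight_curves=curves,
        weight_optima=optima,
        weight_tests=weight_tests,
        weight_anova=weight_anova,
        accuracies=accs,
        group_classification=group_class,
        provenance={
            "config": config.to_dict(),
            "config_hash": h,
            "stage_seeds": seeds,
            "version": __version__,
            "categories": list(CATEGORIES),
        },
    )


def write_report(bundle: ReportBundle, outdir: str | Path) -> Path:
    """Persist all tables as CSV plus a machine-readable provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables().items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, default=str)
    )
    lines = [
        f"partwhole report {bundle.provenance['config_hash']}",
        f"group classification tests: {len(bundle.group_classification)}",
        f"significant after FDR: {int(bundle.group_classification['significant'].sum())}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return outdir


def load_report(indir: str | Path) -> ReportBundle:
    indir = Path(indir)
    tables = {}
    for name in (
        "correlations",
        "group_rsm",
        "similarity_anovas",
        "weight_curves",
        "weight_optima",
        "weight_tests",
        "weight_anova",
        "accuracies",
        "group_classification",
    ):
        tables[name] = pd.read_csv(indir / f"{name}.csv")
    provenance = json.loads((indir / "provenance.json").read_text())
    return ReportBundle(provenance=provenance, **tables)
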
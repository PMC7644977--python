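"""End-to-end analysis pipeline and its configuration.

Stages mirror the analysis flow of a clustered sound-evaluation survey:
simulate (or load) the long-format data, prepare the design (composite
outcome, binary loudness, dummy coding, z-standardization), screen
variables with single-fixed-factor mixed models, select variables with
the percentile Lasso, bootstrap estimated marginal means, and assess
coder reliability. Every artifact is written with provenance metadata
(master seed, config hash, package version); each stage draws its
randomness from a named child seed of the master seed so stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import bootstrap_alpha, reliability_label
from .bootstrap import bootstrap_emm
from .datasets import default_config, generate_ratings, generate_survey
from .lasso import make_penalty
from .lmm import fit_mixed, fixed_effect_tests, r2_nakagawa
from .preprocess import PreparedDesign, binarize_loudness, prepare_design
from .select import percentile_lasso

__all__ = ["PipelineConfig", "run_pipeline", "single_factor_battery",
           "stage_seed"]

log = logging.getLogger("soundlasso")

R2M_SCREEN = 0.05  # screening threshold on marginal R2


def stage_seed(master_seed: int, stage: str) -> int:
    """Named child seed of the master seed for one pipeline stage."""
    key = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master_seed, key]).generate_state(1)[0]
               % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    input_csv: str | None = None  # None -> simulate
    n_clusters: int = 1301
    outcome: str = "annoyance"
    cluster: str = "cluster_id"
    predictors: list[str] = field(default_factory=list)  # empty -> all
    loudness_column: str = "loudness"
    subset: str = "all"  # all | low_level | mid_high_level
    R: int = 100
    K: int = 5
    q: float = 95.0
    n_grid: int = 100
    B: int = 50_000
    emm_factors: list[str] = field(default_factory=lambda: ["macro_category"])
    group_norm: str = "l2"
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "prepare", "battery", "select", "emmeans"])

    def __post_init__(self) -> None:
        if self.subset not in {"all", "low_level", "mid_high_level"}:
            raise ValueError("subset must be all, low_level or mid_high_level")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def single_factor_battery(design: PreparedDesign,
                          variables: list[str] | None = None) -> pd.DataFrame:
    """One random-intercept model per variable (factors enter with all
    their dummies): estimate, CI, p, Satterthwaite df per design column,
    and per-model marginal/conditional R2 with the R2m >= 0.05 screen.

    Per-variable failures are logged and the battery continues.
    """
    variables = list(variables) if variables is not None else list(design.groups)
    rows = []
    for term in variables:
        try:
            sub = design.subset_terms([term])
            fit = fit_mixed(sub, method="REML")
            r2m, r2c = r2_nakagawa(fit)
            tests = fixed_effect_tests(fit)
        except Exception as err:
            log.warning("battery: model for %r failed: %s", term, err)
            continue
        for col, t in tests.iterrows():
            if col == "(Intercept)":
                continue
            rows.append({
                "variable": term, "column": col, "estimate": t.estimate,
                "ci_low": t.ci_low, "ci_high": t.ci_high,
                "p_value": t.p_value, "df": t.df,
                "r2m": r2m, "r2c": r2c, "passes_screen": r2m >= R2M_SCREEN,
            })
    return pd.DataFrame(rows)


def _prepare_stage(data: pd.DataFrame, config: PipelineConfig) -> PreparedDesign:
    predictors = config.predictors or [
        c for c in data.columns
        if c not in {config.cluster, config.outcome,
                     "pleasant_agreement", "annoying_agreement"}
    ]
    data = data.copy()
    if config.loudness_column in data.columns:
        data["loudness_binary"] = binarize_loudness(data[config.loudness_column])
        predictors = ["loudness_binary" if p == config.loudness_column else p
                      for p in predictors]
    if config.subset != "all":
        if config.loudness_column not in data.columns:
            raise ValueError("loudness subset requested but no loudness column")
        data = data[data["loudness_binary"] == config.subset]
        # the subset selector becomes the grouping variable: drop it from
        # the candidate set
        predictors = [p for p in predictors if p != "loudness_binary"]
    return prepare_design(data, config.outcome, predictors, cluster=config.cluster)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages and write a report bundle.

    Returns a manifest of artifact paths; on stage failure a FAILED
    marker naming the stage is written and the exception re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"provenance": {
        "seed": config.seed, "config_hash": config.digest(),
        "version": __version__,
    }}
    stage = "init"
    try:
        stage = "simulate"
        if config.input_csv is not None:
            data = pd.read_csv(config.input_csv)
        elif "simulate" in config.stages:
            ds = generate_survey(default_config(
                seed=stage_seed(config.seed, "simulate"),
                n_clusters=config.n_clusters))
            data = ds.data
            ds.to_csv(out / "simulated")
            manifest["simulate"] = str(out / "simulated.csv")
        else:
            raise ValueError("no input_csv and simulate stage disabled")

        stage = "prepare"
        design = _prepare_stage(data, config)
        design.save(out / "prepared")
        manifest["prepare"] = {"n_obs": design.n_obs,
                               "n_clusters": design.n_clusters,
                               "n_dropped": design.n_dropped}
        log.info("prepared design: %d obs, %d clusters, %d dropped",
                 design.n_obs, design.n_clusters, design.n_dropped)

        if "battery" in config.stages:
            stage = "battery"
            battery = single_factor_battery(design)
            battery.to_csv(out / "battery.csv", index=False)
            manifest["battery"] = str(out / "battery.csv")

        if "select" in config.stages:
            stage = "select"
            penalty = make_penalty(design, 0.0, group_norm=config.group_norm)
            sel = percentile_lasso(
                design, penalty, R=config.R, K=config.K, q=config.q,
                n_grid=config.n_grid, seed=stage_seed(config.seed, "select"))
            pd.DataFrame({"cycle": np.arange(config.R),
                          "lambda_opt": sel.lambda_opt_per_cycle}
                         ).to_csv(out / "cycle_lambdas.csv", index=False)
            (out / "final_model.txt").write_text(sel.refit.report())
            report = {
                "lambda_final": sel.lambda_final,
                "lambda_max": sel.lambda_max,
                "selected": sel.selected_terms,
                "r2m": sel.refit.r2m, "r2c": sel.refit.r2c,
                "icc_adj": sel.refit.icc,
                "sigma2": sel.refit.fit.sigma2, "tau00": sel.refit.fit.tau00,
                "n_obs": sel.refit.fit.n_obs,
                "n_clusters": sel.refit.fit.n_clusters,
            }
            (out / "selection.json").write_text(json.dumps(report, indent=2))
            manifest["select"] = report

        if "emmeans" in config.stages:
            stage = "emmeans"
            factors = [f for f in config.emm_factors if f in data.columns]
            if config.subset == "all" and "loudness_binary" in data.columns \
                    and len(factors) == 1:
                factors = factors + ["loudness_binary"]
            if factors:
                emm = bootstrap_emm(data, config.outcome, factors, B=config.B,
                                    seed=stage_seed(config.seed, "emmeans"),
                                    cluster=config.cluster)
                emm.table.to_csv(out / "emmeans.csv", index=False)
                manifest["emmeans"] = str(out / "emmeans.csv")

        if "alpha" in config.stages:
            stage = "alpha"
            ratings = generate_ratings(500, 2, agreement=0.8, n_categories=3,
                                       seed=stage_seed(config.seed, "alpha"))
            res = bootstrap_alpha(ratings, B=1000,
                                  seed=stage_seed(config.seed, "alpha_boot"))
            manifest["alpha"] = {"alpha": res.alpha, "ci": [res.ci_low, res.ci_high],
                                 "label": reliability_label(res.alpha)}
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
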
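"""End-to-end orchestration: descriptives -> strata -> fits -> reports.

A single :class:`PipelineConfig` drives the whole analysis for one or more
outcome variants: descriptive tables, stratum construction with a sparse-
cell audit, the three model tiers fitted by MCMC, the VPC/PCV/OR metrics
report, ranked stratum residuals with caterpillar-plot exports, and
convergence diagnostics.  Runs are pure functions of (input, config, seed):
the same seed reproduces every output file bit for bit, and the effective
configuration is always dumped to a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import metrics_report, stratum_residuals
from .model import MAIHDAModel, McmcConfig
from .simulate import SimulationTruth, simulate_survey
from .strata import build_strata, sparse_strata_report
from .survey import (
    SurveyDataset,
    ValidationError,
    descriptive_frame,
    descriptive_table,
    read_survey,
    write_survey,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "sample_size"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def sample_size(
    p: float, deff: float = 1.0, d: float = 0.05, z: float = 1.96, nonresponse: float = 0.0
) -> int:
    """Required sample size for a single proportion under clustering.

    ceil( z^2 * p * (1-p) * deff / (d^2 * (1-NR)) ) — the standard design
    formula with a design effect and a non-response inflation.
    """
    if not 0 < p < 1:
        raise ValidationError("p must be in (0, 1)")
    if not 0 <= nonresponse < 1:
        raise ValidationError("nonresponse must be in [0, 1)")
    if d <= 0:
        raise ValidationError("margin of error must be > 0")
    if deff < 1:
        raise ValidationError("design effect must be >= 1")
    return math.ceil(z**2 * p * (1.0 - p) * deff / (d**2 * (1.0 - nonresponse)))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: input, outcomes, designs, MCMC, output."""

    input_path: str
    output_dir: str
    outcomes: tuple[str, ...] = ("hu_within",)
    covariates: tuple[str, ...] | None = None  # None = all declared covariates
    mcmc: McmcConfig = field(default_factory=McmcConfig.test_scale)
    seed: int = 0
    sparse_threshold: int = 5
    pcv_method: str = "variance"
    write_draws: bool = True
    simulate_variants: bool = True

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValidationError("outcome list must be non-empty")


def _stage_seed(seed: int, *indices: int) -> int:
    """Deterministic per-stage substream below 2^31."""
    ss = np.random.SeedSequence([seed, *indices])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)


def _load_input(config: PipelineConfig) -> SurveyDataset:
    path = Path(config.input_path)
    if path.suffix == ".json":
        truth = SimulationTruth.from_json(path)
        dataset, _ = simulate_survey(truth, include_variants=config.simulate_variants)
        return dataset
    return read_survey(path)


def run_pipeline(config: PipelineConfig, log=print) -> dict:
    """Run the full analysis; returns {outcome: {"metrics": ..., "fits": ...}}."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        dataset = _load_input(config)
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        raise PipelineError(f"stage 'load': {exc}") from exc
    for outcome in config.outcomes:
        if outcome not in dataset.frame.columns:
            raise PipelineError(f"stage 'load': outcome column {outcome!r} absent from input")

    covs = config.covariates
    if covs is None:
        covs = tuple(dataset.covariate_schema)
    for cov in covs:
        if cov not in dataset.covariate_schema:
            raise PipelineError(f"stage 'load': covariate {cov!r} not in schema")

    write_survey(dataset, out / "input_canonical.csv")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            }
        },
    }
    cfg_bytes = json.dumps(manifest["config"], sort_keys=True).encode()
    manifest["config_sha256"] = hashlib.sha256(cfg_bytes).hexdigest()

    results: dict = {}
    tiers = ("model1_null", "model2_main", "model3_adjusted")
    for oi, outcome in enumerate(config.outcomes):
        odir = out / outcome
        odir.mkdir(exist_ok=True)
        log(f"[{outcome}] descriptive tables")
        try:
            tables = descriptive_table(dataset, outcome)
        except Exception as exc:
            raise PipelineError(f"stage 'describe:{outcome}': {exc}") from exc
        descriptive_frame(tables).to_csv(odir / "descriptives.csv", index=False)

        log(f"[{outcome}] strata")
        try:
            analysis = SurveyDataset(
                dataset.analysis_set(outcome).reset_index(drop=True),
                dataset.scheme,
                dict(dataset.covariate_schema),
            )
            strata = build_strata(analysis)
        except Exception as exc:
            raise PipelineError(f"stage 'strata:{outcome}': {exc}") from exc
        strata.to_csv(odir / "strata.csv")
        if not strata.excluded.empty:
            strata.excluded.to_csv(odir / "exclusions.csv", index=False)
        sparse = sparse_strata_report(strata, config.sparse_threshold)
        (odir / "sparse_report.json").write_text(
            json.dumps(
                {
                    "threshold": sparse.threshold,
                    "n_observed": sparse.n_observed,
                    "n_possible": strata.n_possible,
                    "n_flagged": sparse.n_flagged,
                    "pct_flagged": sparse.pct_flagged,
                },
                indent=1,
            )
        )

        fits = {}
        for ti, tier in enumerate(tiers):
            log(f"[{outcome}] fitting {tier}")
            cfg = dataclasses.replace(
                config.mcmc, seed=_stage_seed(config.seed, oi, ti)
            )
            try:
                model = MAIHDAModel(
                    dataset,
                    outcome,
                    tier=tier,
                    covariates=covs if tier == "model3_adjusted" else None,
                )
                fit = model.fit(cfg)
            except Exception as exc:
                raise PipelineError(f"stage 'fit:{outcome}:{tier}': {exc}") from exc
            fits[tier] = fit
            for w in fit.warnings:
                log(f"[{outcome}] {tier}: {w}")
            if config.write_draws:
                fit.to_csv(odir / f"draws_{tier}.csv")
            fit.summary().to_csv(odir / f"summary_{tier}.csv", index=False)
            diag = fit.diagnostics()
            diag.to_csv(odir / f"diagnostics_{tier}.csv")
            res = stratum_residuals(fit)
            res.to_csv(odir / f"residuals_{tier}.csv", index=False)
            res.sort_values("rank")[
                ["rank", "stratum_id", "median", "lo95", "hi95", "significant"]
            ].to_csv(odir / f"caterpillar_{tier}.csv", index=False)

        log(f"[{outcome}] metrics report")
        try:
            report = metrics_report(
                fits["model1_null"],
                fits["model2_main"],
                fits["model3_adjusted"],
                method=config.pcv_method,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'report:{outcome}': {exc}") from exc
        report.to_csv(odir / "metrics.csv")
        for tier, table in report.or_tables.items():
            table.to_csv(odir / f"odds_ratios_{tier}.csv", index=False)
        results[outcome] = {"metrics": report, "fits": fits, "strata": strata}

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    log(f"run complete; outputs in {out}")
    return results
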
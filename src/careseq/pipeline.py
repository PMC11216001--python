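"""End-to-end pipeline: simulate/load -> sequences -> typologies -> models.

One config drives the full analysis; every stage writes CSV reports with JSON
twins into the output directory, and a manifest records the config hash and
seed so identical configs reproduce identical numbers.  The distance matrix
and clustering, the most expensive stage, are cached on disk keyed by the
config hash.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alphabet import SWEEP_COLUMNS
from .clustering import bootstrap_stability, cluster_sequences, label_typologies, quality_profile
from .inequality import ModelSpec, fit_modified_poisson_rr, fit_weighted_multinomial
from .msm import (
    ScenarioSpec,
    compose_weights,
    covariate_balance,
    estimate_ate,
    estimate_cde,
    fit_exposure_propensity,
    fit_mediator_propensity,
)
from .sequences import CostScheme, build_sequences
from .synthetic import GeneratorParams, apply_attrition, default_calibration, generate_cohort

logger = logging.getLogger(__name__)

CATEGORICAL_TABLE1 = [
    "education", "ethnicity", "sex", "maternal_age_band", "family_composition",
    "general_health", "employment", "life_events", "school_adjustment",
    "childcare_sw1", "outcome_raised_td",
]
CONTINUOUS_TABLE1 = ["attachment_score", "maternal_mental_health_sw1",
                     "maternal_mental_health_sw5"]

BALANCE_COVARIATES = ["ethnicity", "maternal_age_band"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    synthetic: dict | None = None          # GeneratorParams dict; None -> default
    input_file: str | None = None          # CSV cohort instead of simulation
    seed: int | None = 0
    cost_scheme: str = "constant"          # "constant" | "transition_rates"
    substitution_cost: float = 2.0
    indel_cost: float = 1.0
    k: int = 4
    k_range: tuple[int, int] = (2, 8)
    bootstrap_B: int = 0                   # 0 disables stability assessment
    rr_adjustments: tuple[str, ...] = ("unadjusted", "partial", "full")
    scenarios: tuple[str, ...] = ("Private group childcare", "Single professional care")
    truncation: tuple[float, float] | None = None
    output_dir: str = "careseq_output"

    def __post_init__(self) -> None:
        if (self.synthetic is not None) and (self.input_file is not None):
            raise ValueError("config must name exactly one input source")
        if self.input_file is None and self.seed is None:
            raise ValueError("synthetic runs require a seed")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["rr_adjustments"] = list(self.rr_adjustments)
        d["scenarios"] = list(self.scenarios)
        d["truncation"] = list(self.truncation) if self.truncation else None
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("k_range", "rr_adjustments", "scenarios", "truncation"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunReport:
    """Manifest plus the file paths of every emitted table."""

    manifest: dict
    tables: dict[str, str] = field(default_factory=dict)
    figures: dict[str, str] = field(default_factory=dict)
    log_path: str | None = None


def describe_cohort(cohort: pd.DataFrame, weight_column: str = "design_weight") -> pd.DataFrame:
    """Weighted descriptive table: counts/percentages and means (SE).

    If the cohort carries a ``retained`` flag, both the observed (all rows)
    and analytic (retained) columns are reported, mirroring a baseline-vs-
    complete-case descriptive table.
    """
    frames = [("observed", cohort)]
    if "retained" in cohort.columns and cohort["retained"].nunique() > 1:
        frames.append(("analytic", cohort[cohort["retained"] == 1]))
    elif "retained" in cohort.columns:
        frames.append(("analytic", cohort))
    rows = []
    for sample, df in frames:
        w = df[weight_column].to_numpy(dtype=float)
        for col in CATEGORICAL_TABLE1:
            if col not in df.columns:
                continue
            vals = df[col].astype(str)
            for lv in sorted(vals.unique()):
                m = (vals == lv).to_numpy()
                rows.append({
                    "sample": sample, "variable": col, "level": lv,
                    "n": int(m.sum()),
                    "weighted_pct": 100.0 * w[m].sum() / w.sum(),
                })
        for col in CONTINUOUS_TABLE1:
            if col not in df.columns:
                continue
            x = df[col].to_numpy(dtype=float)
            mean = np.average(x, weights=w)
            var = np.average((x - mean) ** 2, weights=w)
            ess = w.sum() ** 2 / (w**2).sum()
            rows.append({
                "sample": sample, "variable": col, "level": "mean",
                "n": len(x), "weighted_mean": mean, "se": np.sqrt(var / ess),
            })
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, outdir: Path, name: str, report: RunReport) -> None:
    csv_path = outdir / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(json.loads(df.to_json(orient="records")), fh, indent=2)
    report.tables[name] = str(csv_path)


def _load_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, GeneratorParams | None]:
    if config.input_file is not None:
        from .synthetic import read_cohort

        cohort = read_cohort(config.input_file)
        missing = [c for c in ("child_id", "education", "design_weight", *SWEEP_COLUMNS)
                   if c not in cohort.columns]
        if missing:
            raise ValueError(f"input cohort lacks required columns {missing}")
        return cohort, None
    params = default_calibration() if config.synthetic is None \
        else GeneratorParams.from_dict(config.synthetic)
    cohort = generate_cohort(params, seed=config.seed)
    return apply_attrition(cohort, params), params


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order and write every report artifact."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("careseq")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report = RunReport(manifest={
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }, log_path=str(log_path))

    stage = "simulate"
    try:
        cohort, params = _load_cohort(config)
        logger.info("cohort ready: n=%d", len(cohort))
        _write(describe_cohort(cohort), outdir, "table1_descriptives", report)

        stage = "sequences"
        seqs = build_sequences(cohort)
        logger.info("sequences built: n=%d, T=%d", len(seqs), seqs.n_sweeps)

        stage = "cluster"
        costs = (CostScheme.constant(seqs.alphabet, config.substitution_cost, config.indel_cost)
                 if config.cost_scheme == "constant"
                 else CostScheme.transition_rates(seqs))
        cache = outdir / f"cache_{config.config_hash()}_labels.csv"
        if cache.exists():
            cached = pd.read_csv(cache)
            labels_named = cached["typology"].to_numpy()
            logger.info("cluster labels loaded from cache %s", cache.name)
        else:
            assignment = cluster_sequences(seqs, costs, config.k)
            names = label_typologies(assignment, seqs)
            labels_named = assignment.named_labels()
            if config.k != 4:
                logger.warning(
                    "k=%d: generic cluster names %s; the hypothetical-scenario "
                    "analysis needs the four named typologies", config.k, names)
            pd.DataFrame({"child_id": seqs.ids, "typology": labels_named}).to_csv(
                cache, index=False)
        prev = pd.DataFrame({
            "typology": pd.Series(labels_named),
            "weight": seqs.weights,
        }).groupby("typology")["weight"].sum().reset_index()
        prev["weighted_pct"] = 100 * prev["weight"] / seqs.weights.sum()
        _write(prev.drop(columns="weight"), outdir, "typology_prevalence", report)
        _write(pd.DataFrame(quality_profile(seqs, costs,
                                            range(config.k_range[0], config.k_range[1] + 1))),
               outdir, "cluster_quality", report)
        if config.bootstrap_B > 0:
            stab = bootstrap_stability(seqs, costs, config.k, B=config.bootstrap_B,
                                       seed=(config.seed or 0) + 104729)
            _write(pd.DataFrame(
                [{"cluster": c, "jaccard_stability": v} for c, v in stab.items()]),
                outdir, "cluster_stability", report)
        try:
            from .plotting import state_distribution_plot
            fig_path = outdir / "state_distributions.png"
            state_distribution_plot(seqs, labels_named, path=fig_path)
            report.figures["state_distributions"] = str(fig_path)
        except Exception as exc:  # plotting must never sink the run
            logger.warning("figure generation failed: %s", exc)

        stage = "models"
        named_four = config.k == 4
        if named_four:
            t2 = fit_weighted_multinomial(cohort, labels_named)
            _write(t2, outdir, "table2_inequalities", report)
            rr_frames = [
                fit_modified_poisson_rr(
                    cohort, labels_named,
                    ModelSpec(outcome="outcome_raised_td", adjustment_set=adj))
                for adj in config.rr_adjustments
            ]
            _write(pd.concat(rr_frames, ignore_index=True), outdir, "table3_rr", report)
        else:
            logger.warning("k != 4: skipping typology inequality/risk models that "
                           "expect the named reference typology")

        stage = "msm"
        efit = fit_exposure_propensity(cohort)
        w_ate = compose_weights(cohort["design_weight"].to_numpy(), efit,
                                truncation=config.truncation)
        ate = estimate_ate(cohort, w_ate, balance_covariates=BALANCE_COVARIATES)
        frames = [ate.effects.assign(estimand="ATE", scenario="")]
        diagnostics = [{"estimand": "ATE", **ate.weight_diagnostics}]
        _write(ate.balance, outdir, "balance_ate", report)
        if named_four:
            mfit = fit_mediator_propensity(cohort, labels_named)
            w_cde = compose_weights(cohort["design_weight"].to_numpy(), efit, mfit,
                                    truncation=config.truncation)
            for scenario_name in config.scenarios:
                sc = ScenarioSpec(estimand="CDE", fixed_mediator=scenario_name)
                try:
                    cde = estimate_cde(cohort, labels_named, w_cde, sc)
                except ValueError as exc:
                    logger.warning("CDE scenario %r not estimable: %s", scenario_name, exc)
                    continue
                frames.append(cde.effects.assign(estimand="CDE", scenario=scenario_name))
                diagnostics.append({"estimand": f"CDE:{scenario_name}",
                                    **cde.weight_diagnostics})
            _write(covariate_balance(
                cohort.assign(typology=labels_named),
                w_cde.values,
                ["attachment_score", "maternal_mental_health_sw1", "employment",
                 "family_composition", "life_events", "general_health"],
                group="typology"), outdir, "balance_mediator", report)
        else:
            logger.warning("k != 4: hypothetical-scenario CDEs skipped")
        _write(pd.concat(frames, ignore_index=True), outdir, "table4_msm", report)
        _write(pd.DataFrame(diagnostics), outdir, "weight_diagnostics", report)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        report.manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({**report.manifest, "tables": report.tables}, fh, indent=2)
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, str(exc)) from exc

    report.manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({**report.manifest, "tables": report.tables,
                   "figures": report.figures}, fh, indent=2)
    root.removeHandler(handler)
    handler.close()
    return report
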
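"""End-to-end orchestration: derive outcomes, impute, screen variables with
the group lasso, learn a Bayesian network over the survivors, and report risk
queries and model comparisons — one run per treatment duration.

Every random draw traces to a named seed recorded in the report, and a rerun
with the same configuration writes a byte-identical ``report.json``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesnet as bn
from . import derive as dv
from . import grouplasso as gl
from . import simulate as sim
from . import stats as st
from .bif import export_bif
from .schema import CohortTable, SchemaError, records_from_frames, records_to_frames


@dataclass
class PipelineConfig:
    """Configuration of one analysis run (one treatment duration)."""

    duration_months: int = 6
    dose_covariate: str = "initial"  # or "average"
    seed: int = 0
    out_dir: str | None = None
    # data source: simulate (dict of GeneratorConfig overrides) or input paths
    simulate: dict = field(default_factory=dict)
    input: dict = field(default_factory=dict)  # baseline/attendance/urine CSVs
    lasso: dict = field(default_factory=dict)  # loss, k, n_lambdas, weights, rule
    bn: dict = field(default_factory=dict)  # whitelist, blacklist, tabu_length, ...
    imputation: dict = field(default_factory=dict)  # m, max_sweeps
    maxrisk_nodes: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "duration_months": self.duration_months,
            "dose_covariate": self.dose_covariate,
            "seed": self.seed,
            "simulate": self.simulate,
            "input": self.input,
            "lasso": self.lasso,
            "bn": self.bn,
            "imputation": self.imputation,
            "maxrisk_nodes": self.maxrisk_nodes,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def assemble_cohort(
    baseline: CohortTable,
    records,
    duration_months: int,
    dose_covariate: str = "initial",
) -> CohortTable:
    """Merge baseline covariates with derived outcomes and discretize."""
    derived = dv.derived_frame(records, duration_months, dose_covariate)
    df = baseline.df.merge(derived, on="participant_id", how="left")
    df = df.rename(columns={"dose_mg": "dose"})
    table = CohortTable(df, sim.cohort_variable_specs(include_derived=True))
    return dv.discretize(table, sim.default_binning_rules())


def _load_or_simulate(config: PipelineConfig):
    if config.input:
        baseline_specs = [
            s for s in sim.cohort_variable_specs(False) if s.role != "outcome"
        ]
        baseline = CohortTable.from_csv(config.input["baseline"], baseline_specs)
        att = pd.read_csv(config.input["attendance"])
        ur = pd.read_csv(config.input["urine"])
        records = records_from_frames(att, ur)
        truth = None
    else:
        gen = sim.default_config(
            config.duration_months, seed=config.seed, **config.simulate
        )
        baseline = sim.generate_baseline(gen)
        records = sim.generate_longitudinal(baseline, gen)
        truth = {
            "dag": [list(e) for e in gen.ground_truth_dag],
            "relapse_coefs": gen.relapse_coefs,
        }
    return baseline, records, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and optionally writes) the run report."""
    report: dict = {"config": config.to_dict(), "seeds": {"master": config.seed}}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _persist(name: str, payload: str) -> None:
        if out:
            (out / name).write_text(payload)

    # -- stage: data --------------------------------------------------------
    try:
        baseline, records, truth = _load_or_simulate(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("data", e) from e
    if truth:
        report["ground_truth"] = truth

    # -- stage: derive ------------------------------------------------------
    try:
        cohort = assemble_cohort(
            baseline, records, config.duration_months, config.dose_covariate
        )
        miss_rate = float(config.simulate.get("missingness_rate", 0.0)) if not config.input else 0.0
        if miss_rate > 0:
            cohort = sim.apply_missingness(
                cohort, miss_rate, seed=config.seed + 11
            )
            report["seeds"]["missingness"] = config.seed + 11
        yes = int((cohort.df["relapse"] == "yes").sum())
        report["derived"] = {
            "n": len(cohort),
            "relapse_yes": yes,
            "relapse_rate": yes / len(cohort),
        }
        if out:
            cohort.to_csv(out / "cohort.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("derive", e) from e

    # -- stage: impute ------------------------------------------------------
    try:
        imp_cfg = {"m": 5, "max_sweeps": 5, **config.imputation}
        if cohort.df.drop(columns=["participant_id"]).isna().any().any():
            completed = st.multiple_impute(
                cohort,
                m=int(imp_cfg["m"]),
                max_sweeps=int(imp_cfg["max_sweeps"]),
                seed=config.seed + 13,
            )
            report["seeds"]["imputation"] = config.seed + 13
        else:
            completed = [cohort]
        report["imputation"] = {"m": len(completed)}
    except Exception as e:  # noqa: BLE001
        raise StageError("impute", e) from e

    # -- stage: group-lasso selection ---------------------------------------
    try:
        lcfg = {
            "loss": "logistic",
            "k": 10,
            "n_lambdas": 100,
            "weights": "sqrt",
            "rule": "min",
            **config.lasso,
        }
        selections, paths = [], []
        for i, tab in enumerate(completed):
            work = tab.copy()
            work.df = work.df.drop(columns=["participant_id"])
            design = gl.encode(work)
            path = gl.cv_select_lambda(
                design,
                k=int(lcfg["k"]),
                seed=config.seed + 17 + i,
                loss=lcfg["loss"],
                weights=lcfg["weights"],
                n_lambdas=int(lcfg["n_lambdas"]),
                rule=lcfg["rule"],
            )
            selections.append(tuple(gl.selected_variables(path)))
            paths.append(path)
        modal = Counter(frozenset(s) for s in selections).most_common(1)[0][0]
        selected = [v for v in selections[0] if v in modal] or sorted(modal)
        report["selection"] = {
            "per_imputation": [list(s) for s in selections],
            "modal": sorted(modal),
            "lambda": paths[0].selected_lambda,
            "cv_error_min": float(np.min(paths[0].cv_mean)),
        }
        report["seeds"]["lasso_cv"] = config.seed + 17
        _persist(
            "selected.json",
            json.dumps({"selected": sorted(modal)}, indent=2, sort_keys=True),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("select", e) from e

    # -- stage: BN learning ---------------------------------------------------
    try:
        bcfg = {
            "whitelist": [],
            "blacklist": [],
            "tabu_length": 10,
            "max_iter": 1000,
            "max_parents": 4,
            "pseudo_count": 0.0,
            **config.bn,
        }
        outcome = cohort.outcome
        bn_vars = list(dict.fromkeys(list(selected) + [outcome]))
        work = completed[0].copy()
        work.df = work.df[bn_vars]
        dag = bn.tabu_learn(
            work,
            nodes=bn_vars,
            whitelist=set(map(tuple, bcfg["whitelist"])),
            blacklist=set(map(tuple, bcfg["blacklist"])),
            tabu_length=int(bcfg["tabu_length"]),
            max_iter=int(bcfg["max_iter"]),
            seed=config.seed + 19,
            max_parents=bcfg["max_parents"],
        )
        net = bn.fit_mle(dag, work, pseudo_count=float(bcfg["pseudo_count"]))
        report["seeds"]["bn_tabu"] = config.seed + 19
        report["network"] = {
            "nodes": dag.nodes,
            "edges": sorted(map(list, dag.edges)),
            "score": bn.score(dag, work),
        }
        _persist("net.bif", export_bif(net))
    except Exception as e:  # noqa: BLE001
        raise StageError("learn", e) from e

    # -- stage: risk queries --------------------------------------------------
    try:
        cpt_reports = {}
        for v in [x for x in bn_vars if x != outcome]:
            rows = {}
            for lvl in net.levels(v):
                try:
                    prof = bn.query(net, {v: lvl}, outcome)
                    rows[lvl] = prof.distribution
                except bn.ZeroProbabilityEvidenceError:
                    rows[lvl] = None
            cpt_reports[v] = rows
        mb = config.maxrisk_nodes or net.dag.markov_blanket(outcome)
        # cap the exhaustive search space
        nodes, size = [], 1
        for v in mb:
            if size * len(net.levels(v)) > 4096:
                break
            nodes.append(v)
            size *= len(net.levels(v))
        maxrisk = None
        if nodes:
            prof = bn.max_risk_profile(net, outcome, nodes)
            maxrisk = {
                "evidence": prof.evidence,
                "probability": prof.probability("yes"),
                "ties": prof.ties,
            }
        report["risk"] = {
            "conditional_distributions": cpt_reports,
            "max_risk": maxrisk,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("query", e) from e

    # -- stage: model comparison ----------------------------------------------
    try:
        eval_table = completed[0].copy()
        eval_table.df = eval_table.df[bn_vars]
        bn_scores = bn.classifier_scores(net, eval_table, outcome)
        fit = paths[0].fit_at()
        design0 = gl.encode(
            CohortTable(completed[0].df.drop(columns=["participant_id"]),
                        completed[0].specs)
        )
        # in-sample logistic scores at the selected penalty
        Xraw = (design0.X * design0.scales + design0.centers) if design0.scales is not None else design0.X
        from scipy.special import expit

        eta = fit.intercept + Xraw @ fit.coef
        logi_scores = expit(eta) if fit.loss == "logistic" else eta
        comp = st.compare_models(completed[0], bn_scores, logi_scores)
        report["evaluation"] = {
            "bn_auc": comp.roc_a.auc,
            "bn_auc_ci": list(comp.roc_a.ci),
            "logistic_auc": comp.roc_b.auc,
            "logistic_auc_ci": list(comp.roc_b.ci),
            "auc_difference": comp.auc_difference,
        }
        if out:
            curve = pd.DataFrame(
                {
                    "threshold": comp.roc_a.thresholds,
                    "fpr": comp.roc_a.fpr,
                    "tpr": comp.roc_a.tpr,
                }
            )
            curve.to_csv(out / "roc_bn.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    payload = json.dumps(report, indent=2, sort_keys=True, default=float)
    _persist("report.json", payload)
    return report


def duration_comparison(cohorts: dict[int, CohortTable]) -> dict:
    """Cross-duration relapse comparison (Table-1 analogue) from cohort tables."""
    counts = {}
    for d, tab in cohorts.items():
        yes = int((tab.df["relapse"] == "yes").sum())
        counts[d] = (yes, len(tab) - yes)
    return st.relapse_comparison(counts)


def write_simulation(config: sim.GeneratorConfig, out_dir) -> None:
    """Simulate one cohort and write baseline.csv / attendance.csv / urine.csv
    plus the ground truth as truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    baseline = sim.generate_baseline(config)
    records = sim.generate_longitudinal(baseline, config)
    baseline.to_csv(out / "baseline.csv")
    att, ur = records_to_frames(records)
    att.to_csv(out / "attendance.csv", index=False)
    ur.to_csv(out / "urine.csv", index=False)
    scores = sim._linear_scores(baseline, config.relapse_coefs)
    truth = {
        "dag": [list(e) for e in config.ground_truth_dag],
        "relapse_coefs": config.relapse_coefs,
        "intercept": sim.calibrate_intercept(scores, config.target_relapse_rate),
        "seed": config.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
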
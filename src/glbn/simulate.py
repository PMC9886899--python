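"""Synthetic MMT cohort generator.

Emulates the two data streams the analysis consumes — a baseline table of
categorical covariates and per-participant daily attendance / dose /
monthly-urine records — with the statistical structure the pipeline assumes:

* baseline covariates are drawn by ancestral sampling from a known
  ground-truth DAG with explicit conditional probability tables;
* relapse propensity follows a sparse *group-structured* logistic model on
  the baseline covariates, with the intercept calibrated so the cohort's
  expected relapse proportion equals a target (32% for the 6-month cohort,
  39% for the 12-month cohort — the marginal rates reported for the real
  clinics);
* attendance gaps arise from a covariate-dependent daily dropout hazard, so
  derived compliance (continuous treatment days) is associated with relapse
  through shared causes;
* monthly urine positivity is a two-state Markov chain per participant, so
  the "two consecutive positives" relapse rule is exercised non-trivially;
  relapsers are guaranteed a qualifying run inside the assessment window and
  non-relapsers never produce one.

Everything is driven by a single integer seed, byte-for-byte reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .schema import (
    DAYS_PER_MONTH,
    BinningRule,
    CohortTable,
    LongitudinalRecord,
    SchemaError,
    VariableSpec,
)
from . import derive as dv

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: baseline covariate levels (reference level first)
BASELINE_LEVELS: dict[str, tuple[str, ...]] = {
    "age": ("<30", "30-40", ">40"),
    "age_initial_use": ("<20", "20-30", ">30"),
    "hiv": ("negative", "positive"),
    "sexual_behavior": ("low_risk", "high_risk"),
    "job": ("unemployed", "self_employed", "worker", "service", "farmer"),
    "time_to_clinic": ("<10", "10-", "30-", "60-"),
    "transportation": ("walk", "public", "bike_or_motorcycle", "self_driving"),
    "family_relationship": ("close", "average", "estranged"),
    "drug_friend_contact": ("none", "monthly", "weekly_or_more"),
    "living_status": ("with_family", "alone", "other"),
}

ROLE_OF: dict[str, str] = {
    "age": "demographic",
    "age_initial_use": "drug_use",
    "hiv": "sex_behavior",
    "sexual_behavior": "sex_behavior",
    "job": "demographic",
    "time_to_clinic": "demographic",
    "transportation": "demographic",
    "family_relationship": "demographic",
    "drug_friend_contact": "drug_use",
    "living_status": "demographic",
    "dose": "treatment",
    "continuous_days": "treatment",
    "relapse": "outcome",
}

DEFAULT_DAG: tuple[tuple[str, str], ...] = (
    ("age", "age_initial_use"),
    ("age", "job"),
    ("sexual_behavior", "hiv"),
    ("living_status", "family_relationship"),
    ("job", "transportation"),
)

# CPTs: node -> {parent-level tuple -> probability vector over node levels};
# the key None is the root marginal / fallback row.
DEFAULT_CPTS: dict[str, dict[tuple | None, tuple[float, ...]]] = {
    "age": {None: (0.35, 0.45, 0.20)},
    "sexual_behavior": {None: (0.75, 0.25)},
    "time_to_clinic": {None: (0.20, 0.35, 0.30, 0.15)},
    "living_status": {None: (0.60, 0.25, 0.15)},
    "drug_friend_contact": {None: (0.50, 0.30, 0.20)},
    "age_initial_use": {
        ("<30",): (0.55, 0.40, 0.05),
        ("30-40",): (0.30, 0.50, 0.20),
        (">40",): (0.15, 0.45, 0.40),
    },
    "hiv": {
        ("low_risk",): (0.95, 0.05),
        ("high_risk",): (0.85, 0.15),
    },
    "job": {
        ("<30",): (0.35, 0.15, 0.20, 0.20, 0.10),
        ("30-40",): (0.25, 0.20, 0.25, 0.15, 0.15),
        (">40",): (0.25, 0.20, 0.15, 0.10, 0.30),
    },
    "family_relationship": {
        ("with_family",): (0.55, 0.35, 0.10),
        ("alone",): (0.25, 0.40, 0.35),
        ("other",): (0.35, 0.40, 0.25),
    },
    "transportation": {
        ("unemployed",): (0.45, 0.30, 0.20, 0.05),
        ("self_employed",): (0.25, 0.25, 0.30, 0.20),
        ("worker",): (0.30, 0.30, 0.30, 0.10),
        ("service",): (0.30, 0.35, 0.25, 0.10),
        ("farmer",): (0.35, 0.15, 0.40, 0.10),
    },
}

#: ground-truth log-odds contributions of the relapse model (sparse at the
#: group level: only four covariates carry signal; unlisted levels are 0)
DEFAULT_RELAPSE_COEFS: dict[str, dict[str, float]] = {
    "hiv": {"positive": 0.9},
    "age_initial_use": {"<20": 0.8, "20-30": 0.3},
    "family_relationship": {"estranged": 0.8, "average": 0.2},
    "drug_friend_contact": {"weekly_or_more": 0.9, "monthly": 0.3},
}

DEFAULT_DROPOUT_MULTIPLIERS: dict[str, dict[str, float]] = {
    "drug_friend_contact": {"weekly_or_more": 1.8, "monthly": 1.2},
    "family_relationship": {"estranged": 1.6, "average": 1.1},
}


@dataclass
class GeneratorConfig:
    """Conditions of a simulated cohort; defaults match the 6-month study arm."""

    n_participants: int = 903
    duration_months: int = 6
    target_relapse_rate: float = 0.32
    ground_truth_dag: tuple[tuple[str, str], ...] = DEFAULT_DAG
    cpt_overrides: dict = field(default_factory=dict)
    relapse_coefs: dict = field(default_factory=lambda: DEFAULT_RELAPSE_COEFS)
    dropout_hazard: float = 0.004  # per attended day, prob. of starting a gap
    dropout_multipliers: dict = field(
        default_factory=lambda: DEFAULT_DROPOUT_MULTIPLIERS
    )
    long_gap_prob: float = 0.25  # fraction of gaps drawn from the >14-day regime
    missingness_rate: float = 0.0
    # urine-chain parameters: month-1 positive rate (adjustment phase), then a
    # 2-state chain with P(+|-) and P(+|+) per relapse status
    urine_adjust_pos: float = 0.45
    urine_relapser: tuple[float, float] = (0.25, 0.65)  # (P(+|-), P(+|+))
    urine_nonrelapser: tuple[float, float] = (0.15, 0.0)
    dose_mean: float = 42.0
    dose_sd: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_months not in (6, 12):
            raise ValueError("duration_months must be 6 or 12")
        for p in (
            self.target_relapse_rate,
            self.dropout_hazard,
            self.long_gap_prob,
            self.missingness_rate,
            self.urine_adjust_pos,
            *self.urine_relapser,
            *self.urine_nonrelapser,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    @property
    def window_months(self) -> int:
        return self.duration_months + 1

    @property
    def window_days(self) -> int:
        return self.window_months * DAYS_PER_MONTH


def default_config(duration_months: int = 6, **overrides) -> GeneratorConfig:
    """Study-arm defaults: n=903 / 32% at 6 months, n=710 / 39% at 12 months."""
    base = dict(n_participants=903, duration_months=6, target_relapse_rate=0.32)
    if duration_months == 12:
        base = dict(n_participants=710, duration_months=12, target_relapse_rate=0.39)
    base.update(overrides)
    return GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# Schema helpers
# ---------------------------------------------------------------------------

def cohort_variable_specs(include_derived: bool = True) -> list[VariableSpec]:
    """VariableSpecs for the simulated cohort (outcome first, then covariates)."""
    specs = [VariableSpec("relapse", ("yes", "no"), group_id=0, role="outcome")]
    gid = 1
    for name, levels in BASELINE_LEVELS.items():
        specs.append(VariableSpec(name, levels, group_id=gid, role=ROLE_OF[name]))
        gid += 1
    if include_derived:
        specs.append(
            VariableSpec("dose", ("<30", "30-60", ">60"), group_id=gid, role="treatment")
        )
        specs.append(
            VariableSpec(
                "continuous_days",
                ("<30", "30-", "60-", "90-"),
                group_id=gid + 1,
                role="treatment",
            )
        )
    return specs


def default_binning_rules() -> list[BinningRule]:
    return [
        BinningRule("dose", (30.0, 60.0), labels=("<30", "30-60", ">60")),
        BinningRule(
            "continuous_days", (30.0, 60.0, 90.0), labels=("<30", "30-", "60-", "90-")
        ),
    ]


# ---------------------------------------------------------------------------
# Baseline sampling
# ---------------------------------------------------------------------------

def _topological_order(nodes: list[str], edges) -> list[str]:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise SchemaError("ground_truth_dag contains a cycle")
    return list(nx.topological_sort(g))


def _cpt_rows(node: str, config: GeneratorConfig) -> dict:
    table = dict(DEFAULT_CPTS.get(node, {}))
    table.update(config.cpt_overrides.get(node, {}))
    if not table:
        k = len(BASELINE_LEVELS[node])
        table = {None: tuple(1.0 / k for _ in range(k))}
    return table


def generate_baseline(config: GeneratorConfig) -> CohortTable:
    """Ancestral sampling of the baseline covariates from the ground-truth DAG."""
    rng = np.random.default_rng(config.seed)
    nodes = list(BASELINE_LEVELS)
    edges = [e for e in config.ground_truth_dag]
    for u, v in edges:
        if u not in BASELINE_LEVELS or v not in BASELINE_LEVELS:
            raise SchemaError(f"DAG edge ({u}, {v}) references unknown variable")
    order = _topological_order(nodes, edges)
    parents = {n: [u for u, v in edges if v == n] for n in nodes}

    n = config.n_participants
    data: dict[str, np.ndarray] = {}
    for node in order:
        levels = BASELINE_LEVELS[node]
        table = _cpt_rows(node, config)
        draws = np.empty(n, dtype=object)
        if not parents[node]:
            if None in table:
                probs = np.asarray(table[None], dtype=float)
            else:
                # node declared rootless but its default table is conditional:
                # use the average row as the marginal
                probs = np.mean(
                    [np.asarray(v, dtype=float) for v in table.values()], axis=0
                )
            probs = probs / probs.sum()
            idx = rng.choice(len(levels), size=n, p=probs)
            draws[:] = np.asarray(levels, dtype=object)[idx]
        else:
            parent_vals = np.stack([data[p] for p in parents[node]], axis=1)
            # group rows by parent configuration, draw each group at once
            keys = pd.Series(map(tuple, parent_vals))
            for key, grp in keys.groupby(keys, sort=True):
                row = table.get(key, table.get(None))
                if row is None:
                    raise SchemaError(f"no CPT row for {node} | {key}")
                probs = np.asarray(row, dtype=float)
                probs = probs / probs.sum()
                idx = rng.choice(len(levels), size=len(grp), p=probs)
                draws[grp.index.to_numpy()] = np.asarray(levels, dtype=object)[idx]
        data[node] = draws

    df = pd.DataFrame({n: data[n] for n in nodes})
    df.insert(0, "participant_id", [f"P{i:05d}" for i in range(n)])
    specs = [s for s in cohort_variable_specs(include_derived=False) if s.role != "outcome"]
    out = CohortTable(df.drop(columns=["participant_id"]), specs)
    out.df.insert(0, "participant_id", df["participant_id"])
    return out


# ---------------------------------------------------------------------------
# Longitudinal simulation
# ---------------------------------------------------------------------------

def _linear_scores(baseline: CohortTable, coefs: dict) -> np.ndarray:
    s = np.zeros(len(baseline), dtype=float)
    for var, level_coefs in coefs.items():
        if var not in baseline.df.columns:
            raise SchemaError(f"relapse coefficient references unknown variable {var!r}")
        col = baseline.df[var].astype(str).to_numpy()
        for level, beta in level_coefs.items():
            s += beta * (col == level)
    return s


def calibrate_intercept(scores: np.ndarray, target: float) -> float:
    """Intercept b with mean(expit(b + scores)) == target (monotone root)."""
    f = lambda b: float(np.mean(expit(b + scores))) - target
    return float(brentq(f, -30.0, 30.0, xtol=1e-12))


def _simulate_attendance(
    rng: np.random.Generator, window_days: int, hazard: float, config: GeneratorConfig
) -> np.ndarray:
    att = np.ones(window_days, dtype=bool)
    d = 1  # day 0 always attended (enrollment dosing)
    while d < window_days:
        if rng.random() < hazard:
            if rng.random() < config.long_gap_prob:
                gap = 15 + rng.geometric(0.08)
            else:
                gap = 1 + rng.geometric(0.15)
            gap = int(min(gap, window_days - d))
            att[d : d + gap] = False
            d += gap
        d += 1
    return att


def _simulate_urine(
    rng: np.random.Generator, months: int, relapser: bool, config: GeneratorConfig
) -> np.ndarray:
    p_from_neg, p_from_pos = (
        config.urine_relapser if relapser else config.urine_nonrelapser
    )
    ur = np.zeros(months, dtype=bool)
    ur[0] = rng.random() < config.urine_adjust_pos
    prev = False  # chain restarts after the adjustment month
    for m in range(1, months):
        p = p_from_pos if prev else p_from_neg
        ur[m] = rng.random() < p
        prev = ur[m]
    if relapser:
        pairs = ur[1:-1] & ur[2:]
        if not pairs.any():
            # guarantee a qualifying run inside the assessed months 2..D+1
            start = int(rng.integers(1, months - 1))
            ur[start : start + 2] = True
    return ur


def generate_longitudinal(
    baseline: CohortTable, config: GeneratorConfig
) -> list[LongitudinalRecord]:
    """Daily attendance/dose and monthly urine series for each baseline row.

    The derived relapse status of each record equals a Bernoulli draw from the
    participant's ground-truth propensity, by construction of the urine chain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scores = _linear_scores(baseline, config.relapse_coefs)
    intercept = calibrate_intercept(scores, config.target_relapse_rate)
    propensity = expit(intercept + scores)
    relapse = rng.random(len(baseline)) < propensity

    hazard_mult = np.ones(len(baseline))
    for var, mults in config.dropout_multipliers.items():
        col = baseline.df[var].astype(str).to_numpy()
        for level, m in mults.items():
            hazard_mult *= np.where(col == level, m, 1.0)

    records = []
    days, months = config.window_days, config.window_months
    ids = baseline.df["participant_id"].astype(str).to_numpy()
    for i in range(len(baseline)):
        att = _simulate_attendance(
            rng, days, min(1.0, config.dropout_hazard * hazard_mult[i]), config
        )
        base_dose = float(np.clip(rng.normal(config.dose_mean, config.dose_sd), 10, 100))
        dose = np.full(days, np.nan)
        dose[att] = np.round(base_dose)
        dose[:7][att[:7]] = np.round(base_dose * 0.85)  # titration week
        ur = _simulate_urine(rng, months, bool(relapse[i]), config)
        records.append(LongitudinalRecord(ids[i], att, dose, ur))
    return records


def apply_missingness(
    table: CohortTable, rate: float, seed: int, protect: tuple[str, ...] = ("relapse",)
) -> CohortTable:
    """Mask cells completely at random at the given rate; protected columns
    (the outcome, and identifiers) are never masked."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = [
        c
        for c in out.df.columns
        if c not in protect and c != "participant_id"
    ]
    mask = rng.random((len(out.df), len(cols))) < rate
    for j, c in enumerate(cols):
        col = out.df[c].astype(object)
        col[mask[:, j]] = np.nan
        out.df[c] = col
    return out


def generate_group_sparse_cohort(
    seed: int,
    n: int = 1000,
    n_groups: int = 12,
    n_levels: int = 10,
    n_active: int = 3,
    effect: float = 0.8,
    intercept: float = -1.0,
) -> tuple[CohortTable, list[str]]:
    """Categorical cohort whose outcome follows a known group-sparse logistic model.

    ``n_groups`` independent uniform categorical covariates with ``n_levels``
    levels each; the first ``n_active`` variables carry alternating +/-effect
    log-odds contributions on their non-reference levels, the rest carry none.
    The intercept sets the outcome prevalence (about 35% at the default -1).
    Used to exercise support recovery of the group-lasso screen; returns the
    table and the names of the truly active variables.
    """
    rng = np.random.default_rng(seed)
    levels = tuple(f"l{k}" for k in range(n_levels))
    cats = rng.integers(0, n_levels, size=(n, n_groups))
    eta = np.full(n, float(intercept))
    for j in range(n_active):
        for l in range(1, n_levels):
            sign = 1.0 if l % 2 == 1 else -1.0
            eta += sign * effect * (cats[:, j] == l)
    y = rng.random(n) < expit(eta)

    data = {"relapse": np.where(y, "yes", "no")}
    specs = [VariableSpec("relapse", ("yes", "no"), group_id=0, role="outcome")]
    names = []
    for j in range(n_groups):
        name = f"v{j:02d}"
        names.append(name)
        data[name] = np.asarray(levels, dtype=object)[cats[:, j]]
        specs.append(VariableSpec(name, levels, group_id=j + 1, role="drug_use"))
    table = CohortTable(pd.DataFrame(data), specs)
    return table, names[:n_active]


# ---------------------------------------------------------------------------
# Full cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: GeneratorConfig, dose_covariate: str = "initial"
) -> tuple[CohortTable, list[LongitudinalRecord], dict]:
    """Baseline + longitudinal simulation, derivation, and discretization.

    Returns the analysis-ready cohort table (categorical throughout, outcome
    included, missingness applied if configured), the raw longitudinal
    records, and a ground-truth dictionary (DAG, relapse coefficients,
    calibrated intercept).
    """
    baseline = generate_baseline(config)
    records = generate_longitudinal(baseline, config)
    derived = dv.derived_frame(records, config.duration_months, dose_covariate)

    df = baseline.df.merge(derived, on="participant_id", how="left")
    df = df.rename(columns={"dose_mg": "dose"})
    specs = cohort_variable_specs(include_derived=True)
    table = CohortTable(df, specs)
    table = dv.discretize(table, default_binning_rules())
    if config.missingness_rate > 0:
        table = apply_missingness(
            table, config.missingness_rate, seed=int(np.random.default_rng(
                np.random.SeedSequence([config.seed, 2])).integers(2**31))
        )
    scores = _linear_scores(baseline, config.relapse_coefs)
    truth = {
        "dag": [list(e) for e in config.ground_truth_dag],
        "relapse_coefs": config.relapse_coefs,
        "intercept": calibrate_intercept(scores, config.target_relapse_rate),
        "seed": config.seed,
    }
    return table, records, truth
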
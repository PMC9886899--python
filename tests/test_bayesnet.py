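"""Bayesian-network engine: BIC scoring, Tabu structure search with
constraints, MLE parameter learning, and exact inference vs brute force."""

import numpy as np
import pandas as pd
import pytest

from glbn import CohortTable, VariableSpec
from glbn import bayesnet as bn

from .conftest import collider_cohort, enumeration_posterior, random_net


def two_node_table(n00=40, n01=10, n10=20, n11=30):
    rows = (
        [("a0", "b0")] * n00 + [("a0", "b1")] * n01
        + [("a1", "b0")] * n10 + [("a1", "b1")] * n11
    )
    df = pd.DataFrame(rows, columns=["A", "B"])
    specs = [VariableSpec("A", ("a0", "a1"), 0), VariableSpec("B", ("b0", "b1"), 1)]
    return CohortTable(df, specs)


# -- DAG and constraints -------------------------------------------------------

def test_dag_constraint_validation():
    with pytest.raises(bn.ConstraintError):
        bn.Dag(["A", "B"], whitelist={("A", "B")}, blacklist={("A", "B")})
    with pytest.raises(bn.ConstraintError):
        bn.Dag(["A", "B"], whitelist={("A", "B"), ("B", "A")})
    d = bn.Dag(["A", "B", "C"], whitelist={("A", "B")})
    assert ("A", "B") in d.edges
    assert d.markov_blanket("A") == ["B"]


# -- scoring -------------------------------------------------------------------

def test_empty_dag_score_is_sum_of_marginal_bics():
    table = two_node_table()
    dag = bn.Dag(["A", "B"], set())
    got = bn.score(dag, table)
    n = 100
    expected = 0.0
    for counts in ([50, 50], [60, 40]):
        c = np.array(counts, dtype=float)
        expected += float((c * np.log(c / n)).sum()) - 0.5 * np.log(n) * 1
    assert got == pytest.approx(expected, abs=1e-9)


def test_true_dependence_raises_score():
    table = collider_cohort(seed=0, n=4000)
    empty = bn.Dag(["A", "B", "C"], set())
    with_edge = bn.Dag(["A", "B", "C"], {("A", "C")})
    assert bn.score(with_edge, table) > bn.score(empty, table)
    # an edge between independent variables is penalized
    noise_edge = bn.Dag(["A", "B", "C"], {("A", "B")})
    assert bn.score(noise_edge, table) < bn.score(empty, table)


def test_score_invariant_to_node_relabeling():
    table = collider_cohort(seed=1, n=1000)
    dag = bn.Dag(["A", "B", "C"], {("A", "C"), ("B", "C")})
    s1 = bn.score(dag, table)
    renamed = table.df.rename(columns={"A": "X", "B": "Y", "C": "Z"})
    specs = [
        VariableSpec("X", ("no", "yes"), 0),
        VariableSpec("Y", ("no", "yes"), 1),
        VariableSpec("Z", ("no", "yes"), 2),
    ]
    dag2 = bn.Dag(["X", "Y", "Z"], {("X", "Z"), ("Y", "Z")})
    s2 = bn.score(dag2, CohortTable(renamed, specs))
    assert s1 == pytest.approx(s2, abs=1e-9)


# -- structure search ----------------------------------------------------------

def test_tabu_recovers_v_structure():
    hits = 0
    for seed in range(5):
        dag = bn.tabu_learn(collider_cohort(seed=seed, n=5000), seed=seed)
        hits += dag.edges == {("A", "C"), ("B", "C")}
    assert hits >= 4


def test_tabu_respects_constraints():
    table = collider_cohort(seed=2, n=2000)
    dag = bn.tabu_learn(
        table, whitelist={("A", "B")}, blacklist={("B", "C")}, seed=0
    )
    assert ("A", "B") in dag.edges
    assert ("B", "C") not in dag.edges
    with pytest.raises(bn.ConstraintError):
        bn.tabu_learn(table, whitelist={("A", "B")}, blacklist={("A", "B")})


def test_tabu_on_independent_data_is_sparse():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            f"V{i}": np.where(rng.random(2000) < 0.5, "yes", "no")
            for i in range(4)
        }
    )
    specs = [VariableSpec(f"V{i}", ("no", "yes"), i) for i in range(4)]
    dag = bn.tabu_learn(CohortTable(df, specs), seed=1)
    assert len(dag.edges) <= 1


def test_tabu_beats_empty_graph_score():
    table = collider_cohort(seed=3, n=3000)
    learned = bn.tabu_learn(table, seed=3)
    assert bn.score(learned, table) >= bn.score(bn.Dag(["A", "B", "C"], set()), table)


# -- parameter learning ---------------------------------------------------------

def test_mle_single_node_marginal_from_study_counts():
    df = pd.DataFrame({"relapse": ["yes"] * 289 + ["no"] * 614})
    table = CohortTable(
        df, [VariableSpec("relapse", ("yes", "no"), 0, role="outcome")]
    )
    net = bn.fit_mle(bn.Dag(["relapse"], set()), table)
    assert net.cpts["relapse"].table[0] == pytest.approx(0.320, abs=5e-4)


def test_mle_conditional_frequencies_match_hand_division():
    table = two_node_table(40, 10, 20, 30)
    net = bn.fit_mle(bn.Dag(["A", "B"], {("A", "B")}), table)
    assert np.allclose(net.cpts["B"].table, [[0.8, 0.2], [0.4, 0.6]])
    assert np.allclose(net.cpts["A"].table, [0.5, 0.5])


def test_mle_unobserved_parent_config_gets_uniform_row():
    df = pd.DataFrame({"A": ["a0"] * 10, "B": ["b0"] * 5 + ["b1"] * 5})
    specs = [VariableSpec("A", ("a0", "a1"), 0), VariableSpec("B", ("b0", "b1"), 1)]
    net = bn.fit_mle(bn.Dag(["A", "B"], {("A", "B")}), CohortTable(df, specs))
    assert np.allclose(net.cpts["B"].table[1], [0.5, 0.5])
    assert net.cpts["B"].imputed_rows == [("a1",)]


def test_sample_then_refit_recovers_cpts(chain_net):
    n = 20000
    cohort = chain_net.to_cohort(n, seed=7)
    refit = bn.fit_mle(chain_net.dag, cohort)
    for v in chain_net.nodes:
        t0, t1 = chain_net.cpts[v].table, refit.cpts[v].table
        se = np.sqrt(np.maximum(t0 * (1 - t0), 1e-9) / (n / 4))
        assert np.all(np.abs(t1 - t0) < 3 * se + 1e-3)


# -- inference -------------------------------------------------------------------

def test_query_without_evidence_is_marginal(chain_net):
    prof = bn.query(chain_net, {}, "A")
    assert prof.distribution == pytest.approx({"a0": 0.6, "a1": 0.4})


def test_query_matches_enumeration_on_chain(chain_net):
    for ev in ({}, {"A": "a1"}, {"A": "a0", "B": "b1"}, {"C": "c1"}):
        target = "C" if "C" not in ev else "A"
        got = bn.query(chain_net, ev, target).distribution
        want = enumeration_posterior(chain_net, ev, target)
        for lvl in got:
            assert got[lvl] == pytest.approx(want[lvl], abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_query_matches_enumeration_on_random_nets(seed):
    net = random_net(seed)
    rng = np.random.default_rng(seed + 100)
    for _ in range(6):
        nodes = list(net.nodes)
        rng.shuffle(nodes)
        target = nodes[0]
        k = int(rng.integers(0, len(nodes)))
        ev = {v: net.levels(v)[rng.integers(len(net.levels(v)))] for v in nodes[1 : 1 + k]}
        try:
            got = bn.query(net, ev, target).distribution
        except bn.ZeroProbabilityEvidenceError:
            continue
        want = enumeration_posterior(net, ev, target)
        for lvl in got:
            assert got[lvl] == pytest.approx(want[lvl], abs=1e-10)


def test_joint_of_learned_net_sums_to_one(small_cohort):
    table, _, _ = small_cohort
    work = table.copy()
    cols = ["relapse", "hiv", "age", "family_relationship", "continuous_days"]
    work.df = work.df[cols]
    dag = bn.tabu_learn(work, nodes=cols, seed=0)
    net = bn.fit_mle(dag, work)
    assert sum(net.joint_enumeration().values()) == pytest.approx(1.0, abs=1e-10)


def test_impossible_evidence_raises(chain_net):
    crisp = {
        "A": bn.Cpt("A", (), ("a0", "a1"), (), np.array([1.0, 0.0])),
        "B": chain_net.cpts["B"],
        "C": chain_net.cpts["C"],
    }
    net = bn.BayesNet(chain_net.dag, crisp)
    with pytest.raises(bn.ZeroProbabilityEvidenceError):
        bn.query(net, {"A": "a1"}, "C")
    with pytest.raises(ValueError):
        bn.query(chain_net, {"C": "c0"}, "C")


def test_max_risk_profile_matches_exhaustive_search(chain_net):
    prof = bn.max_risk_profile(chain_net, "C", ["A", "B"], target_level="c1")
    best = max(
        (
            bn.query(chain_net, {"A": a, "B": b}, "C").distribution["c1"]
            for a in ("a0", "a1")
            for b in ("b0", "b1")
        )
    )
    assert prof.probability("c1") == pytest.approx(best, abs=1e-12)
    # C depends on B only: both levels of A tie, lexicographically first wins
    assert prof.evidence["A"] == "a0"
    assert len(prof.ties) == 2


def test_max_risk_on_random_net_vs_bruteforce():
    net = random_net(5, n_nodes=5)
    q = [v for v in net.nodes if v != net.nodes[-1]][:3]
    target = net.nodes[-1]
    lvl = net.levels(target)[0]
    prof = bn.max_risk_profile(net, target, q, target_level=lvl)
    import itertools

    best = 0.0
    for combo in itertools.product(*(net.levels(v) for v in q)):
        ev = dict(zip(q, combo))
        try:
            best = max(best, bn.query(net, ev, target).distribution[lvl])
        except bn.ZeroProbabilityEvidenceError:
            pass
    assert prof.probability(lvl) == pytest.approx(best, abs=1e-12)


def test_classifier_scores_match_per_row_queries(chain_net):
    cohort = chain_net.to_cohort(50, seed=3)
    scores = bn.classifier_scores(chain_net, cohort, "C", target_level="c1")
    for i in (0, 7, 23):
        ev = {v: cohort.df[v].iloc[i] for v in ("A", "B")}
        assert scores[i] == pytest.approx(
            bn.query(chain_net, ev, "C").distribution["c1"]
        )
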
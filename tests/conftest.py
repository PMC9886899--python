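import numpy as np
import pandas as pd
import pytest

from glbn.bayesnet import BayesNet, Cpt, Dag
from glbn.schema import CohortTable, LongitudinalRecord, VariableSpec


def make_record(attendance, doses=None, urine=(), pid="P1"):
    att = np.asarray(attendance, dtype=bool)
    dose = np.full(att.size, np.nan)
    if doses is not None:
        doses = np.asarray(doses, dtype=float)
        dose[att] = doses[att] if doses.size == att.size else doses
    ur = np.asarray(urine, dtype=bool)
    return LongitudinalRecord(pid, att, dose, ur)


@pytest.fixture
def chain_net():
    """A -> B -> C with hand-specified CPTs (used against brute-force oracles)."""
    dag = Dag(["A", "B", "C"], {("A", "B"), ("B", "C")})
    cpts = {
        "A": Cpt("A", (), ("a0", "a1"), (), np.array([0.6, 0.4])),
        "B": Cpt(
            "B", ("A",), ("b0", "b1"), (("a0", "a1"),),
            np.array([[0.7, 0.3], [0.2, 0.8]]),
        ),
        "C": Cpt(
            "C", ("B",), ("c0", "c1"), (("b0", "b1"),),
            np.array([[0.9, 0.1], [0.5, 0.5]]),
        ),
    }
    return BayesNet(dag, cpts)


def random_net(seed: int, n_nodes: int = 6, max_levels: int = 3, edge_p: float = 0.4):
    """Random DAG over a topological order with Dirichlet CPT rows."""
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    levels = {n: tuple(f"x{k}" for k in range(rng.integers(2, max_levels + 1)))
              for n in names}
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_p:
                edges.add((names[i], names[j]))
    dag = Dag(names, edges)
    cpts = {}
    for v in names:
        ps = tuple(dag.parents(v))
        pl = tuple(levels[p] for p in ps)
        shape = tuple(len(x) for x in pl) + (len(levels[v]),)
        q = int(np.prod(shape[:-1])) if ps else 1
        rows = rng.dirichlet(np.ones(shape[-1]), size=q)
        cpts[v] = Cpt(v, ps, levels[v], pl, rows.reshape(shape))
    return BayesNet(dag, cpts)


def enumeration_posterior(net: BayesNet, evidence: dict, target: str) -> dict:
    """Brute-force posterior from the full joint table."""
    joint = net.joint_enumeration()
    nodes = net.nodes
    acc = {lvl: 0.0 for lvl in net.levels(target)}
    for combo, p in joint.items():
        a = dict(zip(nodes, combo))
        if all(a[k] == v for k, v in evidence.items()):
            acc[a[target]] += p
    tot = sum(acc.values())
    return {k: v / tot for k, v in acc.items()}


def collider_cohort(seed: int, n: int = 5000):
    """Data from the v-structure A -> C <- B (orientation identifiable)."""
    rng = np.random.default_rng(seed)
    A = rng.random(n) < 0.5
    B = rng.random(n) < 0.5
    C = rng.random(n) < (0.15 + 0.6 * (A & B))
    df = pd.DataFrame(
        {
            "A": np.where(A, "yes", "no"),
            "B": np.where(B, "yes", "no"),
            "C": np.where(C, "yes", "no"),
        }
    )
    specs = [
        VariableSpec("A", ("no", "yes"), 0),
        VariableSpec("B", ("no", "yes"), 1),
        VariableSpec("C", ("no", "yes"), 2),
    ]
    return CohortTable(df, specs)


@pytest.fixture(scope="session")
def small_cohort():
    """A complete simulated 6-month cohort shared across tests."""
    import glbn
    from glbn import simulate as sim

    table, records, truth = glbn.simulate_cohort(
        sim.default_config(6, n_participants=300, seed=11)
    )
    return table, records, truth
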
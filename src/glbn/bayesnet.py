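"""Discrete Bayesian networks: Tabu-search structure learning, maximum-
likelihood conditional probability tables, exact inference, and risk queries.

A network factorises the joint distribution of categorical variables as
``P(X) = prod_i P(X_i | parents(X_i))``.  Structure is learned by greedy
local search over single-edge moves (add / delete / reverse) scored by the
decomposable BIC, with a tabu list forbidding the reversal of recent moves so
the search can step through score-decreasing moves and escape local optima.
Domain knowledge ("expert adjustment") enters as whitelist edges that must be
present and blacklist edges that may never appear.

Inference is exact: posteriors by variable elimination, verified against
brute-force joint enumeration on small networks in the test suite.  The
pipeline's risk queries — conditional relapse distributions given covariate
configurations and the search for the highest-risk profile — are thin layers
over :func:`query`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CohortTable, SchemaError, VariableSpec

Edge = tuple[str, str]


class ConstraintError(ValueError):
    """Whitelist/blacklist constraints are mutually inconsistent."""


class ZeroProbabilityEvidenceError(ValueError):
    """The supplied evidence has probability zero under the network."""


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------

@dataclass
class Dag:
    """Directed acyclic graph over named nodes with edge constraints."""

    nodes: list[str]
    edges: set[Edge] = field(default_factory=set)
    whitelist: set[Edge] = field(default_factory=set)
    blacklist: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = set(map(tuple, self.edges))
        self.whitelist = set(map(tuple, self.whitelist))
        self.blacklist = set(map(tuple, self.blacklist))
        known = set(self.nodes)
        for u, v in self.edges | self.whitelist | self.blacklist:
            if u not in known or v not in known:
                raise SchemaError(f"edge ({u}, {v}) references unknown node")
        if self.whitelist & self.blacklist:
            raise ConstraintError("whitelist and blacklist overlap")
        missing = self.whitelist - self.edges
        if missing:
            self.edges |= missing
        if self.blacklist & self.edges:
            raise ConstraintError("blacklisted edge present in DAG")
        if not self.is_acyclic():
            raise ConstraintError("graph (or whitelist) contains a cycle")

    def parents(self, v: str) -> list[str]:
        return sorted(u for u, w in self.edges if w == v)

    def children(self, u: str) -> list[str]:
        return sorted(w for x, w in self.edges if x == u)

    def parent_map(self) -> dict[str, list[str]]:
        return {v: self.parents(v) for v in self.nodes}

    def has_path(self, src: str, dst: str) -> bool:
        """True if dst is reachable from src along directed edges."""
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
        stack, seen = [src], set()
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x])
        return False

    def is_acyclic(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return nx.is_directed_acyclic_graph(g)

    def topological_order(self) -> list[str]:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return list(nx.topological_sort(g))

    def copy(self) -> "Dag":
        return Dag(list(self.nodes), set(self.edges), set(self.whitelist), set(self.blacklist))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def markov_blanket(self, node: str) -> list[str]:
        """Parents, children, and co-parents of ``node``."""
        mb = set(self.parents(node)) | set(self.children(node))
        for c in self.children(node):
            mb |= set(self.parents(c))
        mb.discard(node)
        return sorted(mb)


# ---------------------------------------------------------------------------
# Data coding
# ---------------------------------------------------------------------------

def _code_data(
    table: CohortTable, nodes: list[str]
) -> tuple[np.ndarray, dict[str, tuple[str, ...]]]:
    """Integer-code the table's columns; requires complete data."""
    levels = {n: table.spec(n).levels for n in nodes}
    cols = []
    for n in nodes:
        col = table.df[n]
        if col.isna().any():
            raise SchemaError(f"column {n!r} has missing values; impute first")
        lut = {l: i for i, l in enumerate(levels[n])}
        cols.append(col.astype(str).map(lut).to_numpy(dtype=np.int64))
    return np.column_stack(cols), levels


# ---------------------------------------------------------------------------
# BIC scoring
# ---------------------------------------------------------------------------

class BicScorer:
    """Decomposable BIC over integer-coded data with a (node, parents) cache."""

    def __init__(self, data: np.ndarray, cards: np.ndarray):
        self.data = data
        self.cards = np.asarray(cards, dtype=np.int64)
        self.n = data.shape[0]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, i: int, parents: tuple[int, ...]) -> float:
        key = (i, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        r = int(self.cards[i])
        q = int(np.prod(self.cards[list(key[1])])) if key[1] else 1
        idx = self.data[:, i].copy()
        stride = r
        for p in key[1]:
            idx += self.data[:, p] * stride
            stride *= int(self.cards[p])
        counts = np.bincount(idx, minlength=r * q).reshape(q, r)
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(
                counts > 0, counts * (np.log(counts) - np.log(row_tot)), 0.0
            ).sum()
        score = float(ll) - 0.5 * np.log(self.n) * (r - 1) * q
        self._cache[key] = score
        return score

    def total(self, parent_map: dict[int, tuple[int, ...]]) -> float:
        return sum(self.local(i, ps) for i, ps in parent_map.items())


def score(dag: Dag, data: CohortTable) -> float:
    """BIC of a DAG: per-node multinomial log-likelihood minus the
    0.5*log(n)*#parameters complexity penalty, summed over nodes."""
    coded, levels = _code_data(data, dag.nodes)
    cards = np.array([len(levels[n]) for n in dag.nodes])
    scorer = BicScorer(coded, cards)
    pos = {n: i for i, n in enumerate(dag.nodes)}
    return scorer.total(
        {pos[v]: tuple(pos[u] for u in dag.parents(v)) for v in dag.nodes}
    )


# ---------------------------------------------------------------------------
# Tabu structure search
# ---------------------------------------------------------------------------

def tabu_learn(
    data: CohortTable,
    nodes: list[str] | None = None,
    whitelist: set[Edge] | None = None,
    blacklist: set[Edge] | None = None,
    tabu_length: int = 10,
    max_iter: int = 1000,
    seed: int = 0,
    max_parents: int | None = None,
    patience: int = 25,
) -> Dag:
    """Greedy add/delete/reverse search with a tabu list.

    Each iteration applies the best legal non-tabu move even when it lowers
    the score (the escape mechanism); the inverse of an applied move is tabu
    for ``tabu_length`` iterations, with the usual aspiration exception for
    moves that beat the best score seen.  Returns the best DAG visited.
    Whitelist edges are present in every visited graph; blacklisted edges
    never appear.  Search stops after ``patience`` non-improving moves.
    """
    nodes = list(nodes) if nodes is not None else [
        s.name for s in data.specs if s.name in data.df.columns
    ]
    whitelist = set(map(tuple, whitelist or set()))
    blacklist = set(map(tuple, blacklist or set()))
    dag = Dag(nodes, set(), whitelist, blacklist)  # validates constraints

    coded, levels = _code_data(data, nodes)
    cards = np.array([len(levels[n]) for n in nodes])
    scorer = BicScorer(coded, cards)
    pos = {n: i for i, n in enumerate(nodes)}
    rng = np.random.default_rng(seed)

    parents: dict[str, set[str]] = {v: set(dag.parents(v)) for v in nodes}

    def local(v: str) -> float:
        return scorer.local(pos[v], tuple(pos[u] for u in parents[v]))

    def local_with(v: str, ps: set[str]) -> float:
        return scorer.local(pos[v], tuple(pos[u] for u in ps))

    current = sum(local(v) for v in nodes)
    best_score = current
    best_edges = set(dag.edges)
    tabu: dict[tuple, int] = {}
    since_improvement = 0

    for it in range(max_iter):
        moves = []  # (delta, order, kind, u, v)
        edges = dag.edges
        node_order = list(nodes)
        rng.shuffle(node_order)
        for u in node_order:
            for v in node_order:
                if u == v:
                    continue
                if (u, v) not in edges:
                    if (u, v) in blacklist:
                        continue
                    if max_parents is not None and len(parents[v]) >= max_parents:
                        continue
                    if dag.has_path(v, u):
                        continue  # would create a cycle
                    delta = local_with(v, parents[v] | {u}) - local(v)
                    moves.append((delta, ("add", u, v)))
                else:
                    if (u, v) not in whitelist:
                        delta = local_with(v, parents[v] - {u}) - local(v)
                        moves.append((delta, ("delete", u, v)))
                        # reversal = delete (u,v) + add (v,u)
                        if (v, u) not in blacklist and not _path_avoiding_edge(
                            dag, u, v
                        ):
                            if max_parents is None or len(parents[u]) < max_parents:
                                d = (
                                    local_with(v, parents[v] - {u})
                                    - local(v)
                                    + local_with(u, parents[u] | {v})
                                    - local(u)
                                )
                                moves.append((d, ("reverse", u, v)))
        if not moves:
            break
        moves.sort(key=lambda m: -m[0])
        applied = False
        for delta, (kind, u, v) in moves:
            sig = _inverse_signature(kind, u, v)
            is_tabu = tabu.get((kind, u, v), -1) >= it
            if is_tabu and current + delta <= best_score:
                continue  # tabu and no aspiration
            _apply_move(dag, parents, kind, u, v)
            tabu[sig] = it + tabu_length
            current += delta
            applied = True
            break
        if not applied:
            break
        if current > best_score + 1e-9:
            best_score = current
            best_edges = set(dag.edges)
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= patience:
                break
    return Dag(nodes, best_edges, whitelist, blacklist)


def _inverse_signature(kind: str, u: str, v: str) -> tuple:
    if kind == "add":
        return ("delete", u, v)
    if kind == "delete":
        return ("add", u, v)
    return ("reverse", v, u)


def _apply_move(dag: Dag, parents: dict[str, set[str]], kind: str, u: str, v: str):
    if kind == "add":
        dag.edges.add((u, v))
        parents[v].add(u)
    elif kind == "delete":
        dag.edges.discard((u, v))
        parents[v].discard(u)
    else:  # reverse u->v into v->u
        dag.edges.discard((u, v))
        parents[v].discard(u)
        dag.edges.add((v, u))
        parents[u].add(v)


def _path_avoiding_edge(dag: Dag, u: str, v: str) -> bool:
    """Path u ~> v that does not use the edge (u, v) (cycle check for reversal)."""
    adj: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for a, b in dag.edges:
        if (a, b) != (u, v):
            adj[a].append(b)
    stack, seen = [u], set()
    while stack:
        x = stack.pop()
        if x == v:
            return True
        if x in seen:
            continue
        seen.add(x)
        stack.extend(adj[x])
    return False


# ---------------------------------------------------------------------------
# Parameters and the network object
# ---------------------------------------------------------------------------

@dataclass
class Cpt:
    """P(node | parents) with one row per parent configuration.

    ``table`` has shape ``(*parent_cards, node_card)``; axes follow the
    ``parents`` order.  Rows of unobserved parent configurations fall back to
    the uniform distribution and are listed in ``imputed_rows``.
    """

    node: str
    parents: tuple[str, ...]
    levels: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: np.ndarray
    imputed_rows: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        expected = tuple(len(pl) for pl in self.parent_levels) + (len(self.levels),)
        if self.table.shape != expected:
            raise SchemaError(
                f"CPT for {self.node}: shape {self.table.shape} != {expected}"
            )
        if np.any(self.table < 0):
            raise SchemaError(f"CPT for {self.node}: negative entry")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise SchemaError(f"CPT for {self.node}: rows must sum to 1")

    def prob(self, assignment: dict[str, str]) -> float:
        idx = tuple(
            pl.index(assignment[p]) for p, pl in zip(self.parents, self.parent_levels)
        )
        return float(self.table[idx + (self.levels.index(assignment[self.node]),)])


class BayesNet:
    """A DAG plus one CPT per node; supports sampling and exact queries."""

    def __init__(self, dag: Dag, cpts: dict[str, Cpt]):
        if set(cpts) != set(dag.nodes):
            raise SchemaError("need exactly one CPT per node")
        for v in dag.nodes:
            if set(dag.parents(v)) != set(cpts[v].parents):
                raise SchemaError(f"CPT parents of {v!r} disagree with the DAG")
        self.dag = dag
        self.cpts = cpts

    @property
    def nodes(self) -> list[str]:
        return list(self.dag.nodes)

    def levels(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].levels

    # -- joint / sampling ---------------------------------------------------
    def joint_enumeration(self) -> dict[tuple, float]:
        """Full joint table by brute force (small networks only)."""
        if len(self.nodes) > 14:
            raise ValueError("joint enumeration limited to 14 nodes")
        out = {}
        for combo in itertools.product(*(self.levels(n) for n in self.nodes)):
            a = dict(zip(self.nodes, combo))
            p = 1.0
            for v in self.nodes:
                p *= self.cpts[v].prob(a)
            out[combo] = p
        return out

    def sample(self, n: int, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        order = self.dag.topological_order()
        data: dict[str, np.ndarray] = {}
        for v in order:
            cpt = self.cpts[v]
            levels = np.asarray(cpt.levels, dtype=object)
            draws = np.empty(n, dtype=object)
            if not cpt.parents:
                idx = rng.choice(len(levels), size=n, p=cpt.table)
                draws[:] = levels[idx]
            else:
                pcols = np.stack(
                    [
                        np.array(
                            [cpt.parent_levels[k].index(x) for x in data[p]],
                            dtype=int,
                        )
                        for k, p in enumerate(cpt.parents)
                    ],
                    axis=1,
                )
                keys = pd.Series(map(tuple, pcols))
                for key, grp in keys.groupby(keys, sort=True):
                    probs = self.cpts[v].table[key]
                    idx = rng.choice(len(levels), size=len(grp), p=probs)
                    draws[grp.index.to_numpy()] = levels[idx]
            data[v] = draws
        return pd.DataFrame({v: data[v] for v in self.nodes})

    def to_cohort(self, n: int, seed: int = 0, roles: dict | None = None) -> CohortTable:
        df = self.sample(n, seed)
        specs = []
        for gid, v in enumerate(self.nodes):
            role = (roles or {}).get(v, "demographic")
            specs.append(VariableSpec(v, self.levels(v), group_id=gid, role=role))
        return CohortTable(df, specs)


def fit_mle(
    dag: Dag, data: CohortTable, pseudo_count: float = 0.0
) -> BayesNet:
    """Maximum-likelihood CPTs: empirical conditional frequencies per parent
    configuration.  Unobserved configurations get the uniform row (recorded);
    a positive ``pseudo_count`` switches to additive smoothing."""
    coded, levels = _code_data(data, dag.nodes)
    pos = {n: i for i, n in enumerate(dag.nodes)}
    cpts = {}
    for v in dag.nodes:
        ps = dag.parents(v)
        r = len(levels[v])
        pcards = [len(levels[p]) for p in ps]
        q = int(np.prod(pcards)) if ps else 1
        idx = coded[:, pos[v]].copy()
        stride = r
        for p in ps:
            idx += coded[:, pos[p]] * stride
            stride *= len(levels[p])
        counts = np.bincount(idx, minlength=r * q).reshape(q, r).astype(float)
        counts += pseudo_count
        tot = counts.sum(axis=1, keepdims=True)
        imputed = []
        table = np.empty_like(counts)
        for row in range(q):
            if tot[row, 0] == 0:
                table[row] = 1.0 / r
                # decode the parent configuration for the record
                rem, cfg = row, []
                for p, c in zip(ps, pcards):
                    cfg.append(levels[p][rem % c])
                    rem //= c
                imputed.append(tuple(cfg))
            else:
                table[row] = counts[row] / tot[row, 0]
        shaped = table.reshape(*pcards[::-1], r) if ps else table[0]
        # bincount index used little-endian parent strides; transpose to the
        # declared parent order (first parent = leading axis)
        if ps:
            shaped = shaped.transpose(*range(len(ps) - 1, -1, -1), len(ps))
        cpts[v] = Cpt(
            node=v,
            parents=tuple(ps),
            levels=levels[v],
            parent_levels=tuple(levels[p] for p in ps),
            table=shaped,
            imputed_rows=imputed,
        )
    return BayesNet(dag, cpts)


# ---------------------------------------------------------------------------
# Exact inference
# ---------------------------------------------------------------------------

@dataclass
class Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # one axis per var, in order

    def marginalize(self, var: str) -> "Factor":
        ax = self.vars.index(var)
        return Factor(
            tuple(v for v in self.vars if v != var), self.table.sum(axis=ax)
        )


def _multiply(a: Factor, b: Factor) -> Factor:
    out_vars = tuple(dict.fromkeys(a.vars + b.vars))
    sa = [out_vars.index(v) for v in a.vars]
    sb = [out_vars.index(v) for v in b.vars]
    shape_a = [1] * len(out_vars)
    shape_b = [1] * len(out_vars)
    for ax, v in zip(sa, a.vars):
        shape_a[ax] = a.table.shape[a.vars.index(v)]
    for ax, v in zip(sb, b.vars):
        shape_b[ax] = b.table.shape[b.vars.index(v)]
    ta = a.table.transpose(np.argsort(sa)).reshape(shape_a) if a.vars else a.table
    tb = b.table.transpose(np.argsort(sb)).reshape(shape_b) if b.vars else b.table
    return Factor(out_vars, ta * tb)


@dataclass
class RiskProfile:
    """An evidence assignment with the target's posterior distribution."""

    evidence: dict[str, str]
    target: str
    distribution: dict[str, float]
    ties: list[dict[str, str]] = field(default_factory=list)

    def probability(self, level: str = "yes") -> float:
        return self.distribution[level]


def query(net: BayesNet, evidence: dict[str, str], target: str) -> RiskProfile:
    """Exact posterior P(target | evidence) by variable elimination."""
    if target in evidence:
        raise ValueError("target cannot appear in the evidence")
    for var, lvl in evidence.items():
        if var not in net.cpts:
            raise SchemaError(f"unknown evidence variable {var!r}")
        if lvl not in net.levels(var):
            raise SchemaError(f"{var!r} has no level {lvl!r}")

    factors = []
    for v in net.nodes:
        cpt = net.cpts[v]
        f = Factor(cpt.parents + (v,), cpt.table)
        for var, lvl in evidence.items():
            if var in f.vars:
                ax = f.vars.index(var)
                k = (net.levels(var)).index(lvl)
                f = Factor(
                    tuple(x for x in f.vars if x != var),
                    np.take(f.table, k, axis=ax),
                )
        factors.append(f)

    to_eliminate = [
        v for v in net.nodes if v != target and v not in evidence
    ]
    # min-degree elimination order
    while to_eliminate:
        degree = {
            v: sum(v in f.vars for f in factors) for v in to_eliminate
        }
        v = min(to_eliminate, key=lambda x: (degree[x], x))
        to_eliminate.remove(v)
        related = [f for f in factors if v in f.vars]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors = [f for f in factors if v not in f.vars] + [prod.marginalize(v)]

    result = Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    if result.vars != (target,):
        # target may have been absorbed as a scalar when it is evidence-free
        ax_order = [result.vars.index(target)] if target in result.vars else []
        if not ax_order:
            raise SchemaError("internal: target eliminated")
        result = Factor((target,), np.moveaxis(result.table, ax_order[0], 0))
    total = float(result.table.sum())
    if total == 0.0:
        raise ZeroProbabilityEvidenceError(
            f"evidence {evidence} has probability zero under the network"
        )
    post = result.table / total
    dist = {lvl: float(p) for lvl, p in zip(net.levels(target), post)}
    return RiskProfile(dict(evidence), target, dist)


def max_risk_profile(
    net: BayesNet,
    target: str,
    query_nodes: list[str],
    target_level: str = "yes",
) -> RiskProfile:
    """Exhaustive search for the evidence assignment over ``query_nodes``
    maximising P(target = target_level | assignment).

    Assignments whose evidence is impossible under the network are skipped;
    ties at the maximum are broken lexicographically (the first assignment in
    level order wins) and all tied assignments are reported.
    """
    if target in query_nodes:
        raise ValueError("target cannot be a query node")
    best: RiskProfile | None = None
    ties: list[dict[str, str]] = []
    for combo in itertools.product(*(net.levels(v) for v in query_nodes)):
        ev = dict(zip(query_nodes, combo))
        try:
            prof = query(net, ev, target)
        except ZeroProbabilityEvidenceError:
            continue
        p = prof.probability(target_level)
        if best is None or p > best.probability(target_level) + 1e-12:
            best = prof
            ties = [ev]
        elif abs(p - best.probability(target_level)) <= 1e-12:
            ties.append(ev)
    if best is None:
        raise ZeroProbabilityEvidenceError("all query assignments are impossible")
    best.ties = ties
    return best


def classifier_scores(
    net: BayesNet, data: CohortTable, target: str, target_level: str = "yes"
) -> np.ndarray:
    """P(target = level | all other observed columns), row by row.

    Distinct evidence configurations are cached, so the cost scales with the
    number of unique covariate patterns rather than rows.
    """
    other = [v for v in net.nodes if v != target]
    cache: dict[tuple, float] = {}
    out = np.empty(len(data.df))
    for i in range(len(data.df)):
        key = tuple(str(data.df[v].iloc[i]) for v in other)
        if key not in cache:
            ev = dict(zip(other, key))
            cache[key] = query(net, ev, target).probability(target_level)
        out[i] = cache[key]
    return out
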
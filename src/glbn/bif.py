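"""Read and write discrete Bayesian networks in the BIF interchange format.

Only the discrete subset is supported: ``network``, ``variable`` blocks with
``type discrete`` declarations, and ``probability`` blocks with either a
``table`` line (root nodes) or one parenthesised row per parent
configuration.  Level and node names may contain the interval characters used
by the cohort bins (``<30``, ``30-60``); any run of characters outside
whitespace and the structural delimiters ``{}()[]|,;`` is a token.
"""

from __future__ import annotations

import re

import numpy as np

from .bayesnet import BayesNet, Cpt, Dag
from .schema import SchemaError

_TOKEN = re.compile(r"//[^\n]*|[{}()\[\]|,;]|[^\s{}()\[\]|,;]+")


def export_bif(net: BayesNet, name: str = "glbn") -> str:
    lines = [f"network {name} {{", "}"]
    for v in net.nodes:
        levels = ", ".join(net.levels(v))
        lines += [
            f"variable {v} {{",
            f"  type discrete [ {len(net.levels(v))} ] {{ {levels} }};",
            "}",
        ]
    for v in net.nodes:
        cpt = net.cpts[v]
        if cpt.parents:
            head = f"probability ( {v} | {', '.join(cpt.parents)} ) {{"
        else:
            head = f"probability ( {v} ) {{"
        lines.append(head)
        if not cpt.parents:
            row = ", ".join(format(p, ".12g") for p in cpt.table)
            lines.append(f"  table {row};")
        else:
            import itertools

            for combo in itertools.product(*cpt.parent_levels):
                idx = tuple(
                    pl.index(c) for pl, c in zip(cpt.parent_levels, combo)
                )
                row = ", ".join(format(p, ".12g") for p in cpt.table[idx])
                lines.append(f"  ({', '.join(combo)}) {row};")
        lines.append("}")
    return "\n".join(lines) + "\n"


class _Tokens:
    def __init__(self, text: str):
        self.toks = [t for t in _TOKEN.findall(text) if not t.startswith("//")]
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> str:
        if self.i >= len(self.toks):
            raise SchemaError("unexpected end of BIF input")
        t = self.toks[self.i]
        self.i += 1
        return t

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise SchemaError(f"BIF parse error: expected {tok!r}, got {got!r}")

    def until(self, tok: str) -> list[str]:
        out = []
        while True:
            t = self.next()
            if t == tok:
                return out
            out.append(t)


def import_bif(text: str) -> BayesNet:
    tk = _Tokens(text)
    variables: dict[str, tuple[str, ...]] = {}
    order: list[str] = []
    prob_blocks: dict[str, tuple[tuple[str, ...], dict]] = {}

    while tk.peek() is not None:
        kw = tk.next()
        if kw == "network":
            tk.until("{")
            tk.until("}")
        elif kw == "variable":
            name = tk.next()
            tk.expect("{")
            tk.expect("type")
            tk.expect("discrete")
            tk.expect("[")
            n_levels = int(tk.next())
            tk.expect("]")
            tk.expect("{")
            levels = tuple(t for t in tk.until("}") if t != ",")
            tk.expect(";")
            tk.expect("}")
            if len(levels) != n_levels:
                raise SchemaError(f"variable {name}: level count mismatch")
            variables[name] = levels
            order.append(name)
        elif kw == "probability":
            tk.expect("(")
            inner = tk.until(")")
            parts = [t for t in inner if t != ","]
            if "|" in parts:
                bar = parts.index("|")
                node, parents = parts[0], tuple(parts[bar + 1 :])
                if bar != 1:
                    raise SchemaError("probability header must name one child")
            else:
                if len(parts) != 1:
                    raise SchemaError("probability header must name one child")
                node, parents = parts[0], ()
            tk.expect("{")
            rows: dict = {}
            while tk.peek() != "}":
                t = tk.next()
                if t == "table":
                    vals = [float(x) for x in tk.until(";") if x != ","]
                    rows[()] = vals
                elif t == "(":
                    combo = tuple(x for x in tk.until(")") if x != ",")
                    vals = [float(x) for x in tk.until(";") if x != ","]
                    rows[combo] = vals
                else:
                    raise SchemaError(f"BIF parse error in probability block: {t!r}")
            tk.expect("}")
            prob_blocks[node] = (parents, rows)
        else:
            raise SchemaError(f"BIF parse error: unexpected token {kw!r}")

    if set(prob_blocks) != set(variables):
        raise SchemaError("every variable needs exactly one probability block")

    edges = set()
    cpts = {}
    for node, (parents, rows) in prob_blocks.items():
        levels = variables[node]
        parent_levels = tuple(variables[p] for p in parents)
        shape = tuple(len(pl) for pl in parent_levels) + (len(levels),)
        table = np.full(shape, np.nan)
        if not parents:
            table[...] = np.asarray(rows[()], dtype=float)
        else:
            for combo, vals in rows.items():
                idx = tuple(pl.index(c) for pl, c in zip(parent_levels, combo))
                table[idx] = np.asarray(vals, dtype=float)
        if np.isnan(table).any():
            raise SchemaError(f"probability block for {node}: missing rows")
        sums = table.sum(axis=-1, keepdims=True)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise SchemaError(f"probability block for {node}: rows must sum to 1")
        table = table / sums  # absorb text-format rounding
        for p in parents:
            edges.add((p, node))
        cpts[node] = Cpt(
            node=node,
            parents=parents,
            levels=levels,
            parent_levels=parent_levels,
            table=table,
        )
    dag = Dag(order, edges)
    return BayesNet(dag, cpts)
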
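"""Regulator-regulator module graph and single-module modularity MILP.

Two regulators are linked by the correlation of their activity profiles
scaled by the evidence that one regulates the other:

    w(t1,t2) = mean( cor(act_t1, act_t2) * es(t1->t2),
                     cor(act_t1, act_t2) * es(t2->t1) )

(a missing direction contributes es = 0 before the two-direction mean).
Newman's null model subtracts the degree-product expectation, giving the
modularity-corrected weight

    w~(t1,t2) = w(t1,t2) - d_t1 * d_t2 / (2m),   d_t = sum_t2 w(t,t2),
                                                 m = (1/2) sum_t d_t,

which sums to zero over all ordered pairs.  The single-module MILP then
selects at most ``limit`` nodes maximizing the sum of within-module pair
weights; the pair indicator y is forced to the product of its endpoint
indicators, so negative within-module weights penalize the objective rather
than being silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint

from ._solver import DEFAULT_GAP, solve_milp, stack_rows
from .activity import ActivityMatrix
from .regnet import RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = ["ModuleGraph", "pairwise_weights", "modularity_correct", "solve_module"]


@dataclass
class ModuleGraph:
    nodes: tuple[str, ...]
    w: pd.DataFrame  # symmetric, zero diagonal
    w_mod: pd.DataFrame | None = None
    d: pd.Series | None = None
    m: float | None = None

    def weight(self, t1: str, t2: str, corrected: bool = True) -> float:
        mat = self.w_mod if corrected and self.w_mod is not None else self.w
        return float(mat.loc[t1, t2])


def pairwise_weights(
    act: ActivityMatrix, net: RegulatoryNetwork, nodes: list[str] | None = None
) -> ModuleGraph:
    """Correlation-times-evidence edge weights, averaged over both directions."""
    if nodes is None:
        nodes = act.regulator_ids
    nodes = tuple(nodes)
    sub = act.act.loc[list(nodes)].to_numpy()
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 common samples for pairwise correlations")
    if np.isnan(sub).any():
        raise ValueError("activities must be defined over a common sample set")
    sd = sub.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(sub)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant activity for %s; correlations set to 0",
            [nodes[i] for i in np.where(constant)[0]],
        )
        cor[constant, :] = 0.0
        cor[:, constant] = 0.0
    n = len(nodes)
    w = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        es_fwd = net.edge_score(nodes[i], nodes[j])
        es_bwd = net.edge_score(nodes[j], nodes[i])
        w[i, j] = w[j, i] = cor[i, j] * (es_fwd + es_bwd) / 2.0
    frame = pd.DataFrame(w, index=list(nodes), columns=list(nodes))
    return ModuleGraph(nodes=nodes, w=frame)


def modularity_correct(g: ModuleGraph) -> ModuleGraph:
    """Subtract the Newman null-model expectation d_t1 d_t2 / (2m) from w."""
    w = g.w.to_numpy()
    d = w.sum(axis=1)
    m = 0.5 * d.sum()
    if m == 0:
        raise ValueError("degenerate graph: total weight m = 0")
    # diagonal keeps -d_t^2/(2m): the null model corrects self-pairs too,
    # which is what makes the corrected weights sum to zero overall; the
    # module MILP never selects self-pairs, so these terms are bookkeeping only
    w_mod = w - np.outer(d, d) / (2.0 * m)
    g.w_mod = pd.DataFrame(w_mod, index=g.w.index, columns=g.w.columns)
    g.d = pd.Series(d, index=g.w.index)
    g.m = float(m)
    return g


def solve_module(
    g: ModuleGraph,
    limit: int,
    use_corrected: bool = True,
    gap: float = DEFAULT_GAP,
) -> tuple[tuple[str, ...], tuple[tuple[str, str], ...], float]:
    """Select <= ``limit`` nodes maximizing the within-module pair-weight sum.

    Returns (selected nodes, selected pairs, objective).  With
    ``use_corrected`` (default) the modularity-corrected weights are the
    objective coefficients; set it False to optimize the raw weights.
    """
    if limit < 0:
        raise ValueError("limit must be >= 0")
    if use_corrected and g.w_mod is None:
        modularity_correct(g)
    mat = (g.w_mod if use_corrected else g.w).to_numpy()
    nodes = g.nodes
    n = len(nodes)
    pairs = [(i, j) for i, j in combinations(range(n), 2) if mat[i, j] != 0.0]
    P = len(pairs)

    # variables: [x_0..n-1, y_0..P-1]
    nvar = n + P
    c = np.zeros(nvar)
    for p, (i, j) in enumerate(pairs):
        c[n + p] = -mat[i, j]  # maximize

    rows, lb, ub = [], [], []
    for p, (i, j) in enumerate(pairs):
        r = np.zeros(nvar)
        r[i] = 1.0
        r[j] = 1.0
        r[n + p] = -1.0  # x_i + x_j - y <= 1
        rows.append(r)
        lb.append(-np.inf)
        ub.append(1.0)
        r = np.zeros(nvar)
        r[n + p] = 1.0
        r[i] = -1.0  # y <= x_i
        rows.append(r)
        lb.append(-np.inf)
        ub.append(0.0)
        r = np.zeros(nvar)
        r[n + p] = 1.0
        r[j] = -1.0  # y <= x_j
        rows.append(r)
        lb.append(-np.inf)
        ub.append(0.0)
    card = np.zeros(nvar)
    card[:n] = 1.0
    rows.append(card)
    lb.append(-np.inf)
    ub.append(float(limit))

    constraints = [LinearConstraint(stack_rows([np.array(rows)]), lb, ub)]
    integrality = np.ones(nvar)
    bounds = Bounds(np.zeros(nvar), np.ones(nvar))
    sol = solve_milp(c, constraints, integrality, bounds, gap=gap)

    xsel = sol.x[:n] > 0.5
    selected = tuple(nodes[i] for i in range(n) if xsel[i])
    ysel = tuple(
        (nodes[i], nodes[j]) for p, (i, j) in enumerate(pairs) if sol.x[n + p] > 0.5
    )
    return selected, ysel, -sol.objective


def export_module_graph(g: ModuleGraph, path, fmt: str = "graphml") -> None:
    """Write the module graph with w and w~ edge attributes (GraphML or SIF)."""
    gx = nx.Graph()
    gx.add_nodes_from(g.nodes)
    for t1, t2 in combinations(g.nodes, 2):
        w = float(g.w.loc[t1, t2])
        if w == 0.0:
            continue
        attrs = {"w": w}
        if g.w_mod is not None:
            attrs["w_mod"] = float(g.w_mod.loc[t1, t2])
        gx.add_edge(t1, t2, **attrs)
    if fmt == "graphml":
        nx.write_graphml(gx, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for t1, t2 in gx.edges:
                fh.write(f"{t1}\tpair\t{t2}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
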
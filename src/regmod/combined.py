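"""Joint regression + modularity model with a tunable tradeoff.

A single MILP couples the best-subset L1 regression (over the direct
candidate regulators of the target gene) with the single-module modularity
objective (over direct and indirect candidates together):

    minimize  sum_k e_k  -  lambda * sum_{t1<t2} w~(t1,t2) * y(t1,t2)

The node indicators x_t are shared between the two parts for regulators
that are both direct candidates and module nodes, and one cardinality
budget sum x_t <= limit covers the union, so a size-s model spends its s
slots on whichever mix of direct and indirect regulators the objective
prefers.  lambda = 0 reduces to the pure regression; a very large lambda
reduces to the pure modularity module.

The tradeoff is tuned by sweeping lambda over a logarithmic grid, counting
how many direct-pool and indirect-pool regulators all cross-validation
models selected at each lambda, and interpolating the crossing of the two
counts on the log10(lambda) axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint

from ._solver import DEFAULT_GAP, solve_milp, stack_rows
from .activity import ActivityMatrix, compute_activity
from .data_io import ExpressionMatrix
from .miprip import TIE_EPS, cross_validate, make_folds, performance
from .modularity import ModuleGraph, modularity_correct, pairwise_weights
from .regnet import RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedModel",
    "LambdaSweep",
    "preselect_indirect",
    "solve_combined",
    "lambda_sweep",
    "extract_final_module",
]

LAMBDA_GRID = (0.001, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0, 1000.0)


@dataclass
class CombinedModel:
    direct_selected: tuple[str, ...]
    indirect_selected: tuple[str, ...]
    beta0: float
    beta: dict[str, float]
    lam: float
    limit: int
    fit_error: float
    modularity_score: float
    objective: float
    performance: float = float("nan")
    repeat: int = -1
    fold: int = -1


@dataclass
class LambdaSweep:
    grid: tuple[float, ...]
    direct_counts: list[int]
    indirect_counts: list[int]
    mean_performance: list[float]
    capacity: int
    lambda_star: float | None
    models: dict[float, list[CombinedModel]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.grid,
                "direct_selections": self.direct_counts,
                "indirect_selections": self.indirect_counts,
                "mean_performance": self.mean_performance,
            }
        )


def preselect_indirect(
    x: ExpressionMatrix,
    net: RegulatoryNetwork,
    direct_regulators: list[str],
    threshold: float = 0.20,
    sizes: range | list[int] = range(1, 11),
    repeats: int = 10,
    folds: int = 3,
    seed: int = 0,
    bigM: float = 100.0,
    gap: float = DEFAULT_GAP,
) -> tuple[dict[str, list[str]], list[str], list[str]]:
    """Indirect-candidate pools: regulators of each direct regulator's gene.

    Runs the single-target CV ensemble with each direct regulator's coding
    gene as the target and keeps regulators selected in at least
    ``threshold`` of the models (the 20% default is inclusive).  Returns
    (per-direct mapping, pooled union, overlap of the union with the direct
    list).  Direct regulators whose coding gene has no usable expression are
    skipped with a warning, contributing nothing.
    """
    mapping: dict[str, list[str]] = {}
    for d in sorted(direct_regulators):
        if d not in x.values.index:
            logger.warning("no expression for %r; skipped in indirect pre-selection", d)
            mapping[d] = []
            continue
        present = x.values.loc[d].notna()
        if present.sum() < folds:
            logger.warning("too few measured samples for %r; skipped", d)
            mapping[d] = []
            continue
        xs = x.subset_samples(list(x.values.columns[present]))
        candidates = [r for r in net.regulators_of(d) if r != d]
        if not candidates:
            mapping[d] = []
            continue
        cv = cross_validate(
            xs, net, d, candidates, sizes=sizes, repeats=repeats, folds=folds,
            seed=seed, bigM=bigM, gap=gap,
        )
        cut = threshold * cv.n_models
        kept = sorted(r for r, c in cv.frequencies.items() if c >= cut)
        mapping[d] = kept
    pool = sorted(set().union(*mapping.values()) if mapping else set())
    overlap = sorted(set(pool) & set(direct_regulators))
    return mapping, pool, overlap


def solve_combined(
    act: ActivityMatrix,
    target: np.ndarray | pd.Series,
    es_target: dict[str, float],
    direct_candidates: list[str],
    indirect_candidates: list[str],
    module_graph: ModuleGraph,
    lam: float,
    limit: int,
    bigM: float = 100.0,
    gap: float = DEFAULT_GAP,
    use_corrected: bool = True,
) -> CombinedModel:
    """Solve the coupled regression + modularity MILP to proven optimality."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    direct = sorted(direct_candidates)
    nodes = sorted(set(direct) | set(indirect_candidates))
    missing = [v for v in nodes if v not in module_graph.nodes]
    if missing:
        raise ValueError(f"module graph does not span candidates {missing}")
    if use_corrected and module_graph.w_mod is None:
        modularity_correct(module_graph)
    wmat = (module_graph.w_mod if use_corrected else module_graph.w).loc[nodes, nodes].to_numpy()

    A = act.act.loc[direct].to_numpy()
    g = np.asarray(target, dtype=float)
    D, K = A.shape
    es = np.array([es_target.get(r, 0.0) for r in direct])
    X = es[:, None] * A
    n = len(nodes)
    node_index = {v: i for i, v in enumerate(nodes)}
    pairs = [(i, j) for i, j in combinations(range(n), 2) if wmat[i, j] != 0.0]
    P = len(pairs)

    # variables: [beta0, beta_1..D, e_1..K, x_1..n, y_1..P]
    nvar = 1 + D + K + n + P
    xoff, yoff = 1 + D + K, 1 + D + K + n
    c = np.zeros(nvar)
    c[1 + D : xoff] = 1.0
    c[xoff : xoff + n] = TIE_EPS * (1 + np.arange(n))
    for p, (i, j) in enumerate(pairs):
        c[yoff + p] = -lam * wmat[i, j]

    rows, lb, ub = [], [], []
    for k in range(K):
        r = np.zeros(nvar)
        r[0] = 1.0
        r[1 : 1 + D] = X[:, k]
        r[1 + D + k] = 1.0
        rows.append(r)
        lb.append(g[k])
        ub.append(np.inf)
        r = np.zeros(nvar)
        r[0] = -1.0
        r[1 : 1 + D] = -X[:, k]
        r[1 + D + k] = 1.0
        rows.append(r)
        lb.append(-g[k])
        ub.append(np.inf)
    for t, d_name in enumerate(direct):
        xi = xoff + node_index[d_name]
        r = np.zeros(nvar)
        r[1 + t] = 1.0
        r[xi] = -bigM
        rows.append(r)
        lb.append(-np.inf)
        ub.append(0.0)
        r = np.zeros(nvar)
        r[1 + t] = 1.0
        r[xi] = bigM
        rows.append(r)
        lb.append(0.0)
        ub.append(np.inf)
    for p, (i, j) in enumerate(pairs):
        r = np.zeros(nvar)
        r[xoff + i] = 1.0
        r[xoff + j] = 1.0
        r[yoff + p] = -1.0
        rows.append(r)
        lb.append(-np.inf)
        ub.append(1.0)
        r = np.zeros(nvar)
        r[yoff + p] = 1.0
        r[xoff + i] = -1.0
        rows.append(r)
        lb.append(-np.inf)
        ub.append(0.0)
        r = np.zeros(nvar)
        r[yoff + p] = 1.0
        r[xoff + j] = -1.0
        rows.append(r)
        lb.append(-np.inf)
        ub.append(0.0)
    card = np.zeros(nvar)
    card[xoff : xoff + n] = 1.0
    rows.append(card)
    lb.append(-np.inf)
    ub.append(float(limit))

    constraints = [LinearConstraint(stack_rows([np.array(rows)]), lb, ub)]
    integrality = np.zeros(nvar)
    integrality[xoff:] = 1
    bounds = Bounds(
        np.concatenate([np.full(1 + D, -np.inf), np.zeros(K), np.zeros(n + P)]),
        np.concatenate([np.full(1 + D + K, np.inf), np.ones(n + P)]),
    )
    sol = solve_milp(c, constraints, integrality, bounds, gap=gap)

    xsel = sol.x[xoff : xoff + n] > 0.5
    selected = {nodes[i] for i in range(n) if xsel[i]}
    direct_sel = tuple(sorted(selected & set(direct)))
    indirect_sel = tuple(sorted(selected - set(direct)))
    beta = {
        d_name: float(sol.x[1 + t])
        for t, d_name in enumerate(direct)
        if d_name in selected and abs(sol.x[1 + t]) > 0
    }
    fit_error = float(sol.x[1 + D : xoff].sum())
    mod_score = float(
        sum(wmat[i, j] for p, (i, j) in enumerate(pairs) if sol.x[yoff + p] > 0.5)
    )
    return CombinedModel(
        direct_selected=direct_sel,
        indirect_selected=indirect_sel,
        beta0=float(sol.x[0]),
        beta=beta,
        lam=lam,
        limit=limit,
        fit_error=fit_error,
        modularity_score=mod_score,
        objective=fit_error - lam * mod_score,
    )


def lambda_sweep(
    x: ExpressionMatrix,
    net: RegulatoryNetwork,
    target_gene: str,
    direct_candidates: list[str],
    indirect_candidates: list[str],
    grid: tuple[float, ...] = LAMBDA_GRID,
    sizes: range | list[int] = range(2, 21),
    repeats: int = 10,
    folds: int = 3,
    seed: int = 0,
    bigM: float = 100.0,
    gap: float = DEFAULT_GAP,
    keep_models: bool = True,
) -> LambdaSweep:
    """Sweep lambda over a log grid, full CV at every value.

    Pair weights are computed once from the all-sample activities (they are
    constants of the MILP); the CV re-splits samples identically at every
    lambda (same seed) so the counts are comparable across the grid.
    """
    direct = sorted(set(direct_candidates))
    nodes = sorted(set(direct) | set(indirect_candidates))
    act_all = compute_activity(x, net, nodes, exclude_gene=target_gene)
    usable = set(act_all.defined_regulators())
    if set(nodes) - usable:
        logger.warning("dropping candidates with undefined activities: %s", sorted(set(nodes) - usable))
        direct = [d for d in direct if d in usable]
        nodes = [v for v in nodes if v in usable]
        act_all = ActivityMatrix(act_all.act.loc[nodes])
    graph = modularity_correct(pairwise_weights(act_all, net, nodes))
    es_target = {r: net.edge_score(r, target_gene) for r in direct}
    g = x.gene_values(target_gene).to_numpy()
    samples = np.array(x.sample_ids)
    sizes = list(sizes)
    capacity = repeats * folds * sum(sizes)

    direct_counts, indirect_counts, mean_perf = [], [], []
    models_by_lam: dict[float, list[CombinedModel]] = {}
    for lam in grid:
        rng = np.random.default_rng(seed)
        n_dir = n_ind = 0
        perfs: list[float] = []
        models: list[CombinedModel] = []
        for rep in range(repeats):
            parts = make_folds(len(samples), folds, rng)
            for f, test_idx in enumerate(parts):
                train_idx = np.sort(np.setdiff1d(np.arange(len(samples)), test_idx))
                act_tr = act_all.subset_samples(list(samples[train_idx]))
                act_te = act_all.subset_samples(list(samples[test_idx]))
                for size in sizes:
                    m = solve_combined(
                        act_tr, g[train_idx], es_target, direct, nodes, graph,
                        lam=lam, limit=size, bigM=bigM, gap=gap,
                    )
                    m.repeat, m.fold = rep, f
                    pred = np.full(len(test_idx), m.beta0)
                    for r_name in m.direct_selected:
                        if r_name in m.beta:
                            pred = pred + (
                                m.beta[r_name]
                                * es_target.get(r_name, 0.0)
                                * act_te.act.loc[r_name].to_numpy()
                            )
                    m.performance = performance(pred, g[test_idx]) if np.ptp(pred) > 0 else float("nan")
                    n_dir += len(m.direct_selected)
                    n_ind += len(m.indirect_selected)
                    if not np.isnan(m.performance):
                        perfs.append(m.performance)
                    models.append(m)
        direct_counts.append(n_dir)
        indirect_counts.append(n_ind)
        mean_perf.append(float(np.mean(perfs)) if perfs else float("nan"))
        if keep_models:
            models_by_lam[lam] = models

    lam_star = interpolate_crossing(grid, direct_counts, indirect_counts)
    return LambdaSweep(
        grid=tuple(grid),
        direct_counts=direct_counts,
        indirect_counts=indirect_counts,
        mean_performance=mean_perf,
        capacity=capacity,
        lambda_star=lam_star,
        models=models_by_lam,
    )


def interpolate_crossing(
    grid: tuple[float, ...] | list[float],
    direct_counts: list[int] | list[float],
    indirect_counts: list[int] | list[float],
) -> float | None:
    """Crossing of the direct and indirect count curves on the log10 axis.

    Linear interpolation between the adjacent grid points where the sign of
    (direct - indirect) flips; an exact zero at a grid point returns that
    lambda.  Without a sign change the crossing is undefined: a warning is
    logged and the grid value minimizing |direct - indirect| is returned.
    """
    diff = np.asarray(direct_counts, float) - np.asarray(indirect_counts, float)
    logs = np.log10(np.asarray(grid, float))
    exact = np.where(diff == 0)[0]
    if exact.size:
        return float(grid[exact[0]])
    flips = np.where(np.sign(diff[:-1]) != np.sign(diff[1:]))[0]
    if flips.size == 0:
        logger.warning("direct/indirect curves do not cross on the grid")
        return float(grid[int(np.argmin(np.abs(diff)))])
    i = int(flips[0])
    frac = diff[i] / (diff[i] - diff[i + 1])
    return float(10 ** (logs[i] + frac * (logs[i + 1] - logs[i])))


def extract_final_module(
    models: list[CombinedModel],
) -> tuple[tuple[str, ...], tuple[str, ...], int]:
    """Most frequent direct combination + its majority indirect co-selections.

    Ties between equally frequent direct combinations are broken by higher
    mean held-out performance, then lexicographically.  The indirect set
    contains regulators selected in more than half of the models carrying
    the winning direct combination.  Returns (direct, indirect, support).
    """
    if not models:
        raise ValueError("need at least one model")
    groups: dict[tuple[str, ...], list[CombinedModel]] = {}
    for m in models:
        groups.setdefault(tuple(sorted(m.direct_selected)), []).append(m)

    def rank(combo: tuple[str, ...]):
        ms = groups[combo]
        perfs = [m.performance for m in ms if not np.isnan(m.performance)]
        mean_perf = np.mean(perfs) if perfs else -np.inf
        return (-len(ms), -mean_perf, combo)

    winner = min(groups, key=rank)
    support = len(groups[winner])
    counts: dict[str, int] = {}
    for m in groups[winner]:
        for r in m.indirect_selected:
            counts[r] = counts.get(r, 0) + 1
    indirect = tuple(sorted(r for r, c in counts.items() if c > support / 2))
    return winner, indirect, support
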
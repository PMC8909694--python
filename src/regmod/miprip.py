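"""MILP best-subset regression of target expression on regulator activities.

The predicted expression of the target gene in sample k is

    g~_k = beta0 + sum_t beta_t * es_t * act_tk

where es_t is the regulator's edge score onto the target and act_tk its
inferred activity.  The fit minimizes the sum of absolute residuals
(linearized as e_k >= +/-(g_k - g~_k)) while a binary indicator x_t with a
big-M link gates each coefficient, and sum x_t <= size caps the subset
cardinality.  The solver proves global optimality, so for a given training
set and size the selected regulator combination is the exact L1 best subset.

Model ensembles come from repeated cross-validation: the data are split
into thirds, the best combination of each size is fit on two thirds and
scored by Pearson correlation on the held-out third, and per-regulator
selection frequencies are tallied over all models.  Running the ensemble
separately per sample condition and testing each regulator's selection
frequencies against each other (Fisher exact + Benjamini-Hochberg) yields
the condition-specific regulator table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import Bounds, LinearConstraint

from ._solver import DEFAULT_GAP, solve_milp, stack_rows
from .activity import ActivityMatrix, compute_activity
from .data_io import ExpressionMatrix
from .regnet import RegulatoryNetwork
from .stats_assoc import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionModel",
    "CVResult",
    "fit_model",
    "predict",
    "performance",
    "cross_validate",
    "compare_conditions",
    "make_folds",
]

#: secondary-objective perturbation enforcing lexicographic tie-breaks
TIE_EPS = 1e-9


@dataclass
class RegressionModel:
    selected: tuple[str, ...]
    beta0: float
    beta: dict[str, float]
    size_limit: int
    train_error: float
    performance: float = float("nan")
    repeat: int = -1
    fold: int = -1

    def __post_init__(self) -> None:
        assert len(self.selected) <= self.size_limit or self.size_limit < 0


@dataclass
class CVResult:
    models: list[RegressionModel]
    frequencies: dict[str, int]
    n_models: int
    candidates: tuple[str, ...]

    def frequency_table(self) -> pd.DataFrame:
        rows = [
            {"regulator": r, "count": self.frequencies.get(r, 0), "n_models": self.n_models}
            for r in self.candidates
        ]
        df = pd.DataFrame(rows).sort_values("count", ascending=False, kind="stable")
        return df.reset_index(drop=True)


def fit_model(
    act: ActivityMatrix,
    target: np.ndarray | pd.Series,
    es_target: dict[str, float],
    size: int,
    bigM: float = 100.0,
    gap: float = DEFAULT_GAP,
) -> RegressionModel:
    """Globally optimal L1 best-subset fit with at most ``size`` regulators."""
    if size < 0:
        raise ValueError("size must be >= 0")
    regs = sorted(act.regulator_ids)
    A = act.act.loc[regs].to_numpy()  # T x K
    if np.isnan(A).any():
        bad = [r for r in regs if act.act.loc[r].isna().any()]
        raise ValueError(f"undefined activities for regulators {bad}")
    g = np.asarray(target, dtype=float)
    T, K = A.shape
    if g.shape != (K,):
        raise ValueError("target length does not match activity samples")
    es = np.array([es_target.get(r, 0.0) for r in regs])
    X = es[:, None] * A  # predictor rows per regulator

    # variables: [beta0, beta_1..T, e_1..K, x_1..T]
    nvar = 1 + T + K + T
    c = np.zeros(nvar)
    c[1 + T : 1 + T + K] = 1.0
    c[1 + T + K :] = TIE_EPS * (1 + np.arange(T))  # lexicographic tie-break

    resid = np.zeros((2 * K, nvar))
    for k in range(K):
        resid[k, 0] = 1.0
        resid[k, 1 : 1 + T] = X[:, k]
        resid[k, 1 + T + k] = 1.0
        resid[K + k, 0] = -1.0
        resid[K + k, 1 : 1 + T] = -X[:, k]
        resid[K + k, 1 + T + k] = 1.0
    link = np.zeros((2 * T + 1, nvar))
    for t in range(T):
        link[t, 1 + t] = 1.0
        link[t, 1 + T + K + t] = -bigM  # beta - M x <= 0
        link[T + t, 1 + t] = 1.0
        link[T + t, 1 + T + K + t] = bigM  # beta + M x >= 0
    link[2 * T, 1 + T + K :] = 1.0  # cardinality

    constraints = [
        LinearConstraint(stack_rows([resid]), np.concatenate([g, -g]), np.inf),
        LinearConstraint(
            stack_rows([link]),
            np.concatenate([np.full(T, -np.inf), np.zeros(T), [-np.inf]]),
            np.concatenate([np.zeros(T), np.full(T, np.inf), [size]]),
        ),
    ]
    integrality = np.zeros(nvar)
    integrality[1 + T + K :] = 1
    bounds = Bounds(
        np.concatenate([np.full(1 + T, -np.inf), np.zeros(K), np.zeros(T)]),
        np.concatenate([np.full(1 + T + K, np.inf), np.ones(T)]),
    )
    sol = solve_milp(c, constraints, integrality, bounds, gap=gap)

    xsel = sol.x[1 + T + K :] > 0.5
    betas = sol.x[1 : 1 + T]
    selected = tuple(r for r, s in zip(regs, xsel) if s)
    beta = {r: float(b) for r, b, s in zip(regs, betas, xsel) if s}
    for r, b in beta.items():
        if abs(b) >= bigM * (1 - 1e-6):
            logger.warning("coefficient for %r hit the bigM bound (%.3g)", r, b)
    train_error = float(sol.x[1 + T : 1 + T + K].sum())
    return RegressionModel(
        selected=selected,
        beta0=float(sol.x[0]),
        beta=beta,
        size_limit=size,
        train_error=train_error,
    )


def predict(
    model: RegressionModel, act: ActivityMatrix, es_target: dict[str, float]
) -> np.ndarray:
    """Evaluate the fitted linear model on (new) samples."""
    pred = np.full(len(act.sample_ids), model.beta0, dtype=float)
    for r in model.selected:
        if r not in act.act.index:
            raise ValueError(f"activity missing for selected regulator {r!r}")
        row = act.act.loc[r].to_numpy()
        if np.isnan(row).any():
            raise ValueError(f"activity undefined for selected regulator {r!r}")
        pred += model.beta[r] * es_target.get(r, 0.0) * row
    return pred


def performance(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Pearson correlation between prediction and measurement (NaN if constant)."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape or predicted.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        logger.warning("constant vector: correlation undefined")
        return float("nan")
    return float(stats.pearsonr(predicted, measured).statistic)


def make_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded permutation split into ``folds`` parts with sizes differing by <= 1."""
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def cross_validate(
    x: ExpressionMatrix,
    net: RegulatoryNetwork,
    target_gene: str,
    candidates: list[str] | None = None,
    sizes: range | list[int] = range(1, 11),
    repeats: int = 10,
    folds: int = 3,
    seed: int = 0,
    bigM: float = 100.0,
    gap: float = DEFAULT_GAP,
) -> CVResult:
    """Repeated k-fold CV of best-subset models over a grid of sizes.

    For every repeat the samples are re-shuffled into ``folds`` parts; each
    part serves once as the held-out third while models of every size in
    ``sizes`` are fit on the rest and scored on it by Pearson correlation.
    """
    if candidates is None:
        candidates = net.regulators_of(target_gene)
    act_all = compute_activity(x, net, sorted(candidates), exclude_gene=target_gene)
    usable = act_all.defined_regulators()
    dropped = sorted(set(candidates) - set(usable))
    if dropped:
        logger.warning("excluding regulators with undefined activities: %s", dropped)
    act_all = ActivityMatrix(act_all.act.loc[usable])
    es_target = {r: net.edge_score(r, target_gene) for r in usable}
    g = x.gene_values(target_gene).to_numpy()
    samples = np.array(x.sample_ids)

    rng = np.random.default_rng(seed)
    models: list[RegressionModel] = []
    freqs: dict[str, int] = {}
    for rep in range(repeats):
        parts = make_folds(len(samples), folds, rng)
        for f, test_idx in enumerate(parts):
            train_idx = np.sort(np.setdiff1d(np.arange(len(samples)), test_idx))
            act_tr = act_all.subset_samples(list(samples[train_idx]))
            act_te = act_all.subset_samples(list(samples[test_idx]))
            for size in sizes:
                m = fit_model(act_tr, g[train_idx], es_target, size, bigM=bigM, gap=gap)
                m.repeat, m.fold = rep, f
                m.performance = performance(predict(m, act_te, es_target), g[test_idx])
                models.append(m)
                for r in m.selected:
                    freqs[r] = freqs.get(r, 0) + 1
    n_models = repeats * folds * len(list(sizes))
    assert n_models == len(models)
    return CVResult(models=models, frequencies=freqs, n_models=n_models, candidates=tuple(usable))


def compare_conditions(cv_A: CVResult, cv_B: CVResult) -> pd.DataFrame:
    """Per-regulator Fisher exact test on selection frequencies in two ensembles.

    Builds the 2x2 table [count_A, n_A - count_A; count_B, n_B - count_B] per
    regulator, adjusts the two-sided p-values with Benjamini-Hochberg across
    all tested regulators, and returns the table sorted by adjusted p.
    """
    if cv_A.n_models == 0 or cv_B.n_models == 0:
        raise ValueError("both conditions need at least one model")
    regs = sorted(set(cv_A.candidates) | set(cv_B.candidates))
    rows = []
    for r in regs:
        a, b = cv_A.frequencies.get(r, 0), cv_B.frequencies.get(r, 0)
        table = [[a, cv_A.n_models - a], [b, cv_B.n_models - b]]
        p = stats.fisher_exact(table, alternative="two-sided").pvalue
        rows.append(
            {
                "regulator": r,
                "count_A": a,
                "count_B": b,
                "n_A": cv_A.n_models,
                "n_B": cv_B.n_models,
                "p_raw": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p_raw"].tolist())
    return df.sort_values(["p_adj", "p_raw", "regulator"], kind="stable").reset_index(drop=True)
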
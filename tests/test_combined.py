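from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import helpers
from regmod import (
    extract_final_module,
    fit_model,
    generate,
    interpolate_crossing,
    lambda_sweep,
    preprocess_expression,
    preselect_indirect,
    solve_combined,
    solve_module,
)
from regmod.activity import ActivityMatrix
from regmod.combined import CombinedModel
from regmod.modularity import ModuleGraph, modularity_correct


def make_act(arr, regs):
    return ActivityMatrix(
        pd.DataFrame(arr, index=regs, columns=[f"s{j}" for j in range(arr.shape[1])])
    )


def graph_from_w(w, nodes):
    g = ModuleGraph(tuple(nodes), pd.DataFrame(w, index=list(nodes), columns=list(nodes)))
    return modularity_correct(g)


def toy_problem(seed=0, n_direct=4, n_indirect=4, K=30):
    rng = np.random.default_rng(seed)
    direct = [f"D{i}" for i in range(n_direct)]
    indirect = [f"I{i}" for i in range(n_indirect)]
    nodes = sorted(direct + indirect)
    arr = rng.normal(size=(len(nodes), K))
    act = make_act(arr, nodes)
    g = act.act.loc["D0"].to_numpy() - 0.8 * act.act.loc["D1"].to_numpy()
    g = g + 0.3 * rng.normal(size=K)
    es = {d: 1.0 for d in direct}
    w = rng.normal(scale=0.5, size=(len(nodes), len(nodes)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    graph = graph_from_w(w, nodes)
    return act, g, es, direct, indirect, graph


class TestSolveCombined:
    def test_lambda_zero_reduces_to_regression(self):
        act, g, es, direct, indirect, graph = toy_problem(seed=1)
        cm = solve_combined(act, g, es, direct, indirect, graph, lam=0.0, limit=2)
        act_d = ActivityMatrix(act.act.loc[direct])
        rm = fit_model(act_d, g, es, size=2)
        assert cm.fit_error == pytest.approx(rm.train_error, abs=1e-6)
        assert set(cm.direct_selected) == set(rm.selected)

    def test_large_lambda_reduces_to_modularity(self):
        act, g, es, direct, indirect, graph = toy_problem(seed=2)
        cm = solve_combined(act, g, es, direct, indirect, graph, lam=1e6, limit=3)
        sel, _, obj = solve_module(graph, 3)
        assert cm.modularity_score == pytest.approx(obj, abs=1e-6)
        assert set(cm.direct_selected) | set(cm.indirect_selected) == set(sel)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        act, g, es, direct, indirect, graph = toy_problem(seed=seed, K=25)
        lam, limit = 1.0, 3
        cm = solve_combined(act, g, es, direct, indirect, graph, lam=lam, limit=limit)
        nodes = list(graph.nodes)
        wmod = graph.w_mod.to_numpy()
        arr = act.act.loc[nodes].to_numpy()
        best = np.inf
        for s in range(limit + 1):
            for combo in combinations(range(len(nodes)), s):
                d_idx = [i for i in combo if nodes[i] in direct]
                X = (
                    np.array([es[nodes[i]] * arr[i] for i in d_idx])
                    if d_idx
                    else np.empty((0, len(g)))
                )
                fit = helpers.lad_fit(X, g)
                mod = helpers.module_score(wmod, combo)
                best = min(best, fit - lam * mod)
        assert cm.objective == pytest.approx(best, abs=1e-6)

    def test_budget_respected(self):
        act, g, es, direct, indirect, graph = toy_problem(seed=5)
        for limit in (1, 2, 4):
            cm = solve_combined(act, g, es, direct, indirect, graph, lam=0.5, limit=limit)
            assert len(cm.direct_selected) + len(cm.indirect_selected) <= limit

    def test_negative_lambda_rejected(self):
        act, g, es, direct, indirect, graph = toy_problem(seed=6)
        with pytest.raises(ValueError):
            solve_combined(act, g, es, direct, indirect, graph, lam=-1.0, limit=2)

    def test_unspanned_candidates_rejected(self):
        act, g, es, direct, indirect, graph = toy_problem(seed=7)
        with pytest.raises(ValueError, match="span"):
            solve_combined(act, g, es, direct + ["MISSING"], indirect, graph,
                           lam=0.0, limit=2)


class TestInterpolateCrossing:
    def test_hand_interpolated_crossing(self):
        # direct 8 -> 4, indirect 6 -> 12 over lambda 1 -> 3:
        # diff goes +2 -> -8, so the crossing sits 0.2 of the way in log space
        star = interpolate_crossing([1.0, 3.0], [8, 4], [6, 12])
        assert star == pytest.approx(10 ** (0.2 * np.log10(3)), rel=1e-12)

    def test_exact_grid_crossing(self):
        star = interpolate_crossing([0.1, 1.0, 10.0], [9, 7, 2], [3, 7, 12])
        assert star == 1.0

    def test_no_crossing_falls_back_to_closest(self):
        star = interpolate_crossing([0.1, 1.0, 10.0], [9, 8, 7], [1, 2, 4])
        assert star == 10.0


@pytest.fixture(scope="module")
def sweep_setup():
    expr, net, truth = generate(
        n_tfs=8, n_targets_per_tf=3, n_samples_A=45, n_samples_B=0,
        planted_direct_A={"TF01": 1.0, "TF02": 1.0}, planted_direct_B={},
        planted_indirect=["TF05", "TF06", "TF07", "TF08"],
        module_correlation=0.7, noise_sd=0.3, na_frac=0.0, seed=2,
    )
    x = preprocess_expression(expr, "TARGET")
    sweep = lambda_sweep(
        x, net, "TARGET",
        direct_candidates=[f"TF0{i}" for i in range(1, 5)],
        indirect_candidates=["TF05", "TF06", "TF07", "TF08"],
        grid=(0.01, 1.0, 100.0), sizes=[2, 3, 4], repeats=2, folds=3, seed=0,
    )
    return truth, sweep


class TestLambdaSweep:
    def test_counts_within_capacity(self, sweep_setup):
        _, sweep = sweep_setup
        assert sweep.capacity == 2 * 3 * (2 + 3 + 4)
        for d, i in zip(sweep.direct_counts, sweep.indirect_counts):
            assert d + i <= sweep.capacity

    def test_direct_dominates_small_lambda(self, sweep_setup):
        _, sweep = sweep_setup
        assert sweep.direct_counts[0] > sweep.indirect_counts[0]
        assert sweep.indirect_counts[-1] > sweep.direct_counts[-1]
        assert sweep.lambda_star is not None

    def test_models_respect_budget(self, sweep_setup):
        _, sweep = sweep_setup
        for lam, models in sweep.models.items():
            for m in models:
                assert len(m.direct_selected) + len(m.indirect_selected) <= m.limit


class TestExtractFinalModule:
    def mk(self, direct, indirect=(), perf=0.5):
        return CombinedModel(tuple(direct), tuple(indirect), 0.0, {}, 1.0, 5,
                             0.0, 0.0, 0.0, performance=perf)

    def test_unanimous_combination(self):
        models = [self.mk(("A", "B")) for _ in range(5)]
        d, i, support = extract_final_module(models)
        assert d == ("A", "B")
        assert support == 5

    def test_majority_combination_wins(self):
        models = [self.mk(("A", "B"))] * 3 + [self.mk(("A", "C"))] * 2
        d, _, support = extract_final_module(models)
        assert d == ("A", "B")
        assert support == 3

    def test_tie_broken_by_performance(self):
        models = [self.mk(("A", "B"), perf=0.2)] * 2 + [self.mk(("A", "C"), perf=0.9)] * 2
        d, _, _ = extract_final_module(models)
        assert d == ("A", "C")

    def test_indirect_majority_rule(self):
        models = [
            self.mk(("A",), ("X", "Y")),
            self.mk(("A",), ("X",)),
            self.mk(("A",), ("X", "Z")),
        ]
        _, indirect, _ = extract_final_module(models)
        assert indirect == ("X",)  # X in 3/3, Y and Z only in 1/3

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            extract_final_module([])


class TestPreselectIndirect:
    def test_threshold_is_inclusive_and_pool_formed(self):
        expr, net, truth = generate(
            n_tfs=8, n_targets_per_tf=3, n_samples_A=45, n_samples_B=0,
            planted_direct_A={"TF01": 1.0}, planted_direct_B={},
            planted_indirect=["TF05", "TF06", "TF07", "TF08"],
            module_correlation=0.7, noise_sd=0.3, na_frac=0.0, seed=4,
        )
        x = preprocess_expression(expr, "TARGET")
        mapping, pool, overlap = preselect_indirect(
            x, net, ["TF01"], threshold=0.2, sizes=[1, 2], repeats=2, folds=3, seed=0,
        )
        assert set(mapping) == {"TF01"}
        # module members regulate TF01's coding gene in the generated network
        assert set(pool) <= set(net.regulators_of("TF01"))
        assert pool  # someone passes the 20% bar on planted data

    def test_missing_coding_gene_skipped(self, make_expr):
        import pandas as pd

        rng = np.random.default_rng(0)
        x = make_expr(rng.normal(size=(2, 6)), genes=["T", "G1"])
        net_df = pd.DataFrame(
            [("R1", "G1", "s", 1.0)], columns=["regulator", "target", "source", "weight"]
        )
        from regmod import RegulatoryNetwork

        mapping, pool, _ = preselect_indirect(x, RegulatoryNetwork(net_df), ["ABSENT"])
        assert mapping == {"ABSENT": []}
        assert pool == []
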
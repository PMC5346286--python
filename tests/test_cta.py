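"""Classification-tree tests: endpoint assignment optimality, search
oracle equivalence, the minimum-endpoint-size constraint, prediction
routing and holdout scoring.

The independent enumerator below restricts itself to binary predictors,
where the candidate split (at 0.5) and its exact hypergeometric p-value
are reproduced here from first principles with scipy — fully decoupled
from the package's search code.
"""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from odacta.cta import (CTAModel, UndefinedMetricError, fit_cta, model_ess,
                        predict, predict_table, validate_holdout)
from odacta.oda import sidak_criterion


def _binary_split_p(y, flag):
    """Two-direction exact permutation p for a binary split (independent)."""
    P, N = int(y.sum()), int(len(y) - y.sum())
    m = int(flag.sum())
    lo, hi = max(0, m - N), min(m, P)
    A = np.arange(lo, hi + 1)
    ess = A / P + (N - m + A) / N - 1.0
    a_obs = int(y[flag].sum())
    obs = abs(a_obs / P + (N - m + a_obs) / N - 1.0)
    return float(hypergeom(P + N, P, m).pmf(A)[np.abs(ess) >= obs - 1e-12].sum())


def best_tree_ess_enumeration(tab, preds, max_depth, min_leaf, alpha_node):
    """Max model ESS over all trees of binary splits, assignments found
    by enumerating every class labeling of the endpoints."""
    y = tab["outcome"].to_numpy()
    P, N = int(y.sum()), int(len(y) - y.sum())

    def leaves_of(mask, depth):
        """All possible endpoint-partitions of the subjects in mask."""
        partitions = [[mask]]
        if depth >= max_depth:
            return partitions
        for p in preds:
            flag = tab[p].to_numpy() == 1
            right, left = mask & flag, mask & ~flag
            if right.sum() < min_leaf or left.sum() < min_leaf:
                continue
            if _binary_split_p(y[mask], flag[mask]) > alpha_node:
                continue
            for lp in leaves_of(left, depth + 1):
                for rp in leaves_of(right, depth + 1):
                    partitions.append(lp + rp)
        return partitions

    best = -np.inf
    root = np.ones(len(tab), dtype=bool)
    for partition in leaves_of(root, 0):
        k = len(partition)
        for classes in itertools.product([0, 1], repeat=k):
            sens = sum(y[m].sum() for m, cl in zip(partition, classes) if cl) / P
            spec = sum((~y.astype(bool))[m].sum()
                       for m, cl in zip(partition, classes) if not cl) / N
            best = max(best, 100.0 * (sens + spec - 1.0))
    return best


def _random_binary_instance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(60, 200))
    cols = {f"b{i}": (rng.random(n) < rng.uniform(0.25, 0.75)).astype(float)
            for i in range(3)}
    logit = -1.2 + 1.4 * cols["b0"] + rng.uniform(-1, 1) * cols["b1"]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    tab = pd.DataFrame(cols)
    tab["outcome"] = y
    return tab


class TestExhaustiveOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_matches_independent_enumerator(self, seed):
        tab = _random_binary_instance(seed)
        if tab.outcome.min() == tab.outcome.max():
            return
        preds = ["b0", "b1", "b2"]
        min_leaf = math.ceil(0.10 * len(tab) - 1e-9)
        alpha_node = sidak_criterion(0.05, 3)
        oracle = best_tree_ess_enumeration(tab, preds, 2, min_leaf, alpha_node)
        model = fit_cta(tab, preds, mode="exhaustive", max_depth=2, seed=seed)
        assert model.model_ess == pytest.approx(max(oracle, 0.0), abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_at_least_as_good_as_greedy(self, seed):
        tab = _random_binary_instance(seed + 100)
        if tab.outcome.min() == tab.outcome.max():
            return
        preds = ["b0", "b1", "b2"]
        g = fit_cta(tab, preds, mode="greedy", max_depth=2, seed=seed)
        e = fit_cta(tab, preds, mode="exhaustive", max_depth=2, seed=seed)
        assert e.model_ess >= g.model_ess - 1e-9


class TestEndpointAssignment:
    def test_assignment_maximizes_model_ess_over_all_labelings(self):
        """The a_i/P > b_i/N rule matches brute-force enumeration of all
        2^k endpoint labelings."""
        rng = np.random.default_rng(3)
        n = 400
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        y = ((x1 > 0) & (rng.random(n) < 0.6)).astype(int)
        tab = pd.DataFrame({"x1": x1, "x2": x2, "outcome": y})
        model = fit_cta(tab, ["x1", "x2"], mode="greedy", max_depth=2,
                        n_mc=300, seed=0)
        P = int(y.sum())
        N = n - P
        leaves = model.terminals()
        stats = [(e["cases"], e["n"] - e["cases"])
                 for e in model.endpoints]
        best = max(
            100.0 * (sum(a for (a, b), cl in zip(stats, cls) if cl) / P
                     + sum(b for (a, b), cl in zip(stats, cls) if not cl) / N
                     - 1.0)
            for cls in itertools.product([0, 1], repeat=len(leaves)))
        assert model.model_ess == pytest.approx(best, abs=1e-9)

    def test_tie_rate_equal_prevalence_predicted_negative(self):
        # single endpoint: a/P == b/N exactly -> negative by the tie rule
        tab = pd.DataFrame({"x": [1.0, 2, 3, 4], "z": [4.0, 3, 2, 1],
                            "outcome": [1, 0, 1, 0]})
        model = fit_cta(tab, ["x", "z"], alpha=0.05, seed=0)
        assert len(model.terminals()) == 1
        assert model.terminals()[0].endpoint_class == 0
        assert model.model_ess == 0.0


class TestConstraintsAndReduction:
    def test_every_terminal_respects_min_leaf_fraction(self):
        rng = np.random.default_rng(8)
        n = 1200
        x = rng.normal(size=n)
        z = rng.lognormal(size=n)
        y = ((x > 0.5) | (rng.random(n) < 0.1)).astype(int)
        tab = pd.DataFrame({"x": x, "z": z, "outcome": y})
        model = fit_cta(tab, ["x", "z"], min_leaf_frac=0.10, n_mc=300, seed=2)
        for leaf in model.terminals():
            assert leaf.node_n >= 0.10 * n

    def test_single_binary_split_reproduces_2x2_ess(self):
        """A one-split tree on a binary predictor is exactly the 2x2
        analysis: model ESS equals |ESS| of the contingency table."""
        from odacta.metrics import Counts2x2, metrics_from_counts
        rng = np.random.default_rng(4)
        n = 500
        flag = (rng.random(n) < 0.5).astype(float)
        y = ((flag == 1) & (rng.random(n) < 0.55)).astype(int)
        tab = pd.DataFrame({"flag": flag,
                            "dummy": rng.normal(size=n), "outcome": y})
        model = fit_cta(tab, ["flag", "dummy"], max_depth=1, n_mc=300, seed=0)
        assert not model.root.is_terminal
        assert model.root.attribute == "flag"
        a = int(y[flag == 1].sum()); b = int((flag == 1).sum() - a)
        c = int(y[flag == 0].sum()); d = int((flag == 0).sum() - c)
        table_ess = metrics_from_counts(Counts2x2(a, b, c, d)).ess
        assert model.model_ess == pytest.approx(abs(table_ess), abs=1e-9)

    def test_pure_noise_gives_root_only_model(self):
        rng = np.random.default_rng(9)
        n = 300
        tab = pd.DataFrame({"u": rng.normal(size=n), "v": rng.normal(size=n),
                            "outcome": (rng.random(n) < 0.3).astype(int)})
        model = fit_cta(tab, ["u", "v"], n_mc=300, seed=3)
        assert model.root.is_terminal
        assert model.model_ess == 0.0


class TestPredictAndValidate:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(12)
        n = 800
        dur = rng.lognormal(5, 1, size=n)
        flag = (rng.random(n) < 0.4).astype(float)
        risk = np.where(flag == 1, 0.05, np.where(dur > 200, 0.5, 0.08))
        y = (rng.random(n) < risk).astype(int)
        tab = pd.DataFrame({"duration": dur, "flag": flag, "outcome": y})
        model = fit_cta(tab, ["duration", "flag"], n_mc=300, seed=1)
        return model, tab, rng

    def test_boundary_value_routes_to_le_side(self, fitted):
        model, tab, _ = fitted
        node = model.root
        assert not node.is_terminal
        row = {node.attribute: node.cutpoint}
        for other in model.predictors:
            row.setdefault(other, 0.0)
        cls, endpoint = predict(model, row)
        # the <= branch is 'left' for '>' splits, 'right' for '<=' splits
        le_child = model.root.left if node.direction == ">" else model.root.right
        def ids_under(nd):
            if nd.is_terminal:
                return {nd.node_id}
            return ids_under(nd.left) | ids_under(nd.right)
        assert endpoint in ids_under(le_child)

    def test_every_row_reaches_exactly_one_endpoint(self, fitted):
        model, tab, _ = fitted
        preds_tab = predict_table(model, tab)
        assert len(preds_tab) == len(tab)
        per_row = [predict(model, row)[0]
                   for _, row in tab.head(50).iterrows()]
        assert per_row == preds_tab[:50].tolist()

    def test_missing_predictor_raises(self, fitted):
        model, _, _ = fitted
        with pytest.raises(UndefinedMetricError):
            predict(model, {p: float("nan") for p in model.predictors})

    def test_holdout_from_same_distribution_close_to_training(self, fitted):
        model, tab, rng = fitted
        n = 3000
        dur = rng.lognormal(5, 1, size=n)
        flag = (rng.random(n) < 0.4).astype(float)
        risk = np.where(flag == 1, 0.05, np.where(dur > 200, 0.5, 0.08))
        y = (rng.random(n) < risk).astype(int)
        holdout = pd.DataFrame({"duration": dur, "flag": flag, "outcome": y})
        v = validate_holdout(model, holdout)
        assert abs(v["ess"] - model.model_ess) < 15.0
        assert v["n"] == n

    def test_null_holdout_ess_near_zero(self, fitted):
        model, _, rng = fitted
        n = 3000
        holdout = pd.DataFrame({
            "duration": rng.lognormal(5, 1, size=n),
            "flag": (rng.random(n) < 0.4).astype(float),
            "outcome": (rng.random(n) < 0.2).astype(int)})
        v = validate_holdout(model, holdout)
        assert abs(v["ess"]) < 8.0

    def test_training_table_flagged_and_equal(self, fitted):
        model, tab, _ = fitted
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            v = validate_holdout(model, tab)
        assert any("holdout" in str(w.message) for w in caught)
        assert v["ess"] == pytest.approx(model.model_ess)

    def test_recomputed_model_ess_matches_stored(self, fitted):
        model, tab, _ = fitted
        assert model_ess(model, tab) == pytest.approx(model.model_ess)

    def test_shuffled_labels_score_near_zero(self, fitted):
        model, tab, _ = fitted
        shuffled = tab.copy()
        shuffled["outcome"] = np.random.default_rng(0).permutation(
            tab["outcome"].to_numpy())
        assert abs(model_ess(model, shuffled)) < 12.0
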
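"""Hierarchically optimal classification tree analysis (CTA).

CTA chains ODA analyses down the branches of a binary tree: at every
node the ESS-maximizing cutpoint is re-optimized for the subjects
reaching that node, a split is kept only if it passes the Sidak-adjusted
permutation criterion over the node's predictor pool, and every terminal
endpoint is constrained a priori to hold at least ``min_leaf_frac``
(default 10%) of the overall cohort — a guard against overfitting and
underpowered strata.

Endpoint classes are assigned to maximize the overall model ESS, which
decomposes over endpoints: endpoint *i* with ``a_i`` cases and ``b_i``
non-cases (out of cohort totals ``P`` and ``N``) contributes ``a_i/P``
to sensitivity if predicted positive and ``b_i/N`` to specificity if
predicted negative, so the globally optimal assignment is positive iff
``a_i/P > b_i/N`` (ties predicted negative).

Two search modes: ``greedy`` recursively takes the best significant
node-local split; ``exhaustive`` enumerates every tree buildable from
the per-(node, predictor) ODA-optimal candidate splits up to
``max_depth`` and returns the one maximizing model ESS — guaranteed
optimal within that enumerated family (ties: fewer endpoints, then
shallower, then lexicographic predictor order).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import Counts2x2, metrics_from_counts
from .oda import (NoModelError, binary_attribute_p, optimal_cutpoint,
                  permutation_p, sidak_criterion)


class CapacityError(RuntimeError):
    """Exhaustive enumeration exceeded the configured complexity budget."""


class UndefinedMetricError(ValueError):
    pass


@dataclass
class CTANode:
    node_id: int
    node_n: int
    node_cases: int
    depth: int
    # split fields (None for terminals)
    attribute: str | None = None
    direction: str | None = None
    cutpoint: float | None = None
    p_value: float | None = None
    left: "CTANode | None" = None    # condition false
    right: "CTANode | None" = None   # condition true
    endpoint_class: int | None = None

    @property
    def is_terminal(self) -> bool:
        return self.attribute is None

    @property
    def node_positive_rate(self) -> float:
        return self.node_cases / self.node_n if self.node_n else math.nan

    def condition_str(self) -> str:
        if self.is_terminal:
            return "<terminal>"
        return f"{self.attribute} {self.direction} {self.cutpoint:g}"


@dataclass
class CTAModel:
    root: CTANode
    model_ess: float
    endpoints: list[dict]
    alpha: float
    min_leaf_frac: float
    mode: str
    seed: int
    predictors: list[str]
    n_train: int
    cases_train: int

    def terminals(self) -> list[CTANode]:
        out = []
        def walk(node):
            if node.is_terminal:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)
        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# fitting

def _condition_true(values: np.ndarray, direction: str, cutpoint: float) -> np.ndarray:
    """Effect-positive side of a split; values exactly at the cutpoint go
    to the <= side (half-open rule)."""
    gt = values > cutpoint
    return gt if direction == ">" else ~gt


def _candidate_splits(table, predictors, outcome, mask, min_leaf_n,
                      alpha_node, n_mc, seed, exhaustive_limit):
    """Significant, size-feasible ODA-optimal split per predictor at a node."""
    y = table[outcome].to_numpy()[mask]
    cands = []
    for i, name in enumerate(predictors):
        x = table[name].to_numpy(dtype=float)[mask]
        try:
            res = optimal_cutpoint(x, y, attribute=name, min_side=min_leaf_n)
        except NoModelError:
            continue
        if res.is_binary:
            res = replace(res, p_value=binary_attribute_p(res.counts),
                          p_method="hypergeometric")
        else:
            sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
            res = permutation_p(res, x, y, n_mc=n_mc, seed=sub_seed,
                                exhaustive_limit=exhaustive_limit,
                                min_side=min_leaf_n)
        if res.p_value <= alpha_node:
            cands.append(res)
    return cands


def fit_cta(
    table: pd.DataFrame,
    predictors: list[str],
    *,
    outcome: str = "outcome",
    alpha: float = 0.05,
    min_leaf_frac: float = 0.10,
    max_depth: int = 4,
    mode: str = "greedy",
    n_mc: int = 999,
    seed: int = 0,
    exhaustive_limit: int = 0,
    tree_budget: int = 100_000,
) -> CTAModel:
    """Fit a classification tree by chained ODA splits.

    ``exhaustive_limit`` is forwarded to the permutation p-value (0 means
    always Monte-Carlo with ``n_mc`` draws, the fast default for large
    nodes).  ``tree_budget`` caps the number of trees the exhaustive mode
    may enumerate; exceeding it raises :class:`CapacityError` rather than
    silently falling back.
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    y_all = table[outcome].to_numpy()
    if y_all.min() == y_all.max():
        raise ValueError("outcome has a single class")
    root_n = len(table)
    min_leaf_n = max(1, math.ceil(min_leaf_frac * root_n - 1e-9))
    alpha_node = sidak_criterion(alpha, len(predictors))
    P, N = int(y_all.sum()), int(root_n - y_all.sum())

    counter = [0]

    def make_node(mask, depth):
        counter[0] += 1
        return CTANode(node_id=counter[0], node_n=int(mask.sum()),
                       node_cases=int(y_all[mask].sum()), depth=depth)

    def grow_greedy(mask, depth):
        node = make_node(mask, depth)
        nn = node.node_n
        if depth >= max_depth or nn < 2 * min_leaf_n \
                or node.node_cases in (0, nn):
            return node
        cands = _candidate_splits(table, predictors, outcome, mask, min_leaf_n,
                                  alpha_node, n_mc, seed + depth, exhaustive_limit)
        if not cands:
            return node
        best = max(cands, key=lambda r: (r.ess, -predictors.index(r.attribute)))
        x = table[best.attribute].to_numpy(dtype=float)
        cond = _condition_true(x, best.direction, best.cutpoint)
        node.attribute, node.direction = best.attribute, best.direction
        node.cutpoint, node.p_value = best.cutpoint, best.p_value
        node.right = grow_greedy(mask & cond, depth + 1)
        node.left = grow_greedy(mask & ~cond, depth + 1)
        return node

    if mode == "greedy":
        root = grow_greedy(np.ones(root_n, dtype=bool), 0)
    elif mode == "exhaustive":
        root = _exhaustive_search(table, predictors, outcome, y_all, min_leaf_n,
                                  alpha_node, max_depth, n_mc, seed,
                                  exhaustive_limit, tree_budget, P, N, counter)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    model = CTAModel(root=root, model_ess=0.0, endpoints=[], alpha=alpha,
                     min_leaf_frac=min_leaf_frac, mode=mode, seed=seed,
                     predictors=list(predictors), n_train=root_n, cases_train=P)
    assign_endpoint_classes(model, table, outcome=outcome)
    return model


def _tree_ess_and_size(tree_spec, P, N):
    """tree_spec is a nested tuple: ("leaf", a, b) or
    ("split", attr, dirn, cut, p, left, right)."""
    def walk(t):
        if t[0] == "leaf":
            _, a, b = t
            contrib = max(a / P, b / N)
            return contrib, 1, 0
        _, _, _, _, _, lt, rt = t
        cl, nl, dl = walk(lt)
        cr, nr, dr = walk(rt)
        return cl + cr, nl + nr, 1 + max(dl, dr)
    contrib, n_leaves, depth = walk(tree_spec)
    return 100.0 * (contrib - 1.0), n_leaves, depth


def _exhaustive_search(table, predictors, outcome, y_all, min_leaf_n,
                       alpha_node, max_depth, n_mc, seed, exhaustive_limit,
                       tree_budget, P, N, counter):
    """Enumerate all trees over per-node candidate splits; pick max model ESS."""
    xcols = {p: table[p].to_numpy(dtype=float) for p in predictors}
    budget = [0]

    def enum(mask, depth):
        a = int(y_all[mask].sum())
        b = int(mask.sum()) - a
        leaves = [("leaf", a, b)]
        budget[0] += 1
        if budget[0] > tree_budget:
            raise CapacityError(f"exhaustive search exceeded {tree_budget} subtrees")
        if depth >= max_depth or mask.sum() < 2 * min_leaf_n or a == 0 or b == 0:
            return leaves
        cands = _candidate_splits(table, predictors, outcome, mask, min_leaf_n,
                                  alpha_node, n_mc, seed + depth, exhaustive_limit)
        out = list(leaves)
        for res in cands:
            cond = _condition_true(xcols[res.attribute], res.direction, res.cutpoint)
            for lt in enum(mask & ~cond, depth + 1):
                for rt in enum(mask & cond, depth + 1):
                    out.append(("split", res.attribute, res.direction,
                                res.cutpoint, res.p_value, lt, rt))
                    if len(out) > tree_budget:
                        raise CapacityError(
                            f"exhaustive search exceeded {tree_budget} trees")
        return out

    trees = enum(np.ones(len(table), dtype=bool), 0)
    scored = []
    for t in trees:
        ess, n_leaves, depth = _tree_ess_and_size(t, P, N)
        scored.append((-round(ess, 9), n_leaves, depth, _tree_repr(t), t))
    scored.sort(key=lambda s: s[:4])
    best = scored[0][4]
    return _materialize(best, np.ones(len(table), dtype=bool), 0, y_all, xcols, counter)


def _tree_repr(t):
    if t[0] == "leaf":
        return "L"
    return f"({t[1]}{t[2]}{t[3]:g}|{_tree_repr(t[5])}|{_tree_repr(t[6])})"


def _materialize(t, mask, depth, y_all, xcols, counter):
    counter[0] += 1
    node = CTANode(node_id=counter[0], node_n=int(mask.sum()),
                   node_cases=int(y_all[mask].sum()), depth=depth)
    if t[0] == "split":
        _, attr, dirn, cut, p, lt, rt = t
        node.attribute, node.direction, node.cutpoint, node.p_value = attr, dirn, cut, p
        cond = _condition_true(xcols[attr], dirn, cut)
        node.right = _materialize(rt, mask & cond, depth + 1, y_all, xcols, counter)
        node.left = _materialize(lt, mask & ~cond, depth + 1, y_all, xcols, counter)
    return node


# ---------------------------------------------------------------------------
# endpoint assignment / model ESS / prediction

def _route_mask(model: CTAModel, table: pd.DataFrame):
    """Terminal endpoint id per row of table."""
    n = len(table)
    ids = np.zeros(n, dtype=np.int64)
    def walk(node, mask):
        if node.is_terminal:
            ids[mask] = node.node_id
            return
        x = table[node.attribute].to_numpy(dtype=float)
        if np.isnan(x[mask]).any():
            raise UndefinedMetricError(
                f"missing values for predictor {node.attribute!r} during routing")
        cond = _condition_true(x, node.direction, node.cutpoint)
        walk(node.right, mask & cond)
        walk(node.left, mask & ~cond)
    walk(model.root, np.ones(n, dtype=bool))
    return ids


def assign_endpoint_classes(model: CTAModel, table: pd.DataFrame,
                            *, outcome: str = "outcome") -> CTAModel:
    """Assign each terminal the class that maximizes overall model ESS.

    Endpoint *i* is predicted positive iff ``a_i/P > b_i/N`` (ties
    negative); the model ESS follows from the decomposition described in
    the module docstring.  Updates the model in place and returns it.
    """
    y = table[outcome].to_numpy()
    P, N = int(y.sum()), int(len(y) - y.sum())
    if P == 0 or N == 0:
        raise UndefinedMetricError("training table lacks an outcome class")
    ids = _route_mask(model, table)
    endpoints = []
    for leaf in model.terminals():
        sel = ids == leaf.node_id
        a, b = int(y[sel].sum()), int(sel.sum() - y[sel].sum())
        leaf.endpoint_class = int(a / P > b / N)
        endpoints.append({
            "endpoint_id": leaf.node_id,
            "path": _path_to(model.root, leaf.node_id),
            "n": int(sel.sum()),
            "cases": a,
            "positive_rate": a / sel.sum() if sel.sum() else math.nan,
            "predicted_class": leaf.endpoint_class,
        })
    model.endpoints = endpoints
    model.model_ess = model_ess(model, table, outcome=outcome)
    return model


def _path_to(root: CTANode, node_id: int) -> str:
    def walk(node, path):
        if node.node_id == node_id:
            return path or "(root)"
        if node.is_terminal:
            return None
        cond = node.condition_str()
        sep = " & " if path else ""
        return (walk(node.right, f"{path}{sep}{cond}")
                or walk(node.left, f"{path}{sep}not({cond})"))
    return walk(root, "")


def model_ess(model: CTAModel, table: pd.DataFrame, *,
              outcome: str = "outcome") -> float:
    """ESS (sens + spec - 100) of the tree's predictions on a table."""
    y = table[outcome].to_numpy()
    P, N = int(y.sum()), int(len(y) - y.sum())
    if P == 0 or N == 0:
        raise UndefinedMetricError("table lacks an outcome class")
    pred = predict_table(model, table)
    sens = 100.0 * (pred[y == 1] == 1).sum() / P
    spec = 100.0 * (pred[y == 0] == 0).sum() / N
    return float(sens + spec - 100.0)


def predict_table(model: CTAModel, table: pd.DataFrame) -> np.ndarray:
    ids = _route_mask(model, table)
    cls = {leaf.node_id: leaf.endpoint_class for leaf in model.terminals()}
    return np.array([cls[i] for i in ids], dtype=np.int64)


def predict(model: CTAModel, row) -> tuple[int, int]:
    """Route one row (mapping or Series) to (predicted class, endpoint id).

    A value exactly at a cutpoint follows the <= side.  Missing
    predictors raise :class:`UndefinedMetricError`.
    """
    node = model.root
    while not node.is_terminal:
        v = row[node.attribute]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise UndefinedMetricError(f"missing predictor {node.attribute!r}")
        cond = (v > node.cutpoint) if node.direction == ">" else not (v > node.cutpoint)
        node = node.right if cond else node.left
    return node.endpoint_class, node.node_id


def validate_holdout(model: CTAModel, holdout_table: pd.DataFrame, *,
                     outcome: str = "outcome") -> dict:
    """Score the frozen model on a holdout table (no refitting).

    Returns model ESS plus the full 2x2 metrics of predicted vs observed
    outcome.  Passing the training table itself is flagged with a warning
    (the result then equals the training model ESS).
    """
    pred = predict_table(model, holdout_table)
    y = holdout_table[outcome].to_numpy()
    if len(holdout_table) == model.n_train and int(y.sum()) == model.cases_train:
        warnings.warn("holdout table looks identical to training data")
    a = int(((pred == 1) & (y == 1)).sum())
    b = int(((pred == 1) & (y == 0)).sum())
    c = int(((pred == 0) & (y == 1)).sum())
    d = int(((pred == 0) & (y == 0)).sum())
    t = Counts2x2(a, b, c, d)
    m = metrics_from_counts(t)
    if m.ess is None:
        raise UndefinedMetricError("holdout table lacks an outcome class")
    return {"counts": t, "metrics": m, "ess": m.ess, "n": t.n}


# ---------------------------------------------------------------------------
# serialization

def tree_to_dict(model: CTAModel) -> dict:
    def node_dict(node):
        d = {"node_id": node.node_id, "n": node.node_n,
             "cases": node.node_cases,
             "positive_rate": node.node_positive_rate}
        if node.is_terminal:
            d["endpoint_class"] = node.endpoint_class
        else:
            d.update(attribute=node.attribute, direction=node.direction,
                     cutpoint=node.cutpoint, p_value=node.p_value,
                     left=node_dict(node.left), right=node_dict(node.right))
        return d
    return {
        "model_ess": model.model_ess,
        "alpha": model.alpha,
        "min_leaf_frac": model.min_leaf_frac,
        "mode": model.mode,
        "seed": model.seed,
        "predictors": model.predictors,
        "n_train": model.n_train,
        "cases_train": model.cases_train,
        "endpoints": model.endpoints,
        "root": node_dict(model.root),
    }


def tree_to_json(model: CTAModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(model), fh, indent=2)


def render_tree(model: CTAModel) -> str:
    """Plain-text rendering of the tree, one node per line."""
    lines = [f"model ESS {model.model_ess:.1f}%  (n={model.n_train}, "
             f"cases={model.cases_train})"]
    def walk(node, indent, label):
        rate = 100.0 * node.node_positive_rate
        if node.is_terminal:
            cls = "+" if node.endpoint_class else "-"
            lines.append(f"{indent}{label}[endpoint {node.node_id}] n={node.node_n} "
                         f"rate={rate:.2f}% predicted {cls}")
        else:
            lines.append(f"{indent}{label}{node.condition_str()} "
                         f"(n={node.node_n}, rate={rate:.2f}%, p={node.p_value:.4g})")
            walk(node.right, indent + "  ", "yes: ")
            walk(node.left, indent + "  ", "no:  ")
    walk(model.root, "", "")
    return "\n".join(lines)
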
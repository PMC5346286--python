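"""Univariable optimal discriminant analysis (ODA).

ODA dichotomizes an ordered attribute at the cutpoint that explicitly
maximizes classification accuracy as indexed by the effect strength for
sensitivity (ESS = sensitivity + specificity - 100, chance 0 / maximum
100).  Candidate cutpoints are the midpoints between adjacent distinct
observed values, searched exhaustively in both directions (effect-positive
side ``>`` or ``<=`` the cutpoint), which yields the half-integer
cutpoints characteristic of the method (e.g. ">90.5 days").

Because no distributional assumptions are made, statistical significance
comes from the permutation distribution of the *maximized* ESS: outcome
labels are permuted, the cutpoint is re-optimized for every permutation,
and the p-value is the fraction of permutations whose maximal ESS reaches
the observed one.  The enumeration is exact when the number of distinct
labelings is small, and Monte-Carlo (with the +1/(n+1) correction) above
that.  For a fixed binary attribute the permutation distribution is
hypergeometric and the p-value is computed exactly in closed form.

Multiple-comparison control uses the Sidak criterion
``1 - (1 - alpha)**(1/k)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .metrics import BinaryMetrics, Counts2x2, metrics_from_counts

#: enumerate all labelings exactly when C(n, n_cases) is at most this
DEFAULT_EXHAUSTIVE_LIMIT = 200_000
#: Monte-Carlo permutation count when enumeration is infeasible
DEFAULT_N_MC = 25_000


class NoModelError(ValueError):
    """Constant attribute or single-class outcome: no cutpoint model exists."""


@dataclass(frozen=True)
class CutpointResult:
    """An ODA solution for one attribute.

    ``direction`` is the effect-positive side: ``">"`` means subjects with
    value strictly above the cutpoint are predicted to have the effect,
    ``"<="`` the reverse.  ``cutpoint`` is always the midpoint between two
    adjacent distinct observed values; for a binary 0/1 attribute it is
    0.5 and ``is_binary`` is set (screens print such rows without a
    cutpoint).  ``p_method`` is one of ``exhaustive``, ``monte_carlo``,
    ``hypergeometric`` (or ``None`` before a p-value is attached).
    """

    attribute: str
    direction: str
    cutpoint: float
    is_binary: bool
    counts: Counts2x2
    metrics: BinaryMetrics
    n_used: int
    n_missing: int
    p_value: float | None = None
    p_method: str | None = None
    n_permutations: int | None = None
    seed: int | None = None

    @property
    def ess(self) -> float:
        return self.metrics.ess


@dataclass(frozen=True)
class _SortedInstance:
    """Pre-sorted attribute/outcome pair with per-distinct-value cumsums."""

    y_sorted: np.ndarray          # labels in ascending-value order
    midpoints: np.ndarray         # candidate cutpoints, len k-1
    end_idx: np.ndarray           # last sorted position of each distinct value
    total_le: np.ndarray          # subjects <= each candidate cut, len k-1
    n_cases: int
    n_controls: int


def _prepare(values: np.ndarray, outcome: np.ndarray) -> _SortedInstance:
    order = np.argsort(values, kind="stable")
    xs = values[order]
    ys = outcome[order].astype(np.int64)
    distinct, first_idx = np.unique(xs, return_index=True)
    if distinct.size < 2:
        raise NoModelError("attribute is constant; no cutpoint exists")
    end_idx = np.r_[first_idx[1:] - 1, xs.size - 1]
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    total_le = end_idx[:-1] + 1
    n_cases = int(ys.sum())
    n_controls = ys.size - n_cases
    if n_cases == 0 or n_controls == 0:
        raise NoModelError("outcome has a single class; no discrimination possible")
    return _SortedInstance(ys, midpoints, end_idx, total_le, n_cases, n_controls)


def _clean(values, outcome) -> tuple[np.ndarray, np.ndarray, int]:
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome)
    if values.shape != outcome.shape:
        raise ValueError("values and outcome must have equal length")
    keep = ~np.isnan(values)
    n_missing = int((~keep).sum())
    return values[keep], outcome[keep].astype(np.int64), n_missing


def optimal_cutpoint(
    values,
    outcome,
    *,
    attribute: str = "x",
    min_side: int = 1,
) -> CutpointResult:
    """Exhaustive ESS-maximizing cutpoint over all midpoints and directions.

    Missing values (NaN) are excluded pairwise and counted in
    ``n_missing``.  ``min_side`` constrains both sides of the cut to hold
    at least that many subjects (used by the tree fitter's endpoint-size
    constraint).  Ties in ESS are broken by (1) larger sensitivity on the
    smaller outcome class, then (2) smaller cutpoint, then direction
    ``">"`` before ``"<="`` — fully deterministic.
    """
    vals, yy, n_missing = _clean(values, outcome)
    inst = _prepare(vals, yy)
    P, N = inst.n_cases, inst.n_controls

    cases_le = np.cumsum(inst.y_sorted)[inst.end_idx[:-1]]
    ctrl_le = inst.total_le - cases_le
    n = P + N
    feasible = (inst.total_le >= min_side) & (n - inst.total_le >= min_side)
    if not feasible.any():
        raise NoModelError("no cutpoint satisfies the side-size constraint")

    # direction '>': sens = (P - cases_le)/P, spec = ctrl_le/N
    ess_gt = 100.0 * ((P - cases_le) / P + ctrl_le / N - 1.0)

    best = None  # (ess, small_sens, -cutpoint, gt_first) maximized lexicographically
    small_is_cases = P <= N
    for direction, ess_vec in (( ">", ess_gt), ("<=", -ess_gt)):
        e = np.where(feasible, ess_vec, -np.inf)
        i = int(np.argmax(e))
        top = e[i]
        # scan ties explicitly (exact rational ESS values, tolerance for fp)
        tie_idx = np.nonzero(e >= top - 1e-9)[0]
        for j in tie_idx:
            if direction == ">":
                sens_cases = (P - cases_le[j]) / P
                sens_ctrls = ctrl_le[j] / N
            else:
                sens_cases = cases_le[j] / P
                sens_ctrls = (N - ctrl_le[j]) / N
            small_sens = sens_cases if small_is_cases else sens_ctrls
            key = (round(float(e[j]), 9), round(small_sens, 12),
                   -inst.midpoints[j], direction == ">")
            if best is None or key > best[0]:
                best = (key, direction, int(j))

    _, direction, j = best
    cut = float(inst.midpoints[j])
    if direction == ">":
        a, c = P - int(cases_le[j]), int(cases_le[j])
        b, d = N - int(ctrl_le[j]), int(ctrl_le[j])
    else:
        a, c = int(cases_le[j]), P - int(cases_le[j])
        b, d = int(ctrl_le[j]), N - int(ctrl_le[j])
    counts = Counts2x2(a, b, c, d)
    uniq = np.unique(vals)
    is_binary = uniq.size == 2 and set(uniq.tolist()) <= {0.0, 1.0}
    return CutpointResult(
        attribute=attribute, direction=direction, cutpoint=cut,
        is_binary=is_binary, counts=counts, metrics=metrics_from_counts(counts),
        n_used=int(vals.size), n_missing=n_missing,
    )


def _max_abs_ess_rows(labels: np.ndarray, inst: _SortedInstance,
                      feasible: np.ndarray | None = None) -> np.ndarray:
    """Maximal |ESS| over all cuts and both directions, per row of labels.

    ``labels`` has shape (B, n) with each row a labeling in sorted-value
    order.  Vectorized over rows.
    """
    P, N = inst.n_cases, inst.n_controls
    cum = np.cumsum(labels, axis=1)
    cases_le = cum[:, inst.end_idx[:-1]]
    ctrl_le = inst.total_le[None, :] - cases_le
    ess_gt = 100.0 * ((P - cases_le) / P + ctrl_le / N - 1.0)
    if feasible is not None:
        ess_gt = np.where(feasible[None, :], ess_gt, 0.0)
    return np.abs(ess_gt).max(axis=1)


def _signed_ess_at_cut(labels: np.ndarray, inst: _SortedInstance,
                       cut_index: int, direction: str) -> np.ndarray:
    P, N = inst.n_cases, inst.n_controls
    cum = np.cumsum(labels, axis=1)
    cases_le = cum[:, inst.end_idx[:-1][cut_index]]
    ctrl_le = inst.total_le[cut_index] - cases_le
    ess_gt = 100.0 * ((P - cases_le) / P + ctrl_le / N - 1.0)
    return ess_gt if direction == ">" else -ess_gt


def permutation_p(
    result: CutpointResult,
    values,
    outcome,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
    *,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    null: str = "max_ess",
    min_side: int = 1,
    chunk: int = 4096,
) -> CutpointResult:
    """Permutation p-value for an ODA cutpoint result.

    The null distribution re-optimizes the cutpoint (both directions) for
    every relabeling (``null="max_ess"``, the conservative exact-ODA
    choice); ``null="fixed_cut"`` instead scores each relabeling at the
    observed cutpoint and direction.  All ``C(n, n_cases)`` distinct
    labelings are enumerated when that count is at most
    ``exhaustive_limit``; otherwise ``n_mc`` Monte-Carlo permutations are
    drawn with ``seed`` and the p-value gets the +1/(n+1) correction.

    Returns a copy of ``result`` with p-value fields attached.
    """
    if n_mc < 100:
        warnings.warn("n_mc < 100 gives a very coarse Monte-Carlo p-value")
    vals, yy, _ = _clean(values, outcome)
    inst = _prepare(vals, yy)
    n = vals.size
    feasible = (inst.total_le >= min_side) & (n - inst.total_le >= min_side)

    if null == "max_ess":
        observed = abs(result.ess)
        score = lambda rows: _max_abs_ess_rows(rows, inst, feasible)
    elif null == "fixed_cut":
        observed = result.ess
        cut_index = int(np.searchsorted(inst.midpoints, result.cutpoint))
        score = lambda rows: _signed_ess_at_cut(rows, inst, cut_index, result.direction)
    else:
        raise ValueError(f"unknown null {null!r}")

    n_labelings = comb(n, inst.n_cases)
    if n_labelings <= exhaustive_limit:
        hits = total = 0
        positions = range(n)
        it = itertools.combinations(positions, inst.n_cases)
        while True:
            batch = list(itertools.islice(it, chunk))
            if not batch:
                break
            rows = np.zeros((len(batch), n), dtype=np.int64)
            rows[np.arange(len(batch))[:, None], np.array(batch)] = 1
            hits += int((score(rows) >= observed - 1e-9).sum())
            total += len(batch)
        p = hits / total
        method, nperm = "exhaustive", total
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        hits = 0
        base = np.tile(inst.y_sorted, (min(chunk, n_mc), 1))
        done = 0
        while done < n_mc:
            b = min(chunk, n_mc - done)
            rows = rng.permuted(base[:b], axis=1)
            hits += int((score(rows) >= observed - 1e-9).sum())
            done += b
        p = (hits + 1) / (n_mc + 1)
        method, nperm = "monte_carlo", n_mc
    return replace(result, p_value=float(p), p_method=method,
                   n_permutations=nperm, seed=seed)


def binary_attribute_p(t: Counts2x2) -> float:
    """Exact permutation p-value for a fixed binary predictor.

    Permuting outcome labels with the predictor margin fixed makes the
    ``a`` cell hypergeometric; the p-value is the tail probability of
    tables whose |ESS| (both directions, matching the two-direction
    optimization) reaches the observed |ESS|.
    """
    P, N = t.cases, t.noncases
    m = t.positives
    if P == 0 or N == 0:
        raise NoModelError("outcome has a single class")
    lo, hi = max(0, m - N), min(m, P)
    A = np.arange(lo, hi + 1)
    ess = 100.0 * (A / P + (N - m + A) / N - 1.0)
    obs = abs(100.0 * (t.a / P + (N - m + t.a) / N - 1.0))
    pmf = hypergeom(P + N, P, m).pmf(A)
    return float(pmf[np.abs(ess) >= obs - 1e-9].sum())


def sidak_criterion(alpha: float, k: int) -> float:
    """Sidak-adjusted per-comparison threshold ``1 - (1-alpha)**(1/k)``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


def univariable_screen(
    table: pd.DataFrame,
    predictors: list[str],
    *,
    outcome: str = "outcome",
    alpha: float = 0.05,
    mode: str = "generalized",
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> list[CutpointResult]:
    """Screen predictors one at a time, ranked by descending ESS.

    Each ordered predictor gets an ESS-maximizing cutpoint with a
    permutation p-value; binary 0/1 predictors get the exact
    hypergeometric p-value.  ``mode="experimentwise"`` keeps results
    passing the Sidak criterion over the ``k`` screened predictors;
    ``mode="generalized"`` keeps per-comparison p <= alpha.  Predictors
    admitting no model (constant, or single-class outcome after pairwise
    deletion) are skipped.
    """
    if len(predictors) < 2:
        raise ValueError("screen requires at least two predictors")
    if mode == "experimentwise":
        threshold = sidak_criterion(alpha, len(predictors))
    elif mode == "generalized":
        threshold = alpha
    else:
        raise ValueError(f"unknown mode {mode!r}")

    y = table[outcome].to_numpy()
    results: list[CutpointResult] = []
    for i, name in enumerate(predictors):
        x = table[name].to_numpy(dtype=float)
        try:
            res = optimal_cutpoint(x, y, attribute=name)
        except NoModelError:
            continue
        if res.is_binary:
            res = replace(res, p_value=binary_attribute_p(res.counts),
                          p_method="hypergeometric")
        else:
            sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
            res = permutation_p(res, x, y, n_mc=n_mc, seed=sub_seed,
                                exhaustive_limit=exhaustive_limit)
        if res.p_value <= threshold:
            results.append(res)
    results.sort(key=lambda r: (-r.ess, r.attribute))
    return results


def screen_frame(results: list[CutpointResult]) -> pd.DataFrame:
    """Screen results as a table in the conventional printed layout."""
    rows = []
    for r in results:
        m = r.metrics
        rows.append({
            "attribute": r.attribute,
            "direction": r.direction,
            "cutpoint": None if r.is_binary else r.cutpoint,
            "a": r.counts.a, "b": r.counts.b, "c": r.counts.c, "d": r.counts.d,
            "nnh": m.nnh, "risk_ratio": m.risk_ratio,
            "specificity": m.specificity, "sensitivity": m.sensitivity,
            "npv": m.npv, "ppv": m.ppv, "ess": m.ess,
            "p_value": r.p_value, "p_method": r.p_method,
            "n_used": r.n_used, "n_missing": r.n_missing,
        })
    return pd.DataFrame(rows)
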
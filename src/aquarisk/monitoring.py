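"""Monitoring-scheme evaluation and optimal allocation of sampling batches.

A scheme assigns integer batch counts ``x[i, j]`` at each monitoring
province *j* to every source stream *i*.  With per-flow prevalence *a*
and assay sensitivity *s*, a source is detected with probability

    d(a, x) = 1 - (1 - s * a) ** x

(the complement of drawing x consecutive clean samples).  The scheme's
effectiveness at *j* is the joint probability of catching every
contaminated source simultaneously, ``h = prod_i d(a_i, x_i)``; the
product runs over sources with positive prevalence, since a source that
never fails contributes nothing to detect.

The allocation problem maximizes ``h`` per province subject to the batch
budget, a floor on the post-removal trade volume, a cap on the residual
hazard index, and integrality.  The problems are separable across
provinces; the log objective ``sum_i log(1 - q_i ** x_i)`` is separable
concave in the integer counts, so greedy marginal allocation is exact
for the budget-only problem.  Side constraints are handled by screening
the greedy optimum and, when active, by an exact state-space dynamic
program (small instances) or a greedy repair heuristic (large ones).
An exhaustive enumeration oracle is provided for verification.
"""
from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .flows import ContaminationMatrix
from .food_loss import TradeVolumeTable, compute_trade_volume
from .health_risk import RiskTable

logger = logging.getLogger(__name__)

#: Absolute tolerance for probability constraints (residual HI, h cap).
PROB_TOL = 1e-9
#: Absolute tolerance for volume constraints, tons.
VOLUME_TOL = 1e-6

ORACLE_MAX_SOURCES = 4
ORACLE_MAX_BUDGET = 15
DP_MAX_STATES = 500_000


def detection_probability(a, x, s: float = 1.0):
    """Probability that x batches catch a source with prevalence a.

    Returns ``1 - (1 - s*a)**x``; scalar or elementwise on arrays.
    """
    a_arr = np.asarray(a, dtype=float)
    x_arr = np.asarray(x)
    if np.any(x_arr < 0):
        raise ValueError("batch counts must be >= 0")
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise ValueError("prevalence must be in [0, 1]")
    if not 0 < s <= 1:
        raise ValueError("sensitivity must be in (0, 1]")
    p = s * a_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            p >= 1.0,
            np.where(x_arr > 0, 1.0, 0.0),
            -np.expm1(x_arr * np.log1p(-p)),
        )
    if np.isscalar(a) and np.isscalar(x):
        return float(out)
    return out


def joint_detection(a, x, s: float = 1.0) -> float:
    """Joint probability of detecting every positive-prevalence source.

    Sources with ``a == 0`` are skipped; if any source with ``a > 0``
    has ``x == 0`` the joint probability is 0.
    """
    a = np.asarray(a, dtype=float)
    x = np.asarray(x)
    mask = a > 0
    if not mask.any():
        return 0.0
    d = detection_probability(a[mask], x[mask], s)
    return float(np.prod(d))


# ---------------------------------------------------------------------------
# allocation containers
# ---------------------------------------------------------------------------

@dataclass
class AllocationMatrix:
    """Integer sampling batches per (monitoring province, source)."""

    table: pd.DataFrame  # monitoring_province, source_province, batches
    budgets: dict[str, int]
    label: str = "custom"

    def __post_init__(self) -> None:
        t = self.table
        if (t["batches"] < 0).any():
            raise ValueError("batch counts must be >= 0")
        if not (t["batches"] == t["batches"].astype(int)).all():
            raise ValueError("batch counts must be integers")
        totals = t.groupby("monitoring_province")["batches"].sum()
        for j, total in totals.items():
            budget = self.budgets.get(j)
            if budget is not None and total > budget:
                raise ValueError(
                    f"allocation at {j} ({total}) exceeds budget {budget}"
                )

    def for_monitor(self, monitor: str) -> pd.Series:
        sub = self.table[self.table["monitoring_province"] == monitor]
        return sub.set_index("source_province")["batches"]


@dataclass
class SchemeEvaluation:
    """Detection probabilities and saved loss / saved risk per province."""

    summary: pd.DataFrame    # monitor, h, g_ant, STV, STV_intercepted, SHI, residual_HI, TV_after
    detections: pd.DataFrame  # monitor, source, batches, a, a_ant, d, d_ant
    label: str = "custom"
    stv_mode: str = "as_printed"


@dataclass
class SchemeComparison:
    """Optimized-minus-baseline deltas per province plus national totals."""

    table: pd.DataFrame  # monitor, delta_stv, delta_stv_intercepted, delta_shi
    national: dict[str, float] = field(default_factory=dict)


def evaluate_scheme(
    alloc: AllocationMatrix,
    matrix: ContaminationMatrix,
    risk: RiskTable,
    loss: TradeVolumeTable,
    config: StudyConfig,
    stv_mode: str = "as_printed",
    baseline_h: dict[str, float] | None = None,
) -> SchemeEvaluation:
    """Evaluate a monitoring scheme against estimated rates and risks.

    ``STV`` follows the printed saved-loss form
    ``mean annual AR loss x (1 - a_ant * g)``; the alternative
    detection-removes-loss reading ``mean annual AR loss x g`` is always
    reported alongside as ``STV_intercepted`` (and becomes the headline
    column when ``stv_mode='intercepted'``).  ``TV_after`` applies the
    scheme's own joint detection unless fixed baseline detection
    probabilities are supplied.
    """
    if stv_mode not in ("as_printed", "intercepted"):
        raise ValueError(f"unknown stv_mode {stv_mode!r}")
    s = config.detection_sensitivity
    cells = matrix.cells.set_index(["monitoring_province", "source_province"])
    known_sources = set(cells.index)
    for row in alloc.table.itertuples():
        if (row.monitoring_province, row.source_province) not in known_sources:
            raise ValueError(
                f"allocation references flow ({row.source_province} -> "
                f"{row.monitoring_province}) absent from the contamination matrix"
            )

    hi_partial = risk.hi_partial.set_index(
        ["monitoring_province", "source_province"])["hi_partial"]
    hi_total = risk.hi.set_index("monitoring_province")["HI"]
    marg = matrix.marginals.set_index("monitoring_province")

    vol = loss.volumes
    latest_year = int(vol["year"].max())
    tv_latest = vol[vol["year"] == latest_year].set_index("province")["TV"]
    mean_ctv_ant = vol.groupby("province")["CTV_ant"].mean()

    det_rows = []
    sum_rows = []
    for j in marg.index:
        sub = cells.loc[j] if j in cells.index.get_level_values(0) else None
        x = alloc.for_monitor(j)
        a_vec, a_ant_vec, x_vec, src = [], [], [], []
        for i, cell in sub.iterrows():
            src.append(i)
            a_vec.append(cell["a"])
            a_ant_vec.append(cell["a_ant"])
            x_vec.append(int(x.get(i, 0)))
        a_vec = np.array(a_vec)
        a_ant_vec = np.array(a_ant_vec)
        x_vec = np.array(x_vec, dtype=int)
        d = detection_probability(a_vec, x_vec, s)
        d_ant = detection_probability(a_ant_vec, x_vec, s)
        h = joint_detection(a_vec, x_vec, s)
        g_ant = joint_detection(a_ant_vec, x_vec, s)
        for i, ai, aanti, xi, di, danti in zip(src, a_vec, a_ant_vec, x_vec, d, d_ant):
            det_rows.append((j, i, xi, ai, aanti, di, danti))

        partials = np.array([hi_partial.get((j, i), 0.0) for i in src])
        shi = float((d_ant * partials).sum())
        hi_j = float(hi_total.get(j, 0.0))

        a_j = float(marg.loc[j, "a"])
        a_j_ant = float(marg.loc[j, "a_ant"])
        ctv = float(mean_ctv_ant.get(j, np.nan))
        stv_printed = ctv * (1.0 - a_j_ant * g_ant)
        stv_intercepted = ctv * g_ant
        stv = stv_printed if stv_mode == "as_printed" else stv_intercepted

        h_for_tv = baseline_h[j] if baseline_h is not None else h
        tv_j = float(tv_latest.get(j, np.nan))
        tv_after = tv_j * (1.0 - a_j * h_for_tv)
        sum_rows.append((j, h, g_ant, stv, stv_printed, stv_intercepted,
                         shi, hi_j - shi, tv_after))

    summary = pd.DataFrame(
        sum_rows,
        columns=["monitoring_province", "h", "g_ant", "STV", "STV_as_printed",
                 "STV_intercepted", "SHI", "residual_HI", "TV_after"],
    )
    detections = pd.DataFrame(
        det_rows,
        columns=["monitoring_province", "source_province", "batches",
                 "a", "a_ant", "d", "d_ant"],
    )
    return SchemeEvaluation(summary, detections, alloc.label, stv_mode)


def compare_schemes(opt: SchemeEvaluation, base: SchemeEvaluation) -> SchemeComparison:
    """Optimized minus baseline saved loss and saved risk, per province."""
    a = opt.summary.set_index("monitoring_province")
    b = base.summary.set_index("monitoring_province")
    if set(a.index) != set(b.index):
        raise ValueError("schemes cover different provinces")
    b = b.reindex(a.index)
    table = pd.DataFrame({
        "delta_stv": a["STV"] - b["STV"],
        "delta_stv_intercepted": a["STV_intercepted"] - b["STV_intercepted"],
        "delta_shi": a["SHI"] - b["SHI"],
        "delta_h": a["h"] - b["h"],
        "delta_g_ant": a["g_ant"] - b["g_ant"],
    }).reset_index()
    national = {
        "delta_stv": float(table["delta_stv"].sum()),
        "delta_stv_intercepted": float(table["delta_stv_intercepted"].sum()),
        "delta_shi": float(table["delta_shi"].sum()),
    }
    return SchemeComparison(table, national)


# ---------------------------------------------------------------------------
# per-province solvers
# ---------------------------------------------------------------------------

def _eval_alloc(q: np.ndarray, x: np.ndarray) -> float:
    """Joint detection for active sources, computed in fixed source order."""
    h = 1.0
    for qi, xi in zip(q, x):
        h *= 1.0 - qi ** int(xi)
    return h


def _eval_shi(q_ant: np.ndarray, hi: np.ndarray, x: np.ndarray) -> float:
    return float(sum(h * (1.0 - qi ** int(xi)) for qi, h, xi in zip(q_ant, hi, x)))


def _feasible(h: float, shi: float, h_cap: float | None, shi_min: float | None) -> bool:
    if h_cap is not None and h > h_cap + PROB_TOL:
        return False
    if shi_min is not None and shi < shi_min - PROB_TOL:
        return False
    return True


def _better(h1: float, x1: tuple, h2: float, x2: tuple) -> bool:
    """True when (h1, x1) beats (h2, x2): larger h, ties to lexicographically smallest x."""
    if h1 != h2:
        return h1 > h2
    return x1 < x2


def _log_gain(q: float, x: int) -> float:
    """log(1 - q**(x+1)) - log(1 - q**x); +inf at x == 0."""
    if q <= 0.0:
        return math.inf if x == 0 else 0.0
    if x == 0:
        return math.inf
    return math.log1p(-(q ** (x + 1))) - math.log1p(-(q ** x))


def _greedy_budget(q: np.ndarray, budget: int) -> np.ndarray:
    """Exact budget-only maximizer of prod(1 - q**x) by marginal allocation.

    The log objective has decreasing integer increments, so greedy is
    optimal.  Gain ties prefer the higher source index, which yields the
    lexicographically smallest optimal allocation.
    """
    n = len(q)
    x = np.zeros(n, dtype=int)
    if budget < n:
        # Some source must stay unsampled, so the joint probability is 0
        # regardless; the canonical representative is the empty scheme.
        return x
    x[:] = 1
    remaining = budget - n
    heap = [(-_log_gain(q[i], 1), -i, 1) for i in range(n)]
    heapq.heapify(heap)
    while remaining > 0 and heap:
        neg_gain, neg_i, xi = heapq.heappop(heap)
        i = -neg_i
        if xi != x[i]:  # stale entry
            heapq.heappush(heap, (-_log_gain(q[i], x[i]), neg_i, int(x[i])))
            continue
        if neg_gain == 0.0:
            break
        x[i] += 1
        remaining -= 1
        heapq.heappush(heap, (-_log_gain(q[i], x[i]), neg_i, int(x[i])))
    return x


def _greedy_weighted(q: np.ndarray, w: np.ndarray, budget: int) -> np.ndarray:
    """Greedy maximizer of sum_i w_i * (1 - q_i**x_i) under the budget.

    Increments ``w * q**x * (1 - q)`` decrease in x, so greedy is exact.
    """
    n = len(q)
    x = np.zeros(n, dtype=int)
    heap = [(-(w[i] * (1 - q[i])), i) for i in range(n) if w[i] > 0 and q[i] < 1]
    heapq.heapify(heap)
    remaining = budget
    while remaining > 0 and heap:
        neg_gain, i = heapq.heappop(heap)
        if neg_gain >= 0.0:
            break
        x[i] += 1
        remaining -= 1
        gain = w[i] * (q[i] ** x[i]) * (1 - q[i])
        heapq.heappush(heap, (-gain, i))
    return x


@dataclass
class ProvinceSolution:
    x: np.ndarray
    h: float
    shi: float
    feasible: bool
    optimal: bool
    solver_used: str
    note: str = ""


def _enumerate_allocations(n_sources: int, budget: int):
    for x in itertools.product(range(budget + 1), repeat=n_sources):
        if sum(x) <= budget:
            yield x


def brute_force_province(
    a: np.ndarray,
    budget: int,
    s: float = 1.0,
    a_ant: np.ndarray | None = None,
    hi_partial: np.ndarray | None = None,
    h_cap: float | None = None,
    shi_min: float | None = None,
) -> ProvinceSolution:
    """Exhaustive enumeration oracle for one province (hard size guard).

    Ties are broken to the lexicographically smallest allocation.  When
    the residual-risk constraint is unsatisfiable at any allocation, the
    maximum-saved-risk allocation is returned flagged infeasible.
    """
    a = np.asarray(a, dtype=float)
    n = len(a)
    if n > ORACLE_MAX_SOURCES or budget > ORACLE_MAX_BUDGET:
        raise ValueError(
            f"oracle guard: needs sources <= {ORACLE_MAX_SOURCES} and "
            f"budget <= {ORACLE_MAX_BUDGET}, got {n} and {budget}"
        )
    q = 1.0 - s * a
    q_ant = 1.0 - s * (a_ant if a_ant is not None else a)
    hi = np.asarray(hi_partial if hi_partial is not None else np.zeros(n), dtype=float)

    best: tuple[float, tuple] | None = None
    best_shi: tuple[float, float, tuple] | None = None
    for x in _enumerate_allocations(n, budget):
        h = _eval_alloc(q, np.asarray(x))
        shi = _eval_shi(q_ant, hi, np.asarray(x))
        if best_shi is None or shi > best_shi[0] + PROB_TOL or (
            abs(shi - best_shi[0]) <= PROB_TOL and _better(h, x, best_shi[1], best_shi[2])
        ):
            best_shi = (shi, h, x)
        if not _feasible(h, shi, h_cap, shi_min):
            continue
        if best is None or _better(h, x, best[0], best[1]):
            best = (h, x)
    if best is None:
        shi, h, x = best_shi
        return ProvinceSolution(np.asarray(x, dtype=int), h, shi, False, True,
                                "oracle", "residual-risk constraint unsatisfiable")
    x = np.asarray(best[1], dtype=int)
    return ProvinceSolution(x, best[0], _eval_shi(q_ant, hi, x), True, True, "oracle")


def _dp_constrained(
    q: np.ndarray,
    q_ant: np.ndarray,
    hi: np.ndarray,
    budget: int,
    h_cap: float | None,
    shi_min: float | None,
) -> ProvinceSolution | None:
    """Exact levelwise dynamic program over partial allocations.

    States are partial allocations keyed by budget used; when no cap on
    the objective is active, Pareto-dominated states (lower joint
    detection and lower saved risk, with a lexicographically larger
    prefix) are pruned.  Returns ``None`` when the state space exceeds
    the guard.
    """
    n = len(q)
    n_states = math.comb(budget + n, n)
    if n_states > DP_MAX_STATES:
        return None
    prune = h_cap is None

    # state: (x_prefix tuple, used)
    states: list[tuple[tuple, int]] = [((), 0)]
    for i in range(n):
        nxt: list[tuple[tuple, int]] = []
        for prefix, used in states:
            for xi in range(budget - used + 1):
                nxt.append((prefix + (xi,), used + xi))
        if prune and i < n - 1:
            # Pareto-prune per used-budget on (partial h, partial shi).
            by_budget: dict[int, list[tuple[tuple, float, float]]] = {}
            for prefix, used in nxt:
                xp = np.asarray(prefix)
                ph = _eval_alloc(q[: i + 1], xp)
                pshi = _eval_shi(q_ant[: i + 1], hi[: i + 1], xp)
                by_budget.setdefault(used, []).append((prefix, ph, pshi))
            kept: list[tuple[tuple, int]] = []
            for used, items in by_budget.items():
                items.sort(key=lambda t: (-t[1], -t[2], t[0]))
                front: list[tuple[tuple, float, float]] = []
                for prefix, ph, pshi in items:
                    if any(fh >= ph and fs >= pshi for _, fh, fs in front):
                        continue
                    front.append((prefix, ph, pshi))
                kept.extend((prefix, used) for prefix, _, _ in front)
            nxt = kept
        states = nxt

    best: tuple[float, tuple] | None = None
    best_shi: tuple[float, float, tuple] | None = None
    for x, used in states:
        xv = np.asarray(x)
        h = _eval_alloc(q, xv)
        shi = _eval_shi(q_ant, hi, xv)
        if best_shi is None or shi > best_shi[0] + PROB_TOL or (
            abs(shi - best_shi[0]) <= PROB_TOL and _better(h, x, best_shi[1], best_shi[2])
        ):
            best_shi = (shi, h, x)
        if not _feasible(h, shi, h_cap, shi_min):
            continue
        if best is None or _better(h, x, best[0], best[1]):
            best = (h, x)
    if best is None:
        shi, h, x = best_shi
        return ProvinceSolution(np.asarray(x, dtype=int), h, shi, False, True,
                                "exact_dp", "residual-risk constraint unsatisfiable")
    x = np.asarray(best[1], dtype=int)
    return ProvinceSolution(x, best[0], _eval_shi(q_ant, hi, x), True, True, "exact_dp")


def _greedy_local(
    q: np.ndarray,
    q_ant: np.ndarray,
    hi: np.ndarray,
    budget: int,
    h_cap: float | None,
    shi_min: float | None,
    max_passes: int = 50,
) -> ProvinceSolution:
    """Greedy construction plus repair and pairwise-swap improvement."""
    n = len(q)
    x = _greedy_budget(q, budget)

    def h_of(xv):
        return _eval_alloc(q, xv)

    def shi_of(xv):
        return _eval_shi(q_ant, hi, xv)

    # Repair the residual-risk floor by moving batches toward risk-heavy sources.
    for _ in range(max_passes * n):
        if shi_min is None or shi_of(x) >= shi_min - PROB_TOL:
            break
        best_move = None
        for t in range(n):
            trial = x.copy()
            trial[t] += 1
            if trial.sum() <= budget:
                gain = shi_of(trial) - shi_of(x)
                if gain > 0 and (best_move is None or gain > best_move[0]):
                    best_move = (gain, None, t)
            for r in range(n):
                if x[r] == 0 or r == t:
                    continue
                trial = x.copy()
                trial[r] -= 1
                trial[t] += 1
                gain = shi_of(trial) - shi_of(x)
                if gain > 0 and (best_move is None or gain > best_move[0]):
                    best_move = (gain, r, t)
        if best_move is None:
            break
        _, r, t = best_move
        if r is not None:
            x[r] -= 1
        x[t] += 1

    # Repair the objective cap by dropping the cheapest batches.
    while h_cap is not None and h_of(x) > h_cap + PROB_TOL:
        best_drop = None
        for r in range(n):
            if x[r] == 0:
                continue
            trial = x.copy()
            trial[r] -= 1
            loss = h_of(x) - h_of(trial)
            if shi_min is not None and shi_of(trial) < shi_min - PROB_TOL:
                continue
            if best_drop is None or loss < best_drop[0]:
                best_drop = (loss, r)
        if best_drop is None:
            break
        x[best_drop[1]] -= 1

    # Pairwise swap improvement while staying feasible.
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        cur_h = h_of(x)
        for r in range(n):
            if x[r] == 0:
                continue
            for t in range(n):
                if r == t:
                    continue
                trial = x.copy()
                trial[r] -= 1
                trial[t] += 1
                th = h_of(trial)
                if th > cur_h and _feasible(th, shi_of(trial), h_cap, shi_min):
                    x = trial
                    cur_h = th
                    improved = True
    h = h_of(x)
    shi = shi_of(x)
    feasible = _feasible(h, shi, h_cap, shi_min)
    return ProvinceSolution(x, h, shi, feasible, False, "greedy_local")


def solve_province(
    a: np.ndarray,
    budget: int,
    s: float = 1.0,
    a_ant: np.ndarray | None = None,
    hi_partial: np.ndarray | None = None,
    h_cap: float | None = None,
    shi_min: float | None = None,
    solver: str = "exact_dp",
) -> ProvinceSolution:
    """Solve one province's allocation problem.

    Sources with zero prevalence are excluded by the caller; ``a`` holds
    the active sources only.  ``h_cap`` encodes the trade-volume floor
    (an upper bound on joint detection), ``shi_min`` the residual-risk
    cap (a lower bound on saved risk).
    """
    a = np.asarray(a, dtype=float)
    n = len(a)
    if n == 0:
        raise ValueError("empty source set")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    q = 1.0 - s * a
    a_ant = np.asarray(a_ant if a_ant is not None else a, dtype=float)
    q_ant = 1.0 - s * a_ant
    hi = np.asarray(hi_partial if hi_partial is not None else np.zeros(n), dtype=float)

    if solver == "oracle":
        return brute_force_province(a, budget, s, a_ant, hi, h_cap, shi_min)

    # Feasibility of the residual-risk floor at full budget.
    if shi_min is not None and shi_min > PROB_TOL:
        x_shi = _greedy_weighted(q_ant, hi, budget)
        shi_max = _eval_shi(q_ant, hi, x_shi)
        if shi_max < shi_min - PROB_TOL:
            return ProvinceSolution(
                x_shi, _eval_alloc(q, x_shi), shi_max, False, True, solver,
                "residual-risk constraint unsatisfiable at full budget",
            )

    # Screening: the budget-only optimum is globally optimal whenever it
    # already satisfies the side constraints.
    x0 = _greedy_budget(q, budget)
    h0 = _eval_alloc(q, x0)
    shi0 = _eval_shi(q_ant, hi, x0)
    if _feasible(h0, shi0, h_cap, shi_min):
        return ProvinceSolution(x0, h0, shi0, True, True, "greedy")

    if solver == "exact_dp":
        sol = _dp_constrained(q, q_ant, hi, budget, h_cap, shi_min)
        if sol is not None:
            return sol
        logger.warning("instance too large for the exact DP; falling back to "
                       "greedy repair")
    return _greedy_local(q, q_ant, hi, budget, h_cap, shi_min)


# ---------------------------------------------------------------------------
# full optimization across provinces
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    allocation: AllocationMatrix
    objective: dict[str, float]
    report: pd.DataFrame  # per-province constraint and solver report
    solver: str


def optimize_allocation(
    matrix: ContaminationMatrix,
    risk: RiskTable,
    trade,
    budgets: dict[str, int],
    config: StudyConfig,
    solver: str = "exact_dp",
    tv_mode: str = "decision",
    baseline_h: dict[str, float] | None = None,
    enforce_tv: bool = True,
    enforce_hi: bool = True,
) -> OptimizationResult:
    """Allocate sampling budgets across sources, province by province.

    ``tv_mode='decision'`` makes the trade-volume floor depend on the
    candidate scheme's own joint detection (so the constraint bounds how
    much volume the scheme may remove); ``tv_mode='baseline'`` checks the
    floor at fixed baseline detection probabilities instead, leaving the
    optimization unconstrained by it.
    """
    if tv_mode not in ("decision", "baseline"):
        raise ValueError(f"unknown tv_mode {tv_mode!r}")
    s = config.detection_sensitivity
    tv = compute_trade_volume(trade)
    latest_year = int(tv["year"].max())
    tv_latest = tv[tv["year"] == latest_year].set_index("province")["TV"]
    tv_mean = tv.groupby("province")["TV"].mean()

    hi_partial = risk.hi_partial.set_index(
        ["monitoring_province", "source_province"])["hi_partial"]
    hi_total = risk.hi.set_index("monitoring_province")["HI"]
    marg = matrix.marginals.set_index("monitoring_province")

    alloc_rows = []
    report_rows = []
    objective: dict[str, float] = {}
    for j, cell_group in matrix.cells.groupby("monitoring_province"):
        budget = int(budgets.get(j, 0))
        if budget < 0:
            raise ValueError(f"budget for {j} must be >= 0")
        active = cell_group[cell_group["a"] > 0]
        inactive = cell_group[cell_group["a"] <= 0]
        src = list(active["source_province"])
        note = ""
        if not src:
            for i in inactive["source_province"]:
                alloc_rows.append((j, i, 0))
            objective[j] = 0.0
            report_rows.append((j, 0.0, 0.0, budget, True, True, "none",
                                np.nan, np.nan, "no contaminated sources"))
            continue

        a_vec = active["a"].to_numpy(dtype=float)
        a_ant_vec = active["a_ant"].to_numpy(dtype=float)
        hi_vec = np.array([hi_partial.get((j, i), 0.0) for i in src])

        h_cap = None
        tv_infeasible = False
        if enforce_tv and tv_mode == "decision" and j in tv_latest.index:
            a_j = float(marg.loc[j, "a"])
            ratio = float(tv_mean.loc[j] / tv_latest.loc[j]) if tv_latest.loc[j] > 0 else np.inf
            if a_j > 0:
                cap = (1.0 - ratio) / a_j
                if cap < -PROB_TOL:
                    # Even an empty scheme breaches the floor: flag and
                    # optimize without it.
                    tv_infeasible = True
                    logger.warning("trade-volume floor unsatisfiable at %s; "
                                   "optimizing without it", j)
                elif cap < 1.0:
                    h_cap = max(cap, 0.0)

        shi_min = None
        hi_j = float(hi_total.get(j, 0.0))
        if enforce_hi and hi_j > config.standard_value:
            shi_min = hi_j - config.standard_value

        sol = solve_province(a_vec, budget, s, a_ant_vec, hi_vec,
                             h_cap, shi_min, solver)
        for i, xi in zip(src, sol.x):
            alloc_rows.append((j, i, int(xi)))
        for i in inactive["source_province"]:
            alloc_rows.append((j, i, 0))
        objective[j] = sol.h
        note = sol.note or ("trade-volume floor dropped" if tv_infeasible else "")
        report_rows.append((
            j, sol.h, sol.shi, budget - int(sol.x.sum()),
            sol.feasible and not tv_infeasible, sol.optimal, sol.solver_used,
            h_cap if h_cap is not None else np.nan,
            shi_min if shi_min is not None else np.nan,
            note,
        ))

    allocation = AllocationMatrix(
        pd.DataFrame(alloc_rows, columns=["monitoring_province", "source_province",
                                          "batches"]),
        budgets=dict(budgets),
        label="optimized",
    )
    report = pd.DataFrame(
        report_rows,
        columns=["monitoring_province", "h", "SHI", "budget_slack", "feasible",
                 "optimal", "solver_used", "h_cap", "shi_min", "note"],
    )
    return OptimizationResult(allocation, objective, report, solver)
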
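"""Revealed-preference relations, GARP tests and consistency indices.

Given a set of observations (chosen bundle, prices, budget), a bundle
``x_i`` is *directly revealed preferred* to ``x_j`` when ``x_j`` was
affordable at the prices of observation ``i`` (``x_j . p_i <= m_i``) and the
bundles differ; the preference is *strict* when ``x_j . p_i < m_i``.  The
Generalized Axiom of Revealed Preference (GARP) requires that no bundle be
(transitively) revealed preferred to another that is strictly directly
preferred to it.

Consistency indices quantify how badly a dataset fails GARP:

* **CCEI** (Afriat's critical cost efficiency index): the largest uniform
  budget-deflation factor ``e`` at which the relaxed relations satisfy GARP.
  The default relaxation applies ``e`` to both the affordability relation
  (``x_j . p_i <= e * m_i``) and the strict comparison — Varian's canonical
  algorithm.  ``variant="paper-literal"`` instead relaxes only the strict
  side while keeping the relations at full budgets.
* **Houtman-Maks index**: minimal number of observations whose removal
  restores GARP consistency.
* **Money pump index**: mean fraction of expenditure extractable by
  arbitraging violating preference cycles.
* **Minimum cost index**: cheapest total relation "slack" that must be
  deleted to break all violating cycles, normalized by n.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

from .core_task import Block

__all__ = [
    "AFFORDABILITY_TOL",
    "ObservationSet",
    "RelationMatrices",
    "ConsistencyResult",
    "HoutmanMaksResult",
    "cost_matrix",
    "relations_at_efficiency",
    "garp_violations",
    "ccei",
    "ccei_breakpoint",
    "count_inconsistent_choices",
    "houtman_maks",
    "money_pump_index",
    "minimum_cost_index",
    "consistency_report",
]

#: Absolute tolerance on affordability comparisons; absorbs float noise from
#: the budget-line construction.  Knife-edge equality counts as affordable
#: (<=), never as strictly cheaper (<).
AFFORDABILITY_TOL = 1e-9

#: Bundles closer than this (sup-norm) are treated as identical.
BUNDLE_EQ_TOL = 1e-12


@dataclass(frozen=True)
class ObservationSet:
    """Chosen bundles with the prices and budgets they were chosen under.

    All choices are assumed to exhaust the budget (``x_i . p_i = m_i``); this
    is enforced at construction because the revealed-preference machinery
    relies on it.
    """

    bundles: np.ndarray  # (n, 2)
    prices: np.ndarray  # (n, 2)
    budgets: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.bundles, dtype=float))
        p = np.atleast_2d(np.asarray(self.prices, dtype=float))
        m = np.atleast_1d(np.asarray(self.budgets, dtype=float))
        object.__setattr__(self, "bundles", b)
        object.__setattr__(self, "prices", p)
        object.__setattr__(self, "budgets", m)
        if b.shape != p.shape or b.shape[0] != m.shape[0] or b.shape[0] < 1:
            raise ValueError(
                f"inconsistent shapes: bundles {b.shape}, prices {p.shape}, "
                f"budgets {m.shape}"
            )
        spent = np.einsum("ij,ij->i", b, p)
        if not np.allclose(spent, m, rtol=1e-6, atol=1e-6):
            worst = np.max(np.abs(spent - m))
            raise ValueError(
                f"choices must exhaust the budget; max |x.p - m| = {worst:g}"
            )

    @property
    def n(self) -> int:
        return self.bundles.shape[0]

    @classmethod
    def from_block(cls, block: Block) -> "ObservationSet":
        bundles, prices, budgets = [], [], []
        for trial in block.trials:
            bundles.append(trial.chosen_bundle.as_array())
            prices.append(trial.prices.as_array())
            budgets.append(trial.budget)
        return cls(
            bundles=np.array(bundles), prices=np.array(prices), budgets=np.array(budgets)
        )

    def subset(self, keep: np.ndarray) -> "ObservationSet":
        return ObservationSet(
            bundles=self.bundles[keep], prices=self.prices[keep], budgets=self.budgets[keep]
        )


@dataclass(frozen=True)
class RelationMatrices:
    """Boolean revealed-preference relations at one efficiency level."""

    r_direct: np.ndarray  # direct revealed preference R_D
    p_direct: np.ndarray  # strict direct revealed preference P_D
    r_closure: np.ndarray  # R, transitive closure of R_D
    efficiency: float


class HoutmanMaksResult(NamedTuple):
    removed: int
    fraction: float
    exact: bool


@dataclass(frozen=True)
class ConsistencyResult:
    """All consistency indices for one block of observations."""

    ccei: float
    n_violating_pairs: int
    n_inconsistent_choices: int
    hmi_removed: int
    hmi_fraction: float
    mpi: float
    mci: float
    hmi_exact: bool = True
    mci_exact: bool = True


def cost_matrix(obs: ObservationSet) -> np.ndarray:
    """``C[i, j] = x_j . p_i``: cost of bundle j at the prices of trial i."""
    return obs.prices @ obs.bundles.T


def _distinct_bundles(obs: ObservationSet) -> np.ndarray:
    """Boolean matrix, True where bundles i and j differ (sup-norm > tol)."""
    diff = np.abs(obs.bundles[:, None, :] - obs.bundles[None, :, :]).max(axis=2)
    return diff > BUNDLE_EQ_TOL


def _transitive_closure(rel: np.ndarray) -> np.ndarray:
    """Transitive closure of a boolean relation by repeated squaring."""
    closure = rel.copy()
    while True:
        nxt = closure | (closure @ closure)
        if np.array_equal(nxt, closure):
            return closure
        closure = nxt


def relations_at_efficiency(
    obs: ObservationSet, e: float, variant: str = "varian"
) -> RelationMatrices:
    """Build R_D, P_D and the closure R at budget-efficiency ``e``.

    ``variant="varian"`` deflates both the affordability relation and the
    strict comparison by ``e``; ``variant="paper-literal"`` keeps R_D (and
    hence R) at full budgets and deflates only the strict side.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"efficiency must lie in [0, 1], got {e}")
    if variant not in ("varian", "paper-literal"):
        raise ValueError(f"unknown variant {variant!r}")
    C = cost_matrix(obs)
    m = obs.budgets[:, None]
    distinct = _distinct_bundles(obs)
    e_weak = e if variant == "varian" else 1.0
    r_direct = (C <= e_weak * m + AFFORDABILITY_TOL) & distinct
    p_direct = C < e * m - AFFORDABILITY_TOL
    np.fill_diagonal(p_direct, False)
    return RelationMatrices(
        r_direct=r_direct,
        p_direct=p_direct,
        r_closure=_transitive_closure(r_direct),
        efficiency=float(e),
    )


def garp_violations(
    obs: ObservationSet, e: float = 1.0, variant: str = "varian"
) -> list[tuple[int, int]]:
    """Ordered pairs (i, j) with ``x_i R x_j`` and ``x_j P_D x_i`` at level e.

    An empty list means GARP holds at efficiency ``e``.  Indices are 0-based.
    """
    rel = relations_at_efficiency(obs, e, variant=variant)
    ii, jj = np.nonzero(rel.r_closure & rel.p_direct.T)
    return list(zip(ii.tolist(), jj.tolist()))


def _consistent_at(obs: ObservationSet, e: float, variant: str) -> bool:
    rel = relations_at_efficiency(obs, e, variant=variant)
    return not np.any(rel.r_closure & rel.p_direct.T)


def ccei(
    obs: ObservationSet, tol: float = 1e-6, variant: str = "varian"
) -> float:
    """Critical cost efficiency index by binary search.

    The violating-pair set grows monotonically with ``e``, so the supremum of
    consistent efficiency levels can be bisected to ``tol``.  Returns 1.0 for
    GARP-consistent data.
    """
    if _consistent_at(obs, 1.0, variant):
        return 1.0
    lo, hi = 0.0, 1.0  # lo consistent, hi inconsistent
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _consistent_at(obs, mid, variant):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ccei_breakpoint(obs: ObservationSet, variant: str = "varian") -> float:
    """Exact CCEI by enumerating the breakpoints ``e = C[i, j] / m_i``.

    The relation structure is piecewise constant between breakpoints, so the
    supremum of consistent efficiencies is always a breakpoint.  This serves
    as the independent oracle for the binary-search implementation.
    """
    if _consistent_at(obs, 1.0, variant):
        return 1.0
    C = cost_matrix(obs)
    ratios = C / obs.budgets[:, None]
    mask = ~np.eye(obs.n, dtype=bool)
    candidates = np.unique(ratios[mask & (ratios > 0) & (ratios <= 1.0)])
    candidates = np.append(candidates, 1.0)
    candidates = np.unique(candidates)
    prev = 0.0
    for k, b in enumerate(candidates):
        upper = candidates[k + 1] if k + 1 < len(candidates) else 1.0
        mid = 0.5 * (b + upper) if upper > b else b
        if not _consistent_at(obs, float(b), variant) or not _consistent_at(
            obs, float(mid), variant
        ):
            # inconsistency first appears at or just above this breakpoint;
            # the set of consistent efficiencies has supremum b
            return float(b)
        prev = b
    return float(prev)


def count_inconsistent_choices(
    obs: ObservationSet, variant: str = "varian", mode: str = "observations"
) -> int:
    """Number of observations appearing in >= 1 violating ordered pair at e=1.

    ``mode="pairs"`` instead counts the violating ordered pairs themselves.
    """
    viols = garp_violations(obs, 1.0, variant=variant)
    if mode == "pairs":
        return len(viols)
    if mode != "observations":
        raise ValueError(f"unknown mode {mode!r}")
    return len({k for pair in viols for k in pair})


def houtman_maks(
    obs: ObservationSet, variant: str = "varian", node_budget: int = 200_000
) -> HoutmanMaksResult:
    """Minimal number of observations to drop for GARP consistency.

    Exact via iterative deepening over subsets of the observations involved
    in violations; above ``node_budget`` examined subsets, falls back to a
    greedy heuristic (remove the observation involved in the most violating
    pairs) and flags the result as inexact.
    """
    viols = garp_violations(obs, 1.0, variant=variant)
    if not viols:
        return HoutmanMaksResult(0, 0.0, True)
    involved = sorted({k for pair in viols for k in pair})
    all_idx = np.arange(obs.n)

    def consistent_without(drop: tuple[int, ...]) -> bool:
        keep = np.setdiff1d(all_idx, np.array(drop))
        return _consistent_at(obs.subset(keep), 1.0, variant)

    nodes = 0
    for k in range(1, len(involved) + 1):
        for drop in itertools.combinations(involved, k):
            nodes += 1
            if nodes > node_budget:
                removed = _houtman_maks_greedy(obs, variant)
                return HoutmanMaksResult(removed, removed / obs.n, False)
            if consistent_without(drop):
                return HoutmanMaksResult(k, k / obs.n, True)
    # removing every involved observation always clears all violations
    k = len(involved)
    return HoutmanMaksResult(k, k / obs.n, True)


def _houtman_maks_greedy(obs: ObservationSet, variant: str) -> int:
    keep = np.arange(obs.n)
    removed = 0
    while True:
        sub = obs.subset(keep)
        viols = garp_violations(sub, 1.0, variant=variant)
        if not viols:
            return removed
        counts = np.zeros(len(keep), dtype=int)
        for i, j in viols:
            counts[i] += 1
            counts[j] += 1
        keep = np.delete(keep, int(np.argmax(counts)))
        removed += 1


def _violating_cycles(
    obs: ObservationSet, max_cycle_len: int, variant: str = "varian"
) -> tuple[list[list[int]], np.ndarray, RelationMatrices]:
    rel = relations_at_efficiency(obs, 1.0, variant=variant)
    C = cost_matrix(obs)
    G = nx.DiGraph(rel.r_direct)
    cycles = []
    for cyc in nx.simple_cycles(G, length_bound=max_cycle_len):
        strict = any(
            rel.p_direct[cyc[k], cyc[(k + 1) % len(cyc)]] for k in range(len(cyc))
        )
        if strict:
            cycles.append(cyc)
    return cycles, C, rel


def money_pump_index(
    obs: ObservationSet, max_cycle_len: int = 3, variant: str = "varian"
) -> float:
    """Mean money-pump cost over simple violating cycles of bounded length.

    For a cycle ``c_0 -> c_1 -> ... -> c_0`` in R_D containing at least one
    strict edge, the pump cost is
    ``sum_k (x_k.p_k - x_{k+1}.p_k) / sum_k x_k.p_k``: the fraction of total
    expenditure an arbitrageur could extract by trading around the cycle.
    Returns 0 when no violating cycle exists.
    """
    cycles, C, _ = _violating_cycles(obs, max_cycle_len, variant)
    if not cycles:
        return 0.0
    costs = []
    for cyc in cycles:
        num = sum(
            obs.budgets[cyc[k]] - C[cyc[k], cyc[(k + 1) % len(cyc)]]
            for k in range(len(cyc))
        )
        den = sum(obs.budgets[k] for k in cyc)
        costs.append(num / den)
    return float(np.mean(costs))


def _has_violation_without(
    r_direct: np.ndarray, p_direct: np.ndarray, removed: set[tuple[int, int]]
) -> tuple[int, int] | None:
    """First (i, j) with i R j and j P_D i among non-removed relations."""
    rd = r_direct.copy()
    pd_ = p_direct.copy()
    for i, j in removed:
        rd[i, j] = False
        pd_[i, j] = False
    closure = _transitive_closure(rd)
    hits = np.nonzero(closure & pd_.T)
    if hits[0].size == 0:
        return None
    return int(hits[0][0]), int(hits[1][0])


def _cycle_edges_for_violation(
    r_direct: np.ndarray, removed: set[tuple[int, int]], i: int, j: int
) -> list[tuple[int, int]]:
    rd = r_direct.copy()
    for a, b in removed:
        rd[a, b] = False
    G = nx.DiGraph(rd)
    path = nx.shortest_path(G, i, j)
    edges = [(path[k], path[k + 1]) for k in range(len(path) - 1)]
    edges.append((j, i))  # the strict relation closing the cycle
    return edges


def minimum_cost_index(
    obs: ObservationSet, variant: str = "varian", node_budget: int = 100_000
) -> float:
    """Minimum cost index: cheapest relation-removal that breaks all cycles.

    Each direct relation (i, j) carries weight ``(m_i - C[i, j]) / m_i``, the
    budget slack that makes it a revealed preference.  The index is the
    minimum total weight of an edge set whose removal leaves no GARP
    violation, divided by n.  Solved by branch-and-bound on violating cycles
    (exact on small instances); beyond ``node_budget`` nodes, the best bound
    found (seeded by a greedy solution) is returned.
    """
    rel = relations_at_efficiency(obs, 1.0, variant=variant)
    C = cost_matrix(obs)
    if not np.any(rel.r_closure & rel.p_direct.T):
        return 0.0
    weights = np.maximum(obs.budgets[:, None] - C, 0.0) / obs.budgets[:, None]

    def removal_cost(removed: set[tuple[int, int]]) -> float:
        return float(sum(weights[i, j] for i, j in removed))

    # greedy seed: repeatedly delete the cheapest edge of some violating cycle
    greedy: set[tuple[int, int]] = set()
    while True:
        hit = _has_violation_without(rel.r_direct, rel.p_direct, greedy)
        if hit is None:
            break
        edges = _cycle_edges_for_violation(rel.r_direct, greedy, *hit)
        greedy.add(min(edges, key=lambda e: weights[e]))

    best = {"cost": removal_cost(greedy), "exact": True}
    nodes = {"n": 0}

    def branch(removed: set[tuple[int, int]], cost: float) -> None:
        nodes["n"] += 1
        if nodes["n"] > node_budget:
            best["exact"] = False
            return
        if cost >= best["cost"]:
            return
        hit = _has_violation_without(rel.r_direct, rel.p_direct, removed)
        if hit is None:
            best["cost"] = cost
            return
        for edge in _cycle_edges_for_violation(rel.r_direct, removed, *hit):
            branch(removed | {edge}, cost + weights[edge])

    branch(set(), 0.0)
    if not best["exact"]:
        warnings.warn(
            "minimum_cost_index hit its node budget; value is an upper bound",
            RuntimeWarning,
            stacklevel=2,
        )
    return best["cost"] / obs.n


def consistency_report(
    block: Block,
    variant: str = "varian",
    mpi_cycle_len: int = 3,
    ccei_tol: float = 1e-6,
) -> ConsistencyResult:
    """Assemble an :class:`ObservationSet` from a block and run all indices."""
    obs = ObservationSet.from_block(block)
    viols = garp_violations(obs, 1.0, variant=variant)
    hm = houtman_maks(obs, variant=variant)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", RuntimeWarning)
        mci = minimum_cost_index(obs, variant=variant)
    mci_exact = not any("node budget" in str(w.message) for w in caught)
    return ConsistencyResult(
        ccei=ccei(obs, tol=ccei_tol, variant=variant),
        n_violating_pairs=len(viols),
        n_inconsistent_choices=len({k for pair in viols for k in pair}),
        hmi_removed=hm.removed,
        hmi_fraction=hm.fraction,
        mpi=money_pump_index(obs, max_cycle_len=mpi_cycle_len, variant=variant),
        mci=mci,
        hmi_exact=hm.exact,
        mci_exact=mci_exact,
    )
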
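"""Node proximity measures on probabilistic (edge-weighted) graphs.

Four measures are provided:

* **probability of best path** — max over s-t paths of the product of edge
  probabilities; exact, via Dijkstra on -log weights.
* **two-terminal network reliability** — probability that a random
  realization of the graph (each edge kept independently with its weight)
  connects s and t; #P-hard exactly, estimated by Monte Carlo over
  realizations of a bounded neighborhood subgraph, with an exhaustive
  oracle for small instances.
* **expected reliable distance** — expected hop-count shortest-path distance
  between s and t conditioned on their being connected in the realization.
* **random walk with restart** — stationary probability of a walker that
  restarts to the root with probability beta and otherwise moves to a
  neighbor with probability proportional to edge weight, symmetrized by
  averaging the two rooted scores.  Computed exactly by a sparse linear
  solve, or by simulation.

The probabilistic measures require capped weights in [0,1]; the random walk
accepts uncapped weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from heapq import heappop, heappush
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_model import Edge, LookupError_, neighborhood_subgraph
from .weighting import WeightedGraph

BEST_PATH = "best_path"
RELIABILITY = "reliability"
ERD = "expected_reliable_distance"
RANDOM_WALK = "random_walk"

MEASURES = (BEST_PATH, RELIABILITY, ERD, RANDOM_WALK)

#: Instance-size cutoff for the exhaustive realization oracle.
_ORACLE_MAX_EDGES = 20

#: Linear-solve convergence tolerance for the exact random walk.
_RW_TOL = 1e-12


class SizeError(Exception):
    """Instance too large for exhaustive enumeration."""


@dataclass(frozen=True)
class ProximityParams:
    measure: str = RANDOM_WALK
    beta: float = 0.2
    n_samples: int = 10_000
    rw_iterations: int = 1_000_000
    rw_method: str = "exact"
    seed: int | None = None
    bounding: tuple[int, int] | None = None  # (max_nodes, max_depth)

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown proximity measure {self.measure!r}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("restart probability beta must lie in (0,1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.rw_method not in ("exact", "simulate"):
            raise ValueError(f"unknown rw_method {self.rw_method!r}")


@dataclass(frozen=True)
class ProximityEstimate:
    value: float
    method: str
    std_error: float | None = None
    seed: int | None = None
    defined: bool = True  # False: ERD with no connected realization sampled


# -- probability of best path ---------------------------------------------


def best_path_probability(wg: WeightedGraph, s: str, t: str) -> float:
    """Max over s-t paths of the product of edge weights.

    Computed as a Dijkstra shortest path under -log weights; zero-weight
    edges are treated as absent.  Returns 0 for disconnected pairs and 1 for
    s == t.
    """
    g = wg.graph
    for nid in (s, t):
        g.node(nid)
    if s == t:
        return 1.0
    dist: dict[str, float] = {}
    heap: list[tuple[float, str]] = [(0.0, s)]
    while heap:
        d, u = heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        if u == t:
            return math.exp(-d)
        for ie in g.incident(u):
            w = wg.w(ie.edge)
            if w <= 0.0 or ie.neighbor in dist:
                continue
            heappush(heap, (d - math.log(w), ie.neighbor))
    return 0.0


# -- Monte-Carlo machinery -------------------------------------------------


def sample_realization(wg: WeightedGraph, rng: np.random.Generator) -> list[Edge]:
    """One random realization: each edge kept independently w.p. its weight."""
    edges = list(wg.graph.edges())
    w = np.array([wg.w(e) for e in edges], dtype=float)
    if w.size and (w.min() < 0.0 or w.max() > 1.0):
        raise ValueError("realization sampling requires weights in [0,1]")
    keep = rng.random(w.size) < w
    return [e for e, k in zip(edges, keep) if k]


def _edge_arrays(wg: WeightedGraph) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Node order plus (u_idx, v_idx, weight) arrays for the stored edges."""
    nodes = wg.graph.node_ids
    idx = {n: i for i, n in enumerate(nodes)}
    edges = list(wg.graph.edges())
    ui = np.array([idx[e.source] for e in edges], dtype=np.int64)
    vi = np.array([idx[e.target] for e in edges], dtype=np.int64)
    w = np.array([wg.w(e) for e in edges], dtype=float)
    if w.size and (w.min() < 0.0 or w.max() > 1.0):
        raise ValueError("probabilistic measures require weights in [0,1]")
    return nodes, ui, vi, w


def _st_distance(
    n: int, ui: np.ndarray, vi: np.ndarray, mask: np.ndarray, s: int, t: int
) -> int:
    """Hop distance s->t in the realization selected by ``mask``; -1 if none."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for k in np.flatnonzero(mask):
        adj[ui[k]].append(vi[k])
        adj[vi[k]].append(ui[k])
    if s == t:
        return 0
    dist = [-1] * n
    dist[s] = 0
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    if v == t:
                        return dist[v]
                    nxt.append(v)
        frontier = nxt
    return -1


def _bound(wg: WeightedGraph, s: str, t: str, params: ProximityParams) -> WeightedGraph:
    if params.bounding is None:
        return wg
    max_nodes, max_depth = params.bounding
    sub = neighborhood_subgraph(wg.graph, [s, t] if s != t else [s], max_nodes, max_depth, wg.weight)
    return wg.subgraph(sub.node_ids)


def _mc_reliability_erd(
    wg: WeightedGraph, s: str, t: str, params: ProximityParams
) -> tuple[float, float, float | None, bool]:
    """Shared MC loop.

    Returns (reliability, reliability SE, ERD or None, erd_defined).  Samples
    are grouped by realized edge mask so connectivity/BFS runs once per
    distinct realization, which collapses the work on small bounded subgraphs.
    """
    wg = _bound(wg, s, t, params)
    nodes, ui, vi, w = _edge_arrays(wg)
    idx = {n: i for i, n in enumerate(nodes)}
    if s not in idx or t not in idx:
        raise LookupError_(f"terminal missing from bounded subgraph: {s!r}/{t!r}")
    si, ti = idx[s], idx[t]
    n, m, ns = len(nodes), len(w), params.n_samples
    rng = np.random.default_rng(params.seed)

    # degenerate edges: certain (w==1) and absent (w==0) need no sampling
    certain = w >= 1.0
    uncertain = np.flatnonzero((w > 0.0) & (w < 1.0))

    if uncertain.size <= 16:
        # exact enough to group: enumerate the distinct sampled masks
        draws = rng.random((ns, uncertain.size)) < w[uncertain]
        if uncertain.size:
            codes = draws @ (1 << np.arange(uncertain.size, dtype=np.int64))
        else:
            codes = np.zeros(ns, dtype=np.int64)
        uniq, counts = np.unique(codes, return_counts=True)
        conn_n = 0
        dist_sum = 0
        conn_count = 0
        mask = np.zeros(m, dtype=bool)
        for code, cnt in zip(uniq, counts):
            mask[:] = certain
            for j, k in enumerate(uncertain):
                mask[k] = bool((int(code) >> j) & 1)
            d = _st_distance(n, ui, vi, mask, si, ti)
            if d >= 0:
                conn_n += cnt
                dist_sum += d * cnt
                conn_count += cnt
    else:
        conn_n = 0
        dist_sum = 0
        conn_count = 0
        for _ in range(ns):
            mask = rng.random(m) < w
            d = _st_distance(n, ui, vi, mask, si, ti)
            if d >= 0:
                conn_n += 1
                dist_sum += d
                conn_count += 1

    rel = conn_n / ns
    se = math.sqrt(rel * (1.0 - rel) / ns)
    if conn_count == 0:
        return rel, se, None, False
    return rel, se, dist_sum / conn_count, True


def network_reliability(
    wg: WeightedGraph, s: str, t: str, params: ProximityParams
) -> ProximityEstimate:
    """MC estimate of the two-terminal reliability p_r(s, t)."""
    rel, se, _, _ = _mc_reliability_erd(wg, s, t, params)
    return ProximityEstimate(rel, RELIABILITY, std_error=se, seed=params.seed)


def expected_reliable_distance(
    wg: WeightedGraph, s: str, t: str, params: ProximityParams
) -> ProximityEstimate:
    """MC estimate of E[hop distance | s,t connected in the realization].

    Undefined (``defined=False``) when no sampled realization connects the
    pair.
    """
    _, _, erd, ok = _mc_reliability_erd(wg, s, t, params)
    if not ok:
        return ProximityEstimate(math.nan, ERD, seed=params.seed, defined=False)
    return ProximityEstimate(erd, ERD, seed=params.seed)


def exact_reliability_oracle(
    wg: WeightedGraph, s: str, t: str
) -> tuple[float, float | None]:
    """Exhaustive 2^|E| enumeration of realizations (small graphs only).

    Returns (reliability, expected reliable distance or None when the pair is
    never connected).  Exact to floating point; the independent check for the
    Monte-Carlo estimators.
    """
    nodes, ui, vi, w = _edge_arrays(wg)
    idx = {n: i for i, n in enumerate(nodes)}
    for nid in (s, t):
        if nid not in idx:
            raise LookupError_(f"unknown node {nid!r}")
    m = len(w)
    if m > _ORACLE_MAX_EDGES:
        raise SizeError(f"{m} edges exceeds oracle limit {_ORACLE_MAX_EDGES}")
    si, ti = idx[s], idx[t]
    n = len(nodes)
    rel = 0.0
    wsum = 0.0
    for code in range(1 << m):
        mask = np.array([(code >> k) & 1 for k in range(m)], dtype=bool)
        pr = float(np.prod(np.where(mask, w, 1.0 - w)))
        if pr == 0.0:
            continue
        d = _st_distance(n, ui, vi, mask, si, ti)
        if d >= 0:
            rel += pr
            wsum += pr * d
    if rel == 0.0:
        return 0.0, None
    return rel, wsum / rel


# -- random walk with restart ----------------------------------------------


class _RwSolver:
    """Exact stationary-distribution solver, cached per weighted graph.

    On the subspace of non-dangling nodes the transition matrix P is
    row-stochastic, and the stationary distribution of the beta-restart walk
    rooted at s solves (I - (1-beta) P^T) pi = beta e_s.  Dangling nodes (no
    positive-weight incident edge) are unreachable in an undirected graph, so
    their stationary mass is 0 unless the root itself is dangling, in which
    case the forced-restart rule pins the walker at the root (pi = e_s).
    One sparse LU factorization serves every root.
    """

    def __init__(self, wg: WeightedGraph, beta: float):
        nodes = wg.graph.node_ids
        self.index = {n: i for i, n in enumerate(nodes)}
        self.nodes = nodes
        n = len(nodes)
        rows, cols, vals = [], [], []
        for e in wg.graph.edges():
            w = wg.w(e)
            if w <= 0.0:
                continue
            i, j = self.index[e.source], self.index[e.target]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        W = sp.csr_array((vals, (rows, cols)), shape=(n, n))
        deg = np.asarray(W.sum(axis=1)).ravel()
        self.dangling = deg <= 0.0
        live = np.flatnonzero(~self.dangling)
        self.live = live
        self.live_pos = -np.ones(n, dtype=np.int64)
        self.live_pos[live] = np.arange(live.size)
        if live.size:
            Wl = W[live][:, live]
            P = sp.diags_array(1.0 / deg[live]) @ Wl
            A = sp.eye_array(live.size, format="csc") - (1.0 - beta) * P.T.tocsc()
            self._lu = spla.splu(A.tocsc())
        else:
            self._lu = None
        self.beta = beta
        self.n = n

    def stationary(self, s: str) -> np.ndarray:
        """pi over all nodes for the walk rooted at s; sums to 1."""
        si = self.index[s]
        pi = np.zeros(self.n)
        if self.dangling[si] or self._lu is None:
            pi[si] = 1.0
            return pi
        b = np.zeros(self.live.size)
        b[self.live_pos[si]] = self.beta
        x = self._lu.solve(b)
        # splu is direct; renormalize to guard rounding at the 1e-12 level
        x = np.maximum(x, 0.0)
        total = x.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ArithmeticError("random-walk stationary solve failed to normalize")
        pi[self.live] = x / total
        return pi


def rw_solver(wg: WeightedGraph, beta: float) -> _RwSolver:
    """Fetch (or build and cache) the exact solver for this graph and beta."""
    key = ("rw_solver", beta)
    solver = wg.cache.get(key)
    if solver is None:
        solver = _RwSolver(wg, beta)
        wg.cache[key] = solver
    return solver


def _simulate_walk(
    wg: WeightedGraph, s: str, iterations: int, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Visit frequencies of an explicit beta-restart walk from s.

    Every step counts as a visit, restarts included; a dangling position
    forces a restart.
    """
    g = wg.graph
    nodes = g.node_ids
    index = {n: i for i, n in enumerate(nodes)}
    nbrs: list[np.ndarray] = []
    cum: list[np.ndarray] = []
    for nid in nodes:
        pairs = [(index[ie.neighbor], wg.w(ie.edge)) for ie in g.incident(nid) if wg.w(ie.edge) > 0.0]
        if pairs:
            arr = np.array([p[0] for p in pairs], dtype=np.int64)
            wts = np.array([p[1] for p in pairs], dtype=float)
            nbrs.append(arr)
            cum.append(np.cumsum(wts) / wts.sum())
        else:
            nbrs.append(np.empty(0, dtype=np.int64))
            cum.append(np.empty(0))
    visits = np.zeros(len(nodes), dtype=np.int64)
    si = index[s]
    pos = si
    restart_draws = rng.random(iterations)
    move_draws = rng.random(iterations)
    for k in range(iterations):
        if restart_draws[k] < beta or nbrs[pos].size == 0:
            pos = si
        else:
            c = cum[pos]
            pos = int(nbrs[pos][np.searchsorted(c, move_draws[k], side="right")])
        visits[pos] += 1
    return visits / iterations


def random_walk_proximity(
    wg: WeightedGraph, s: str, t: str, params: ProximityParams
) -> ProximityEstimate:
    """Symmetric random-walk-with-restart proximity.

    d_RW(s,t) = (d'(s,t) + d'(t,s)) / 2 where d'(s,.) is the stationary
    distribution of the beta-restart walk rooted at s.
    """
    for nid in (s, t):
        wg.graph.node(nid)
    if params.rw_method == "exact":
        solver = rw_solver(wg, params.beta)
        pi_s = solver.stationary(s)
        if s == t:
            return ProximityEstimate(float(pi_s[solver.index[t]]), RANDOM_WALK)
        pi_t = solver.stationary(t)
        val = 0.5 * (pi_s[solver.index[t]] + pi_t[solver.index[s]])
        return ProximityEstimate(float(val), RANDOM_WALK)
    rng = np.random.default_rng(params.seed)
    nodes = wg.graph.node_ids
    index = {n: i for i, n in enumerate(nodes)}
    f_st = _simulate_walk(wg, s, params.rw_iterations, params.beta, rng)[index[t]]
    if s == t:
        val = f_st
    else:
        f_ts = _simulate_walk(wg, t, params.rw_iterations, params.beta, rng)[index[s]]
        val = 0.5 * (f_st + f_ts)
    se = math.sqrt(val * (1 - val) / params.rw_iterations)
    return ProximityEstimate(float(val), RANDOM_WALK, std_error=se, seed=params.seed)


# -- dispatch and batch ----------------------------------------------------


def proximity(wg: WeightedGraph, s: str, t: str, params: ProximityParams) -> ProximityEstimate:
    """Compute the proximity named by ``params.measure`` for one pair."""
    if params.measure == BEST_PATH:
        return ProximityEstimate(best_path_probability(wg, s, t), BEST_PATH)
    if params.measure == RELIABILITY:
        if s == t:
            return ProximityEstimate(1.0, RELIABILITY)
        return network_reliability(wg, s, t, params)
    if params.measure == ERD:
        if s == t:
            return ProximityEstimate(0.0, ERD)
        return expected_reliable_distance(wg, s, t, params)
    return random_walk_proximity(wg, s, t, params)


def proximity_matrix(
    wg: WeightedGraph, nodes: Sequence[str], params: ProximityParams
) -> np.ndarray:
    """Symmetric matrix of pairwise proximities over ``nodes``.

    The diagonal is the self-proximity for the random walk and 1.0 for the
    probabilistic measures (0.0 for ERD, whose self-distance is zero).  For
    the exact random walk one stationary solve per node fills a full row.
    """
    for nid in nodes:
        wg.graph.node(nid)
    k = len(nodes)
    M = np.zeros((k, k))
    if params.measure == RANDOM_WALK and params.rw_method == "exact":
        solver = rw_solver(wg, params.beta)
        cols = np.array([solver.index[n] for n in nodes])
        D = np.vstack([solver.stationary(n)[cols] for n in nodes])
        M = 0.5 * (D + D.T)
        return M
    for i in range(k):
        for j in range(i, k):
            if i == j:
                if params.measure == RANDOM_WALK:
                    M[i, i] = random_walk_proximity(wg, nodes[i], nodes[i], params).value
                elif params.measure == ERD:
                    M[i, i] = 0.0
                else:
                    M[i, i] = 1.0
                continue
            seed = None if params.seed is None else params.seed + 1_009 * i + j
            est = proximity(wg, nodes[i], nodes[j], replace(params, seed=seed))
            M[i, j] = M[j, i] = est.value
    return M
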
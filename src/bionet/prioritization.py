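"""Candidate-gene prioritization from pairwise proximities.

Given a candidate set S (e.g. top hits of an association study) and a
pairwise proximity matrix, three classifiers are provided:

* **supervised** — rank each candidate by its mean proximity to a reference
  set S_R of known disease genes;
* **KNN** — rank each candidate by its mean proximity to its k nearest
  other candidates (unsupervised; default k = 4);
* **cluster-based** — select the single subset maximizing
  sum over ordered internal pairs of (p(s,t) - q), found by best-improvement
  greedy search with random restarts.  The sensitivity q sets how proximal a
  gene must be, on average, to the rest of the cluster to be included.

An evaluation-only leave-one-out protocol scores positives against the other
positives and negatives against the average over all size-(|S_P|-1) subsets
of S_P, so every candidate is scored with the same reference-set size.  The
cluster classifier is evaluated with a pseudo-ROC: per-case TPR/FPR averaged
across cases at each q on a grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

DEFAULT_K = 4
DEFAULT_RESTARTS = 100


class UsageError(Exception):
    pass


@dataclass(frozen=True)
class PrioritizationCase:
    """Candidate set with optional truth split and external reference."""

    candidates: tuple[str, ...]
    truth_positive: frozenset[str] = frozenset()
    reference: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cset = set(self.candidates)
        if len(cset) != len(self.candidates):
            raise UsageError("duplicate candidates")
        if not self.truth_positive <= cset:
            raise UsageError("truth_positive must be a subset of the candidates")
        if cset & set(self.reference):
            raise UsageError("reference set must be disjoint from the candidates")

    @property
    def truth_negative(self) -> frozenset[str]:
        return frozenset(self.candidates) - self.truth_positive

    @classmethod
    def load(cls, path) -> "PrioritizationCase":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            tuple(d["candidates"]),
            frozenset(d.get("truth_positive", ())),
            tuple(d.get("reference", ())),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "candidates": list(self.candidates),
                    "truth_positive": sorted(self.truth_positive),
                    "reference": list(self.reference),
                },
                fh,
                indent=2,
            )


@dataclass(frozen=True)
class ClusterResult:
    cluster: frozenset[str]
    score: float
    sensitivity_q: float
    restarts_used: int
    seed: int | None


class ProximityTable:
    """Symmetric proximity lookup over a fixed node list."""

    def __init__(self, nodes: Sequence[str], matrix: np.ndarray):
        if matrix.shape != (len(nodes), len(nodes)):
            raise UsageError("matrix shape does not match node list")
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.matrix = np.asarray(matrix, dtype=float)

    def p(self, s: str, t: str) -> float:
        return float(self.matrix[self.index[s], self.index[t]])


# -- scoring classifiers ---------------------------------------------------


def supervised_scores(
    prox: ProximityTable, case: PrioritizationCase
) -> dict[str, float]:
    """Mean proximity of each candidate to the reference set S_R."""
    if not case.reference:
        raise UsageError("supervised classifier needs a non-empty reference set")
    ref_idx = [prox.index[t] for t in case.reference]
    return {
        s: float(prox.matrix[prox.index[s], ref_idx].mean()) for s in case.candidates
    }


def loo_supervised_scores(
    prox: ProximityTable, case: PrioritizationCase
) -> dict[str, float]:
    """Leave-one-out supervised protocol (evaluation only).

    Each positive p is scored against S_P \\ {p}.  Each negative is scored as
    the exact average over all |S_P| subsets of size |S_P| - 1, which uses
    every subset equally often, so positives and negatives see reference sets
    of identical size.
    """
    sp = sorted(case.truth_positive)
    if len(sp) < 2:
        raise UsageError("leave-one-out protocol needs at least 2 positives")
    scores: dict[str, float] = {}
    for s in case.candidates:
        if s in case.truth_positive:
            ref = [p for p in sp if p != s]
            scores[s] = float(np.mean([prox.p(s, t) for t in ref]))
        else:
            subset_means = [
                np.mean([prox.p(s, t) for t in subset])
                for subset in combinations(sp, len(sp) - 1)
            ]
            scores[s] = float(np.mean(subset_means))
    return scores


def knn_scores(
    prox: ProximityTable, case: PrioritizationCase, k: int = DEFAULT_K
) -> dict[str, float]:
    """Mean proximity of each candidate to its k nearest other candidates."""
    n = len(case.candidates)
    if not 1 <= k <= n - 1:
        raise UsageError(f"k={k} out of range for {n} candidates")
    scores: dict[str, float] = {}
    for s in case.candidates:
        others = np.array([prox.p(s, t) for t in case.candidates if t != s])
        top = np.sort(others)[-k:]
        scores[s] = float(top.mean())
    return scores


def threshold_classify(
    scores: Mapping[str, float], cutoff: float
) -> tuple[set[str], set[str]]:
    """Split candidates at the score cutoff (>= is positive)."""
    pos = {s for s, v in scores.items() if v >= cutoff}
    return pos, set(scores) - pos


# -- cluster-based classifier ----------------------------------------------


def cluster_score(prox: ProximityTable, subset: Sequence[str], q: float) -> float:
    """Sum over ordered pairs (s != t) in the subset of (p(s,t) - q).

    With a symmetric proximity this is twice the unordered-pair sum; empty
    and singleton subsets score 0.  The diagonal is never read.
    """
    idx = [prox.index[s] for s in set(subset)]
    k = len(idx)
    if k < 2:
        return 0.0
    sub = prox.matrix[np.ix_(idx, idx)]
    return float(sub.sum() - np.trace(sub) - q * k * (k - 1))


def _greedy_from(
    Mq: np.ndarray, member: np.ndarray, id_order: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Best-improvement local search from one initial membership vector.

    ``Mq`` is the (p - q) matrix with a zeroed diagonal.  attach[s] is the
    sum of Mq[s, t] over current cluster members t (self excluded by the
    zero diagonal), so toggling s changes the ordered-pair score by
    +-2 * attach[s]; the symmetric rank-one update keeps attach exact.
    ``id_order`` visits positions in node-id order for deterministic
    tie-breaks.  Every applied move strictly increases the score.
    """
    attach = Mq @ member.astype(float)
    score = float(member.astype(float) @ attach)
    while True:
        gains = np.where(member, -2.0 * attach, 2.0 * attach)
        best, best_s = 0.0, -1
        for s in id_order:
            if gains[s] > best + 1e-12:
                best, best_s = float(gains[s]), s
        if best_s < 0:
            return member, score
        member[best_s] = not member[best_s]
        attach += Mq[best_s] if member[best_s] else -Mq[best_s]
        score += best


def cluster_select(
    prox: ProximityTable,
    candidates: Sequence[str],
    q: float,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
) -> ClusterResult:
    """Greedy multi-restart search for the best-scoring single cluster.

    Each restart initializes membership by independent fair coin flips, then
    repeatedly applies the single-element move (into or out of the cluster)
    with the largest score improvement until none improves; the best terminal
    state across restarts is returned.  The empty cluster (score 0) is
    admissible.  Ties in move selection break toward the smallest node id.
    """
    if restarts < 1:
        raise UsageError("restarts must be >= 1")
    cand = list(candidates)
    idx = [prox.index[s] for s in cand]
    Mq = prox.matrix[np.ix_(idx, idx)] - q
    np.fill_diagonal(Mq, 0.0)
    n = len(cand)
    id_order = sorted(range(n), key=lambda i: cand[i])
    rng = np.random.default_rng(seed)

    best_member = np.zeros(n, dtype=bool)
    best_score = 0.0
    for _ in range(restarts):
        member = rng.random(n) < 0.5
        member, score = _greedy_from(Mq, member, id_order)
        if score > best_score + 1e-12:
            best_member, best_score = member.copy(), score
    cluster = frozenset(cand[i] for i in np.flatnonzero(best_member))
    # recompute from scratch so the reported score is the definition, not the trajectory
    final = cluster_score(prox, list(cluster), q)
    return ClusterResult(cluster, final, q, restarts, seed)


def cluster_exhaustive(
    prox: ProximityTable, candidates: Sequence[str], q: float
) -> tuple[frozenset[str], float]:
    """Exact optimum by 2^|S| enumeration (test oracle; |S| <= ~20)."""
    cand = list(candidates)
    idx = [prox.index[s] for s in cand]
    M = prox.matrix[np.ix_(idx, idx)] - q
    M = M.copy()
    np.fill_diagonal(M, 0.0)
    n = len(cand)
    if n > 20:
        raise UsageError("exhaustive search limited to 20 candidates")
    codes = np.arange(1 << n, dtype=np.int64)
    V = ((codes[:, None] >> np.arange(n)) & 1).astype(float)
    scores = np.einsum("bi,ij,bj->b", V, M, V)
    best = int(np.argmax(scores))
    members = frozenset(cand[i] for i in range(n) if (best >> i) & 1)
    return members, float(scores[best])


# -- pseudo-ROC ------------------------------------------------------------


@dataclass(frozen=True)
class PseudoRocCurve:
    """Composite (FPR, TPR) points over a q grid, ordered by q descending.

    Unlike a ranking ROC this averaged curve need not be monotone and is
    returned as-is; no AUC is attached.
    """

    points: tuple[tuple[float, float], ...]
    q_grid: tuple[float, ...]


def case_rates(case: PrioritizationCase, predicted: set[str]) -> tuple[float, float]:
    """(FPR, TPR) of a predicted-positive set against the case truth."""
    sp, sn = case.truth_positive, case.truth_negative
    tpr = len(predicted & sp) / len(sp) if sp else 0.0
    fpr = len(predicted & sn) / len(sn) if sn else 0.0
    return fpr, tpr


def cluster_pseudo_roc(
    cases: Sequence[PrioritizationCase],
    prox_tables: Sequence[ProximityTable],
    q_grid: Sequence[float],
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
) -> PseudoRocCurve:
    """Composite pseudo-ROC of the cluster classifier over a q grid.

    For each q, the cluster is selected independently on every case; each
    case yields a TPR/FPR which are averaged across cases into one composite
    point.
    """
    if not q_grid:
        raise UsageError("q grid must be non-empty")
    qs = sorted(q_grid, reverse=True)
    points = []
    for qi, q in enumerate(qs):
        fprs, tprs = [], []
        for ci, (case, prox) in enumerate(zip(cases, prox_tables)):
            s = None if seed is None else seed + 7_919 * qi + ci
            res = cluster_select(prox, case.candidates, q, restarts, s)
            fpr, tpr = case_rates(case, set(res.cluster))
            fprs.append(fpr)
            tprs.append(tpr)
        points.append((float(np.mean(fprs)), float(np.mean(tprs))))
    return PseudoRocCurve(tuple(points), tuple(qs))
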
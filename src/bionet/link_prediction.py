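"""Link prediction: pair scoring, ROC/AUC, paired AUC tests, relevance tuning.

Candidate node pairs are ranked by a proximity measure; performance is read
off a ROC curve whose AUC equals the probability that a random positive
outranks a random negative (ties credited 1/2).  Two score vectors over the
same pairs are compared with the DeLong paired placement-value test.
Relevance coefficients per edge type are tuned one at a time on a training
pair set, every other coefficient held at its default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .proximity import ERD, RANDOM_WALK, ProximityParams, proximity
from .weighting import RelevanceMap, WeightingConfig, apply_weights
from .graph_model import HeteroGraph

log = logging.getLogger(__name__)

POSITIVE = 1
NEGATIVE = 0


class EvaluationError(Exception):
    pass


class SamplingError(Exception):
    pass


def _canon(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LabeledPairSet:
    """Unordered node pairs with binary labels (1 positive, 0 negative)."""

    pairs: tuple[tuple[str, str, int], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a, b, lab in self.pairs:
            key = _canon((a, b))
            if key in seen:
                raise EvaluationError(f"duplicate pair {key}")
            seen.add(key)
            if lab not in (POSITIVE, NEGATIVE):
                raise EvaluationError(f"label must be 0/1, got {lab!r}")

    @classmethod
    def from_lists(cls, positives, negatives, provenance: str = "") -> "LabeledPairSet":
        rows = [(*_canon(tuple(p)), POSITIVE) for p in positives]
        rows += [(*_canon(tuple(p)), NEGATIVE) for p in negatives]
        return cls(tuple(rows), provenance)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs])

    def pair_keys(self) -> list[tuple[str, str]]:
        return [_canon((a, b)) for a, b, _ in self.pairs]

    @classmethod
    def load(cls, path, provenance: str = "") -> "LabeledPairSet":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("node1\t"):
                    continue
                a, b, lab = line.split("\t")[:3]
                rows.append((*_canon((a, b)), int(lab)))
        return cls(tuple(rows), provenance or str(path))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node1\tnode2\tlabel\n")
            for a, b, lab in self.pairs:
                fh.write(f"{a}\t{b}\t{lab}\n")


@dataclass(frozen=True)
class RocCurve:
    points: tuple[tuple[float, float], ...]
    auc: float


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    p_value: float


# -- scoring ---------------------------------------------------------------


def score_pairs(
    wg, pairs: LabeledPairSet, params: ProximityParams
) -> list[tuple[tuple[str, str], float]]:
    """One proximity score per labeled pair, in input order.

    A pair with a node absent from the graph scores 0 (and is logged):
    candidate lists routinely reference entities the graph does not index,
    and silently dropping them would bias the AUC.
    """
    out = []
    for i, (a, b, _) in enumerate(pairs.pairs):
        if a not in wg.graph or b not in wg.graph:
            log.warning("pair (%s, %s) has a node missing from the graph; scored 0", a, b)
            out.append(((a, b), 0.0))
            continue
        seed = None if params.seed is None else params.seed + i
        est = proximity(wg, a, b, replace(params, seed=seed))
        val = est.value
        if params.measure == ERD:
            # ERD is a distance: shorter means closer, so rank by its negative
            val = -val if est.defined else -np.inf
        out.append(((a, b), float(val)))
    return out


# -- ROC / AUC -------------------------------------------------------------


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted 1/2."""
    pos = scores[labels == POSITIVE]
    neg = scores[labels == NEGATIVE]
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("AUC needs at least one positive and one negative")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (pos.size * neg.size)


def roc_auc(
    scored: Sequence[tuple[tuple[str, str], float]], pairs: LabeledPairSet
) -> RocCurve:
    """ROC curve by descending score, tied scores as one diagonal segment.

    The reported AUC is the trapezoidal area, which with grouped ties equals
    the Mann-Whitney statistic with half-credit for ties.
    """
    by_key = {_canon(k): v for k, v in scored}
    keys = pairs.pair_keys()
    if set(by_key) != set(keys):
        raise EvaluationError("scores do not cover the labeled pairs")
    scores = np.array([by_key[k] for k in keys], dtype=float)
    labels = pairs.labels
    n_pos = int((labels == POSITIVE).sum())
    n_neg = int((labels == NEGATIVE).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both classes")

    points = [(0.0, 0.0)]
    tp = fp = 0
    for s in sorted(set(scores), reverse=True):
        grp = labels[scores == s]
        tp += int((grp == POSITIVE).sum())
        fp += int((grp == NEGATIVE).sum())
        points.append((fp / n_neg, tp / n_pos))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocCurve(tuple(map(tuple, points)), auc)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per positive, V01 per negative."""
    pos = scores[labels == POSITIVE]
    neg = scores[labels == NEGATIVE]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), cmp.mean(axis=0)


def compare_auc(
    scored_a: Sequence[tuple[tuple[str, str], float]],
    scored_b: Sequence[tuple[tuple[str, str], float]],
    pairs: LabeledPairSet,
) -> AucComparison:
    """Paired nonparametric AUC comparison (DeLong covariance of placements).

    Both score lists must cover the same labeled pairs.  Returns both AUCs
    and the two-sided p-value of the AUC difference; identical scores give
    p = 1.
    """
    keys = pairs.pair_keys()
    a_map = {_canon(k): v for k, v in scored_a}
    b_map = {_canon(k): v for k, v in scored_b}
    if set(a_map) != set(keys) or set(b_map) != set(keys):
        raise EvaluationError("score lists must cover the same labeled pairs")
    sa = np.array([a_map[k] for k in keys], dtype=float)
    sb = np.array([b_map[k] for k in keys], dtype=float)
    labels = pairs.labels

    v10a, v01a = _placements(sa, labels)
    v10b, v01b = _placements(sb, labels)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = v10a.size, v01a.size

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 0.0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return AucComparison(auc_a, auc_b, min(p, 1.0))


# -- negative sampling -----------------------------------------------------


def sample_negative_pairs(
    positives: Iterable[tuple[str, str]],
    n: int,
    excluded: Callable[[tuple[str, str]], bool] | None = None,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Uniform negatives from random pairings of nodes seen in the positives.

    Pairing nodes that already occur among positives keeps the negatives as
    well-studied as the positives, so the task is not made artificially easy.
    The positives themselves and any pair matching ``excluded`` are never
    returned.
    """
    pos = {_canon(tuple(p)) for p in positives}
    support = sorted({x for p in pos for x in p})
    admissible = [
        pr
        for pr in combinations(support, 2)
        if pr not in pos and not (excluded is not None and excluded(pr))
    ]
    if len(admissible) < n:
        raise SamplingError(
            f"only {len(admissible)} admissible negative pairs, need {n}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(admissible), size=n, replace=False)
    return [admissible[i] for i in sorted(pick)]


# -- one-at-a-time relevance tuning ----------------------------------------

#: Minimum training-AUC improvement for a tuned relevance to replace default.
TUNING_TOLERANCE = 0.002


@dataclass(frozen=True)
class TuningReport:
    selected: RelevanceMap
    profiles: dict[str, dict[float, float]] = field(compare=False)
    baseline_auc: float = 0.0
    tuned_auc: float = 0.0


def _train_auc(
    graph: HeteroGraph,
    relevance: RelevanceMap,
    config: WeightingConfig,
    train: LabeledPairSet,
    params: ProximityParams,
) -> float:
    wg = apply_weights(graph, replace(config, relevance=relevance))
    scored = score_pairs(wg, train, params)
    return roc_auc(scored, train).auc


def tune_relevances(
    graph: HeteroGraph,
    train: LabeledPairSet,
    edge_types: Sequence[str],
    grid: Sequence[float],
    pinned: RelevanceMap | None = None,
    params: ProximityParams | None = None,
    config: WeightingConfig | None = None,
    tolerance: float = TUNING_TOLERANCE,
) -> TuningReport:
    """One-at-a-time relevance search maximizing training AUC.

    With the pinned coefficients applied (e.g. ``codes_for`` fixed at 10),
    each listed edge type is varied over ``grid`` while every other type sits
    at the default, and is assigned its AUC-maximizing value — or left at
    default when the best improvement over the pinned baseline is below
    ``tolerance``.  The heuristic deliberately ignores interactions between
    edge types; as a guard, if the combined map scores below the pinned
    baseline on the training pairs, the baseline map is returned.
    """
    if not grid:
        raise EvaluationError("empty tuning grid")
    if any(v < 0 for v in grid):
        raise EvaluationError("tuning grid must be non-negative")
    pinned = pinned or RelevanceMap()
    params = params or ProximityParams()
    if config is None:
        # the random walk uses the uncapped product; probabilistic measures
        # need capped weights
        config = WeightingConfig(cap=params.measure != RANDOM_WALK)

    baseline_auc = _train_auc(graph, pinned, config, train, params)
    profiles: dict[str, dict[float, float]] = {}
    selected = pinned
    for etype in edge_types:
        prof: dict[float, float] = {}
        for v in grid:
            prof[v] = _train_auc(graph, pinned.with_value(etype, v), config, train, params)
        profiles[etype] = prof
        best_v = max(prof, key=lambda v: (prof[v], -abs(v - 1.0)))
        if prof[best_v] - baseline_auc >= tolerance:
            selected = selected.with_value(etype, best_v)
            log.info("edge type %s tuned to %g (train AUC %.4f)", etype, best_v, prof[best_v])
        else:
            log.info("edge type %s left at default (no noticeable effect)", etype)

    tuned_auc = _train_auc(graph, selected, config, train, params)
    if tuned_auc < baseline_auc:
        log.info("combined tuned map underperforms baseline; keeping baseline")
        selected, tuned_auc = pinned, baseline_auc
    return TuningReport(selected, profiles, baseline_auc, tuned_auc)
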
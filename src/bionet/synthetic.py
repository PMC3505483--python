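"""Synthetic heterogeneous graphs with planted links and gene families.

The generator emulates the structure of an integrated biological database
graph: typed nodes (genes, proteins, pathways, articles) with heavy-tailed
degree distributions produced by preferential attachment, typed edges whose
reliabilities are 1.0 for curated relations and Beta-distributed for
predicted associations, plus two kinds of planted ground truth:

* **gene families** — groups of genes wired to shared dedicated pathway
  nodes, so family members are mutually proximal through multi-hop paths
  (shared annotations), not necessarily direct edges;
* **future links** — a fraction of the direct within-family gene-gene edges
  is removed from the visible graph and held out as positive pairs for link
  prediction, emulating relations that enter the database only in a later
  version.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph_model import EdgeTypeRegistry, HeteroGraph, NodeTypeRegistry
from .link_prediction import LabeledPairSet, SamplingError, sample_negative_pairs
from .prioritization import PrioritizationCase


class GeneratorError(Exception):
    pass


@dataclass(frozen=True)
class EdgeSpec:
    """Background edges of one type: endpoints, count, skew, reliability.

    Endpoint nodes are chosen with probability proportional to
    (degree + 1)^skew, so positive skew yields heavy-tailed (hub-dominated)
    degree distributions.  ``reliability`` is ``("fixed", v)`` or
    ``("beta", a, b)``.
    """

    edge_type: str
    source_type: str
    target_type: str
    count: int
    skew: float = 1.0
    reliability: tuple = ("fixed", 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    node_counts: dict[str, int]
    edge_specs: tuple[EdgeSpec, ...]
    n_families: int = 20
    family_size: int = 8
    n_family_pathways: int = 2
    intra_family_edge_prob: float = 0.9
    cross_family_edge_prob: float = 0.03
    family_link_prob: float = 0.6
    future_link_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.intra_family_edge_prob,
            self.cross_family_edge_prob,
            self.family_link_prob,
            self.future_link_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise GeneratorError(f"probability {p} outside [0,1]")
        if any(c < 0 for c in self.node_counts.values()):
            raise GeneratorError("node counts must be non-negative")


@dataclass(frozen=True)
class PlantedTruth:
    future_links: tuple[tuple[str, str], ...]
    families: tuple[frozenset[str], ...]
    hidden_edges: tuple[tuple[str, str, str, float], ...]  # (u, v, type, rel)


#: Node-type vocabulary of the default fixture.
NODE_TYPES = NodeTypeRegistry.of("Gene", "Protein", "Pathway", "Article")

#: Edge-type vocabulary: directed types with inverses, symmetric ones self-inverse.
EDGE_TYPES = EdgeTypeRegistry.of(
    ("codes_for", "coded_by"),
    "interacts_with",
    "associated_with",
    ("participates_in", "has_participant"),
    ("refers_to", "referred_by"),
    "related_to",
)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Fixture-scale configuration: ~1,800 nodes, 6 edge types, 20 families.

    Sized so that the full pipeline (weighting, random-walk scoring,
    prioritization over many cases) runs in seconds while keeping the
    qualitative structure: hubs via preferential attachment, curated
    (reliability 1) versus predicted (Beta(4,2)) edges, and families tied
    together through shared pathway nodes.
    """
    return GeneratorConfig(
        node_counts={"Gene": 700, "Protein": 600, "Pathway": 150, "Article": 350},
        edge_specs=(
            EdgeSpec("codes_for", "Gene", "Protein", 600, 0.3, ("fixed", 1.0)),
            EdgeSpec("interacts_with", "Protein", "Protein", 500, 0.8, ("fixed", 1.0)),
            EdgeSpec("associated_with", "Protein", "Protein", 800, 0.8, ("beta", 4.0, 2.0)),
            EdgeSpec("participates_in", "Gene", "Pathway", 500, 1.0, ("fixed", 1.0)),
            EdgeSpec("refers_to", "Article", "Gene", 900, 1.0, ("fixed", 1.0)),
            EdgeSpec("related_to", "Gene", "Gene", 150, 0.5, ("fixed", 0.9)),
        ),
        n_families=20,
        family_size=8,
        seed=seed,
    )


def _draw_reliability(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "fixed":
        return float(spec[1])
    if kind == "beta":
        return float(rng.beta(spec[1], spec[2]))
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    raise GeneratorError(f"unknown reliability distribution {spec!r}")


def _pref_pick(
    ids: Sequence[str], degree: dict[str, int], skew: float, rng: np.random.Generator
) -> str:
    w = np.array([(degree[i] + 1.0) ** skew for i in ids])
    return ids[int(rng.choice(len(ids), p=w / w.sum()))]


def generate_graph(config: GeneratorConfig) -> tuple[HeteroGraph, PlantedTruth]:
    """Build the visible graph and its planted ground truth.

    Order of construction: typed nodes; family wiring (members to dedicated
    pathways, plus cross-family noise); direct within-family ``related_to``
    links, of which ``future_link_fraction`` are removed into the hidden
    truth; background edges per spec with preferential attachment.
    """
    rng = np.random.default_rng(config.seed)
    g = HeteroGraph(NODE_TYPES, EDGE_TYPES)
    by_type: dict[str, list[str]] = {}
    for ntype in sorted(config.node_counts):
        count = config.node_counts[ntype]
        ids = [f"{ntype[:4].lower()}{i:05d}" for i in range(count)]
        for nid in ids:
            g.add_node(nid, ntype)
        by_type[ntype] = ids

    for spec in config.edge_specs:
        for nt in (spec.source_type, spec.target_type):
            if nt not in by_type or not by_type[nt]:
                raise GeneratorError(
                    f"edge spec {spec.edge_type!r} references missing node type {nt!r}"
                )
        if spec.edge_type not in EDGE_TYPES:
            raise GeneratorError(f"unregistered edge type {spec.edge_type!r}")

    genes = by_type.get("Gene", [])
    pathways = by_type.get("Pathway", [])
    n_fam = config.n_families
    if n_fam * config.family_size > len(genes):
        raise GeneratorError("not enough genes for the requested families")
    if n_fam * config.n_family_pathways > len(pathways):
        raise GeneratorError("not enough pathways for the requested families")

    # -- plant families: members share dedicated pathway nodes
    families: list[frozenset[str]] = []
    fam_members = []
    for f in range(n_fam):
        members = genes[f * config.family_size : (f + 1) * config.family_size]
        fam_pws = pathways[f * config.n_family_pathways : (f + 1) * config.n_family_pathways]
        for m in members:
            for pw in fam_pws:
                if rng.random() < config.intra_family_edge_prob:
                    g.add_edge(m, pw, "participates_in", 1.0)
        families.append(frozenset(members))
        fam_members.append(members)
    # cross-family noise: random genes joining other families' pathways
    all_fam_pw = pathways[: n_fam * config.n_family_pathways]
    for gene in genes:
        for pw in all_fam_pw:
            if rng.random() < config.cross_family_edge_prob:
                g.add_edge(gene, pw, "participates_in", 1.0)

    # -- direct within-family links; a fraction is hidden as future links
    hidden: list[tuple[str, str, str, float]] = []
    future: list[tuple[str, str]] = []
    for members in fam_members:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() >= config.family_link_prob:
                    continue
                u, v = members[i], members[j]
                if rng.random() < config.future_link_fraction:
                    hidden.append((u, v, "related_to", 0.9))
                    future.append((u, v))
                else:
                    g.add_edge(u, v, "related_to", 0.9)

    # -- background edges with preferential attachment
    degree: dict[str, int] = {n: g.degree(n) for n in g.node_ids}
    hidden_pairs = {frozenset((u, v)) for u, v, _, _ in hidden}
    for spec in config.edge_specs:
        placed = 0
        attempts = 0
        while placed < spec.count and attempts < 20 * spec.count:
            attempts += 1
            u = _pref_pick(by_type[spec.source_type], degree, spec.skew, rng)
            v = _pref_pick(by_type[spec.target_type], degree, spec.skew, rng)
            if u == v or frozenset((u, v)) in hidden_pairs:
                continue
            if g.get_edge(u, v) is not None:
                continue
            g.add_edge(u, v, spec.edge_type, _draw_reliability(spec.reliability, rng))
            degree[u] += 1
            degree[v] += 1
            placed += 1
        if placed < spec.count:
            raise GeneratorError(
                f"could not place {spec.count} {spec.edge_type!r} edges "
                f"({placed} placed)"
            )

    truth = PlantedTruth(tuple(future), tuple(families), tuple(hidden))
    return g, truth


# -- test-case construction ------------------------------------------------


def make_link_cases(
    truth: PlantedTruth,
    graph: HeteroGraph,
    n_pos: int,
    n_neg: int,
    seed: int | None = None,
) -> LabeledPairSet:
    """Labeled pairs: positives from held-out future links, matched negatives.

    Negatives pair nodes occurring among the sampled positives, excluding any
    pair linked in either the visible or the hidden graph.
    """
    if len(truth.future_links) < n_pos:
        raise SamplingError(
            f"only {len(truth.future_links)} future links, need {n_pos}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(truth.future_links), size=n_pos, replace=False)
    positives = [truth.future_links[i] for i in sorted(pick)]
    hidden_pairs = {frozenset((u, v)) for u, v, _, _ in truth.hidden_edges}

    def linked(pair: tuple[str, str]) -> bool:
        u, v = pair
        if frozenset((u, v)) in hidden_pairs:
            return True
        return graph.get_edge(u, v) is not None

    neg_seed = None if seed is None else seed + 1
    negatives = sample_negative_pairs(positives, n_neg, linked, neg_seed)
    return LabeledPairSet.from_lists(positives, negatives, provenance="synthetic")


def make_prioritization_cases(
    truth: PlantedTruth,
    n_cases: int,
    n_positive: int,
    n_negative: int,
    seed: int | None = None,
) -> list[PrioritizationCase]:
    """Candidate-gene cases: positives from one family, negatives from others.

    Negatives are drawn only from other families (never from background
    genes) so that all candidates are equally well-connected and the task is
    not made easy by degree artifacts.  Families are reused round-robin when
    n_cases exceeds the family count.
    """
    fams = [sorted(f) for f in truth.families]
    if len(fams) < 2:
        raise GeneratorError("need at least 2 families")
    if any(len(f) < n_positive for f in fams):
        raise GeneratorError("family_size smaller than requested positives")
    rng = np.random.default_rng(seed)
    cases = []
    for c in range(n_cases):
        fi = c % len(fams)
        fam = fams[fi]
        others = sorted(set().union(*(fams[j] for j in range(len(fams)) if j != fi)))
        if len(others) < n_negative:
            raise GeneratorError("not enough genes in other families for negatives")
        sp = [fam[i] for i in sorted(rng.choice(len(fam), size=n_positive, replace=False))]
        sn = [others[i] for i in sorted(rng.choice(len(others), size=n_negative, replace=False))]
        cases.append(PrioritizationCase(tuple(sp + sn), frozenset(sp)))
    return cases
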
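"""Gene-interaction networks and target-centric subnetwork construction.

A :class:`GeneNetwork` is an undirected graph over gene identifiers whose
edges carry a confidence score in [0, 1] and a set of interaction-type
labels (e.g. ``"regulation"``, ``"binding"``).  Regulatory direction, when
present in the source, is kept only as a type label: neighbourhood queries
are symmetric.

The target-centric construction picks, for a target gene *T*, the objective
genes that are *T*'s direct neighbours and, for each such objective, its own
full neighbour set (which contains *T* by construction).  These neighbour
sets are the predictor sets of the per-objective regression models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Interaction type used when an edge list carries no type column.
UNSPECIFIED_TYPE = "unspecified"

#: STRING-style integer scores (0-999) are divided by this on read.
STRING_SCORE_SCALE = 1000.0


class NetworkError(ValueError):
    """Raised for invalid network queries (unknown gene, unusable target...)."""


@dataclass(frozen=True)
class TargetCentricNetwork:
    """Target gene, its objective-gene neighbours, and their neighbour sets.

    Attributes
    ----------
    target:
        The gene whose knockout is simulated.
    objectives:
        Objective genes directly linked to the target, lexicographically
        ordered so downstream sums are deterministic.
    neighbour_sets:
        For each objective, the set of its direct network neighbours (the
        predictors of its regression model).  The target is a member of
        every set because the target-objective edge exists by construction.
    """

    target: str
    objectives: tuple[str, ...]
    neighbour_sets: Mapping[str, frozenset[str]]

    @property
    def m_t(self) -> int:
        """Number of objective genes linked to the target."""
        return len(self.objectives)

    def unique_node_count(self) -> int:
        """Count distinct genes in the target-centric network.

        The union of the target, its objectives, and every objective's
        neighbour set; overlaps between neighbour sets are counted once.
        """
        nodes: set[str] = {self.target}
        nodes.update(self.objectives)
        for members in self.neighbour_sets.values():
            nodes.update(members)
        return len(nodes)


class GeneNetwork:
    """Undirected, score-weighted gene-interaction network.

    Thin wrapper over :class:`networkx.Graph` enforcing the invariants the
    pipeline relies on: no self-loops, scores in [0, 1], and a set of type
    labels per edge.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float] | tuple[str, str, float, str]],
    ) -> "GeneNetwork":
        """Build a network from ``(gene1, gene2, score[, type])`` tuples.

        Duplicate unordered pairs keep the maximum score and the union of
        type labels; self-loops are rejected.
        """
        net = cls()
        for edge in edges:
            if len(edge) == 3:
                u, v, score = edge  # type: ignore[misc]
                etype = UNSPECIFIED_TYPE
            else:
                u, v, score, etype = edge  # type: ignore[misc]
            net.add_edge(str(u), str(v), float(score), str(etype))
        return net

    def add_edge(self, u: str, v: str, score: float, etype: str = UNSPECIFIED_TYPE) -> None:
        if u == v:
            raise NetworkError(f"self-loop not allowed: {u}")
        score = _normalise_score(score)
        if self._g.has_edge(u, v):
            data = self._g[u][v]
            data["score"] = max(data["score"], score)
            data["types"] = frozenset(data["types"] | {etype})
        else:
            self._g.add_edge(u, v, score=score, types=frozenset({etype}))

    # -- basic queries -----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def edges(self) -> list[tuple[str, str, float, frozenset[str]]]:
        return [
            (u, v, d["score"], d["types"]) for u, v, d in self._g.edges(data=True)
        ]

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, gene: str) -> int:
        """Number of edges incident to ``gene``."""
        if gene not in self._g:
            raise NetworkError(f"unknown gene: {gene}")
        return self._g.degree(gene)

    def neighbours(self, gene: str) -> frozenset[str]:
        if gene not in self._g:
            raise NetworkError(f"unknown gene: {gene}")
        return frozenset(self._g.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return set(self._edge_key()) == set(other._edge_key())

    def _edge_key(self):
        for u, v, d in self._g.edges(data=True):
            a, b = sorted((u, v))
            yield (a, b, round(d["score"], 9), d["types"])

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self._g.copy())


def _normalise_score(score: float) -> float:
    """Map STRING-dialect integer scores (0-999) onto [0, 1]."""
    if score > 1.0:
        score = score / STRING_SCORE_SCALE
    if not 0.0 <= score <= 1.0:
        raise NetworkError(f"edge score out of range after normalisation: {score}")
    return score


# -- filtering -------------------------------------------------------------


def filter_by_score(net: GeneNetwork, threshold: float) -> GeneNetwork:
    """Keep edges whose combined score is at least ``threshold``.

    Nodes left without edges are dropped.  Thresholds always apply on the
    [0, 1] scale (integer STRING scores were normalised on read).
    """
    if not 0.0 <= threshold <= 1.0:
        raise NetworkError(f"threshold must be in [0, 1], got {threshold}")
    out = nx.Graph()
    for u, v, d in net.graph.edges(data=True):
        if d["score"] >= threshold:
            out.add_edge(u, v, **d)
    return GeneNetwork(out)


def filter_by_type(net: GeneNetwork, allowed_types: Iterable[str]) -> GeneNetwork:
    """Keep edges carrying at least one of ``allowed_types``; drop isolated nodes."""
    allowed = set(allowed_types)
    if not allowed:
        raise NetworkError("allowed_types must be non-empty")
    out = nx.Graph()
    for u, v, d in net.graph.edges(data=True):
        if d["types"] & allowed:
            out.add_edge(u, v, **d)
    return GeneNetwork(out)


# -- target-centric construction -------------------------------------------


def build_target_centric(
    net: GeneNetwork, target: str, objective_set: Iterable[str]
) -> TargetCentricNetwork:
    """Build the target-centric network of ``target``.

    Objectives are the members of ``objective_set`` that are direct
    neighbours of the target; each objective contributes its full neighbour
    set (containing the target).  Targets with no objective neighbour are
    untestable and raise :class:`NetworkError`.
    """
    if target not in net:
        raise NetworkError(f"unknown target: {target}")
    objectives = tuple(sorted(net.neighbours(target) & set(objective_set)))
    if not objectives:
        raise NetworkError(f"no objective neighbours for target {target}")
    neighbour_sets = {obj: net.neighbours(obj) for obj in objectives}
    return TargetCentricNetwork(target=target, objectives=objectives, neighbour_sets=neighbour_sets)


def unique_node_count(tcn: TargetCentricNetwork) -> int:
    """Distinct genes in a target-centric network (see the method on the type)."""
    return tcn.unique_node_count()


# -- degree-preserving rewiring ---------------------------------------------


def rewire(net: GeneNetwork, fraction: float, seed: int) -> GeneNetwork:
    """Randomly rewire a fraction of the edges, preserving every degree.

    Performs double-edge swaps (pick edges a-b and c-d, replace with a-d and
    c-b) rejecting swaps that would create self-loops or duplicate edges,
    until at least ``ceil(fraction * |edges|)`` edges have been replaced.
    Each successful swap replaces two edges.  Edge attributes travel with
    the endpoint ``a``/``c`` of the removed edges.

    This emulates noise in network reconstruction while holding the degree
    sequence fixed, so changes in downstream indices are attributable to the
    mis-wiring alone.
    """
    if not 0.0 <= fraction <= 1.0:
        raise NetworkError(f"fraction must be in [0, 1], got {fraction}")
    g = net.graph.copy()
    m = g.number_of_edges()
    n_to_replace = math.ceil(fraction * m)
    if n_to_replace == 0:
        return GeneNetwork(g)
    if m < 2:
        raise NetworkError("cannot rewire: need at least two edges")

    import random

    rng = random.Random(seed)
    replaced = 0
    attempts = 0
    max_attempts = 200 * max(n_to_replace, 1) + 1000
    while replaced < n_to_replace:
        attempts += 1
        if attempts > max_attempts:
            raise NetworkError("cannot rewire: no legal swaps found")
        edges = list(g.edges(data=True))
        (a, b, d1), (c, d, d2) = rng.sample(edges, 2)
        if rng.random() < 0.5:
            c, d = d, c
        # proposed new edges a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, **d1)
        g.add_edge(c, b, **d2)
        replaced += 2
    return GeneNetwork(g)


# -- I/O --------------------------------------------------------------------


def read_edge_tsv(path: str | Path) -> GeneNetwork:
    """Read a whitespace/tab-separated edge list.

    Canonical dialect: ``gene1 gene2 score [type]`` with ``#`` comments.
    The STRING ``protein.links`` dialect (header ``protein1 protein2
    combined_score``) is auto-detected; its integer scores are divided by
    1000 on read.
    """
    path = Path(path)
    net = GeneNetwork()
    with path.open() as fh:
        first = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if first:
                first = False
                lowered = [f.lower() for f in fields]
                if lowered[:2] in (["protein1", "protein2"], ["gene1", "gene2"]):
                    continue  # header row
            if len(fields) < 3:
                raise NetworkError(f"malformed edge line: {line!r}")
            u, v, score = fields[0], fields[1], float(fields[2])
            etype = fields[3] if len(fields) > 3 else UNSPECIFIED_TYPE
            net.add_edge(u, v, score, etype)
    return net


def write_edge_tsv(net: GeneNetwork, path: str | Path) -> None:
    """Write the canonical 4-column edge TSV (type column joins labels with ``|``)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene1\tgene2\tscore\ttype\n")
        for u, v, score, types in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{score:.6g}\t{'|'.join(sorted(types))}\n")
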
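"""Downstream statistics: list distances, structure clustering, rank-sum
validation, gene-set enrichment, degree-matched connectivity, and the
known-target overlap curve.

The connectivity null model scores how unusually interconnected a gene set
is: every gene is replaced by a random gene of identical network degree
(nearest available degree when no exact match exists), the set-internal
edge count of each replicate is recorded, and the empirical probability of
seeing at least the observed count estimates functional relatedness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode
from statsmodels.stats.multitest import multipletests

from .network import GeneNetwork

logger = logging.getLogger(__name__)

#: Below this product of sample sizes the exact rank-sum distribution is used.
EXACT_MW_LIMIT = 10_000


class StatsError(ValueError):
    pass


# -- list distance and structure clustering ---------------------------------


def list_distance(a: Iterable[str], b: Iterable[str]) -> int:
    """Number of mismatches between two gene lists: |union| - |intersection|."""
    sa, sb = set(a), set(b)
    return len(sa | sb) - len(sa & sb)


def cluster_structures(
    lists: Mapping[str, Sequence[str]], linkage: str = "average"
) -> TreeNode:
    """Agglomerate structures by dissimilarity of their top-gene lists.

    Pairwise distances are :func:`list_distance`; the result is a rooted
    tree with branch lengths derived from merge heights, serialisable to
    Newick via ``str(tree)`` / ``tree.write``.
    """
    names = sorted(lists)
    if len(names) < 2:
        raise StatsError("nothing to cluster: need at least 2 structures")
    if linkage not in ("average", "single", "complete"):
        raise StatsError(f"unsupported linkage: {linkage}")
    dm = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        d = list_distance(lists[names[i]], lists[names[j]])
        dm[i, j] = dm[j, i] = d
    z = hierarchy.linkage(squareform(dm, checks=False), method=linkage)
    return TreeNode.from_linkage_matrix(z, names)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


# -- rank-sum validation ------------------------------------------------------


def mann_whitney_greater(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` against ``y``.

    Defaults to the one-sided alternative that ``x`` is stochastically
    greater (the validation direction: experimentally confirmed genes are
    expected to show larger knockout effects than the background).  The
    exact U distribution is used when the samples are small and tie-free;
    otherwise the tie-corrected normal approximation.

    Returns ``(U, p)`` with U counting pairs where x beats y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# -- enrichment ---------------------------------------------------------------


@dataclass
class EnrichmentRow:
    """Hypergeometric enrichment of one annotation term, plus connectivity."""

    term: str
    term_size: int  # members of the term inside the universe
    hits: int  # members of the term inside the study set
    p_value: float
    q_value: float = float("nan")  # BH-adjusted
    connectivity_prob: float = float("nan")  # (k+1)/(n+1) empirical probability
    connectivity_freq: float = float("nan")  # raw k/n frequency
    observed_edges: int = -1
    rank_by_p: int = -1
    rank_by_connectivity: int = -1


def enrich(
    study: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    exclude: Iterable[str] | None = None,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation with BH correction.

    ``exclude`` removes genes from the study set before testing (used to
    re-test top targets after dropping the objective-category members, so
    enrichment is not dominated by the objective set itself).  Annotation
    terms are intersected with the universe; the study set must lie inside
    the universe.
    """
    universe_set = set(universe)
    study_set = set(study)
    if exclude is not None:
        study_set -= set(exclude)
    if not study_set <= universe_set:
        raise StatsError("study outside universe")
    M, N = len(universe_set), len(study_set)
    rows: list[EnrichmentRow] = []
    for term in sorted(annotation):
        members = set(annotation[term]) & universe_set
        if not members:
            continue
        K = len(members)
        hits = len(members & study_set)
        # P(X >= hits), X ~ Hypergeom(M, K, N)
        p = float(sps.hypergeom.sf(hits - 1, M, K, N))
        rows.append(EnrichmentRow(term=term, term_size=K, hits=hits, p_value=min(p, 1.0)))
    if rows:
        _, q, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
        for rank, r in enumerate(
            sorted(rows, key=lambda r: (r.p_value, r.term)), start=1
        ):
            r.rank_by_p = rank
    return rows


# -- degree-matched connectivity null ----------------------------------------


def _internal_edges(net: GeneNetwork, genes: set[str]) -> int:
    members = sorted(genes)
    g = net.graph
    return sum(
        1
        for i, u in enumerate(members)
        for v in members[i + 1 :]
        if g.has_edge(u, v)
    )


def sample_degree_matched(
    net: GeneNetwork,
    genes: Sequence[str],
    rng: np.random.Generator,
    by_degree: Mapping[int, list[str]] | None = None,
) -> set[str]:
    """One degree-matched random replacement of ``genes``.

    Each gene is swapped for a uniformly drawn gene of identical degree,
    excluding the gene itself and genes already drawn into the replicate.
    When no exact-degree candidate remains the nearest available degree is
    used (logged once per call site via the caller).  The replicate's
    degree sequence therefore equals the input's whenever exact matches
    exist.
    """
    if by_degree is None:
        by_degree = _degree_index(net)
    degrees_sorted = sorted(by_degree)
    replacement: set[str] = set()
    for gene in genes:
        deg = net.degree(gene)
        candidates = [g for g in by_degree.get(deg, ()) if g != gene and g not in replacement]
        if not candidates:
            for alt in sorted(degrees_sorted, key=lambda d: (abs(d - deg), d)):
                candidates = [
                    g for g in by_degree[alt] if g != gene and g not in replacement
                ]
                if candidates:
                    logger.warning(
                        "no exact degree-%d candidate for %s; widened to degree %d",
                        deg,
                        gene,
                        alt,
                    )
                    break
        if not candidates:
            raise StatsError("network too small for degree-matched sampling")
        replacement.add(candidates[int(rng.integers(len(candidates)))])
    return replacement


def _degree_index(net: GeneNetwork) -> dict[int, list[str]]:
    by_degree: dict[int, list[str]] = {}
    for node in sorted(net.nodes):
        by_degree.setdefault(net.degree(node), []).append(node)
    return by_degree


def connectivity_score(
    net: GeneNetwork,
    gene_set: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Score set-internal connectivity against degree-matched random sets.

    Each of ``n_random`` replicates replaces every gene with a random gene
    of identical degree (the original gene itself is never re-drawn;
    replicate members are distinct).  When no exact-degree candidate
    remains, the nearest available degree is used with a logged warning.
    Returns ``(observed_internal_edges, (k+1)/(n+1) empirical probability,
    raw frequency k/n)`` where ``k`` counts replicates at least as
    connected as the observed set.
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise StatsError("empty gene set")
    if n_random < 1:
        raise StatsError("n_random must be >= 1")
    missing = [g for g in genes if g not in net]
    if missing:
        raise StatsError(f"genes outside network: {missing[:5]}")
    observed = _internal_edges(net, set(genes))

    by_degree = _degree_index(net)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_random):
        replacement = sample_degree_matched(net, genes, rng, by_degree=by_degree)
        if _internal_edges(net, replacement) >= observed:
            k += 1
    prob = (k + 1) / (n_random + 1)
    freq = k / n_random
    return observed, float(prob), float(freq)


def score_connectivity(
    rows: list[EnrichmentRow],
    net: GeneNetwork,
    annotation: Mapping[str, Iterable[str]],
    study: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
) -> list[EnrichmentRow]:
    """Fill connectivity columns for each term's study-hit gene set."""
    study_set = set(study)
    for i, row in enumerate(rows):
        genes = (set(annotation[row.term]) & study_set) & net.nodes
        if not genes:
            continue
        child = int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        obs, prob, freq = connectivity_score(net, genes, n_random=n_random, seed=child)
        row.observed_edges = obs
        row.connectivity_prob = prob
        row.connectivity_freq = freq
    return rows


def rerank_by_connectivity(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    """Reorder enrichment rows by ascending connectivity probability.

    Most-connected terms come first; ties break by p-value then term id.
    Both rank columns are (re)filled.  Terms lacking a connectivity score
    sort last.
    """
    def key(r: EnrichmentRow):
        prob = r.connectivity_prob if np.isfinite(r.connectivity_prob) else np.inf
        return (prob, r.p_value, r.term)

    ordered = sorted(rows, key=key)
    for rank, r in enumerate(ordered, start=1):
        r.rank_by_connectivity = rank
    for rank, r in enumerate(sorted(rows, key=lambda r: (r.p_value, r.term)), start=1):
        r.rank_by_p = rank
    return ordered


# -- known-target overlap curve ----------------------------------------------


def known_target_ratio_curve(
    effects: Mapping[str, float], known: Iterable[str], n_bins: int
) -> list[tuple[float, float, float]]:
    """Fraction of known targets per equal-count bin of the effect ranking.

    Genes are sorted by ascending whole-set effect and split into
    ``n_bins`` rank bins of (near-)equal size; each bin reports
    ``(effect_min, effect_max, known_fraction)``.  A rising fraction with
    effect magnitude indicates enrichment of established targets among the
    strongest predicted knockouts.
    """
    if n_bins < 1:
        raise StatsError("n_bins must be >= 1")
    known_set = set(known)
    items = sorted(effects.items(), key=lambda gv: (gv[1], gv[0]))
    if not items:
        raise StatsError("no genes to bin")
    bins = np.array_split(np.arange(len(items)), n_bins)
    out = []
    for idx in bins:
        if len(idx) == 0:
            continue
        chunk = [items[i] for i in idx]
        ratio = sum(1 for g, _ in chunk if g in known_set) / len(chunk)
        out.append((chunk[0][1], chunk[-1][1], float(ratio)))
    return out


# -- GMT and table I/O --------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: ``term<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise StatsError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with Path(path).open("w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sets[term])
            fh.write(f"{term}\t{description}\t{genes}\n")


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term\tsize\thits\tp\tq\tconnectivity_prob\trank_p\trank_conn\n")
        for r in rows:
            fh.write(
                f"{r.term}\t{r.term_size}\t{r.hits}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{r.connectivity_prob:.6g}\t{r.rank_by_p}\t{r.rank_by_connectivity}\n"
            )
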
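"""Synthetic networks, expression matrices, and annotations with known truth.

Every stage of the pipeline is testable without external downloads:

- :func:`make_network` draws a preferential-attachment graph, so degrees
  are heavy-tailed like real interaction networks, and labels a fraction
  of nodes as the objective set.
- :func:`make_expression` plants, for each objective gene, a linear model
  of its expression on its network neighbours and generates area-wise
  expression from it, with relative Gaussian noise.  Planted
  structure-specific targets have their target-to-objective coefficients
  scaled per structure, so the fold-change and rank-specificity indices
  should recover the planted structure ordering.
- :func:`nod1_fixture` reproduces a published worked example of the
  target-centric construction (target NOD1, six caspase-pathway objective
  neighbours) with exact neighbour-set sizes and overlap counts.
- :func:`make_annotation` builds random gene-set annotations, optionally
  with one planted term exactly matching a study set.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import GeneNetwork


class SyntheticError(ValueError):
    pass


#: Share of an objective's mean signal contributed by a planted
#: structure-specific target (see the comment in :func:`make_expression`).
PLANTED_COEF_SHARE = 0.25


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic expression matrix."""

    coefficients: dict[tuple[str, str], float]  # (objective, predictor) -> k
    intercepts: dict[str, float]
    noise_sd: float  # relative (fraction of the clean signal)
    structure_multipliers: dict[tuple[str, str], float]  # (target, structure) -> scale
    seed: int


def make_network(
    n_genes: int,
    mean_degree: float = 4.0,
    objective_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[GeneNetwork, set[str]]:
    """Heavy-tailed random network plus a random objective gene set.

    Preferential attachment with ``m = round(mean_degree / 2)`` new edges
    per node gives the hub-dominated degree distribution typical of gene
    networks.  Edge scores are uniform in [0.9, 1.0] (all above the usual
    high-confidence threshold) and typed ``"regulation"``.
    """
    if n_genes < 10:
        raise SyntheticError("n_genes must be >= 10")
    m = max(1, round(mean_degree / 2))
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31)))
    width = len(str(n_genes - 1))
    names = {i: f"G{i:0{width}d}" for i in g.nodes}
    net = GeneNetwork()
    for u, v in sorted(g.edges()):
        net.add_edge(names[u], names[v], 0.9 + 0.1 * float(rng.random()), "regulation")
    n_obj = round(objective_fraction * n_genes)
    all_names = sorted(names.values())
    objectives = set(rng.choice(all_names, size=n_obj, replace=False)) if n_obj else set()
    return net, {str(o) for o in objectives}


def make_expression(
    net: GeneNetwork,
    objectives: Iterable[str],
    n_areas: int = 300,
    n_structures: int = 3,
    noise_sd: float = 0.02,
    structure_multipliers: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate expression satisfying planted per-objective linear models.

    Non-objective genes get i.i.d. lognormal base expression (median ~5).
    Each objective's expression is a planted positive-coefficient linear
    combination of its non-objective neighbours plus an intercept and
    relative Gaussian noise of standard deviation ``noise_sd`` (so the CV
    relative error of a correctly specified model is ~``noise_sd``).
    Structure labels are ``s1 .. s<n_structures>``, assigned to areas in
    contiguous equal blocks; ``structure_multipliers[(target, structure)]``
    scales that target's coefficient inside every objective model for the
    areas of that structure, planting a structure-specific knockout effect.

    Values that come out non-positive are re-drawn (noise only), never
    clipped, preserving the planted linear relationship in expectation.
    """
    objectives = sorted(set(objectives))
    if n_structures < 2 or n_areas < n_structures:
        raise SyntheticError("need n_areas >= n_structures >= 2")
    multipliers = dict(structure_multipliers or {})
    rng = np.random.default_rng(seed)

    areas = [f"p{i:04d}" for i in range(n_areas)]
    structures = [f"s{i + 1}" for i in range(n_structures)]
    blocks = np.array_split(np.arange(n_areas), n_structures)
    area_structure = {}
    for s, idx in zip(structures, blocks):
        for i in idx:
            area_structure[areas[i]] = s
    area_struct_arr = np.array([area_structure[a] for a in areas])

    genes = sorted(net.nodes)
    obj_set = set(objectives)
    base_genes = [g for g in genes if g not in obj_set]

    values = pd.DataFrame(
        index=pd.Index(genes, name="gene"), columns=areas, dtype=float
    )
    for g in base_genes:
        values.loc[g] = rng.lognormal(mean=np.log(5.0), sigma=0.5, size=n_areas)

    coefficients: dict[tuple[str, str], float] = {}
    intercepts: dict[str, float] = {}
    for obj in objectives:
        predictors = sorted(g for g in net.neighbours(obj) if g not in obj_set)
        if not predictors:
            # isolated among objectives: plain base expression, no planted model
            values.loc[obj] = rng.lognormal(mean=np.log(5.0), sigma=0.5, size=n_areas)
            continue
        ks = rng.uniform(0.5, 1.5, size=len(predictors)) / len(predictors)
        k0 = float(rng.uniform(1.0, 5.0))
        X = values.loc[predictors].to_numpy(dtype=float)  # preds x areas
        # Planted structure-specific targets contribute a fixed share of the
        # objective's signal: strong enough that the knockout effect stands
        # out, yet small enough that the structure-varying term leaves a
        # single global linear fit within the usual CV exclusion threshold
        # (worst-structure misfit ~ (4/3)c/(1+3c) for share c, multiplier 3).
        planted_targets = {t for (t, _) in multipliers}
        planted_idx = [i for i, p in enumerate(predictors) if p in planted_targets]
        if planted_idx:
            others = [i for i in range(len(predictors)) if i not in planted_idx]
            base_mean = float((ks[others, None] * X[others]).sum(axis=0).mean()) + k0
            for i in planted_idx:
                ks[i] = PLANTED_COEF_SHARE * base_mean / float(X[i].mean())
        coef_matrix = np.repeat(ks[:, None], n_areas, axis=1)
        for i, pred in enumerate(predictors):
            coefficients[(obj, pred)] = float(ks[i])
            for s in structures:
                mult = multipliers.get((pred, s))
                if mult is not None:
                    coef_matrix[i, area_struct_arr == s] = ks[i] * mult
        clean = (coef_matrix * X).sum(axis=0) + k0
        intercepts[obj] = k0
        noisy = _add_relative_noise(clean, noise_sd, rng)
        values.loc[obj] = noisy
    matrix = ExpressionMatrix(values=values, area_structure=area_structure)
    truth = GroundTruth(
        coefficients=coefficients,
        intercepts=intercepts,
        noise_sd=noise_sd,
        structure_multipliers=multipliers,
        seed=seed,
    )
    return matrix, truth


def _add_relative_noise(clean: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    """Add Normal(0, noise_sd * clean) noise, re-drawing non-positive results."""
    if noise_sd == 0:
        if np.any(clean <= 0):
            raise SyntheticError("planted clean signal is non-positive")
        return clean.copy()
    out = clean + rng.normal(0.0, noise_sd * np.abs(clean))
    for _ in range(100):
        bad = out <= 1e-6
        if not bad.any():
            return out
        out[bad] = clean[bad] + rng.normal(0.0, noise_sd * np.abs(clean[bad]))
    raise SyntheticError("could not generate positive expression; lower noise_sd")


# -- the published worked example --------------------------------------------

#: Objective genes of the NOD1 worked example, in published order, with the
#: published size of each one's neighbour set (target included).
NOD1_OBJECTIVE_SIZES = (
    ("CASP1", 27),
    ("CASP8", 56),
    ("CASP9", 25),
    ("CARD6", 3),
    ("CCK", 141),
    ("RIPK2", 38),
)


def nod1_fixture() -> tuple[GeneNetwork, set[str]]:
    """Deterministic network reproducing the NOD1 worked example.

    Target ``NOD1`` has six objective neighbours with neighbour-set sizes
    (27, 56, 25, 3, 141, 38): multiset total 290, distinct nodes 219.  The
    overlap is realised by NOD1 belonging to all six sets, 50 filler genes
    shared between the CCK and CASP8 sets, and 22 fillers shared between
    the CCK and RIPK2 sets (5 + 50 + 22 = 71 repeated occurrences).
    """
    net = GeneNetwork()
    score, etype = 0.95, "binding"
    for obj, _ in NOD1_OBJECTIVE_SIZES:
        net.add_edge("NOD1", obj, score, etype)

    shared_casp8 = [f"SHA{i:03d}" for i in range(50)]  # CCK & CASP8
    shared_ripk2 = [f"SHB{i:03d}" for i in range(22)]  # CCK & RIPK2
    extra = {
        "CASP1": [f"FCASP1_{i:03d}" for i in range(26)],
        "CASP8": shared_casp8 + [f"FCASP8_{i:03d}" for i in range(5)],
        "CASP9": [f"FCASP9_{i:03d}" for i in range(24)],
        "CARD6": [f"FCARD6_{i:03d}" for i in range(2)],
        "CCK": shared_casp8 + shared_ripk2 + [f"FCCK_{i:03d}" for i in range(68)],
        "RIPK2": shared_ripk2 + [f"FRIPK2_{i:03d}" for i in range(15)],
    }
    for obj, fillers in extra.items():
        for filler in fillers:
            net.add_edge(obj, filler, score, etype)
    objectives = {obj for obj, _ in NOD1_OBJECTIVE_SIZES}
    return net, objectives


def make_annotation(
    universe: Iterable[str],
    n_terms: int = 10,
    term_size_range: tuple[int, int] = (5, 20),
    planted_term: Iterable[str] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random annotation terms over ``universe``, plus an optional planted term.

    The planted term (id ``"planted"``) equals the given gene set exactly,
    guaranteeing it the minimal enrichment p-value when that set is the
    study set.
    """
    universe = sorted(set(universe))
    lo, hi = term_size_range
    if hi > len(universe):
        raise SyntheticError("term sizes exceed universe")
    rng = np.random.default_rng(seed)
    annotation: dict[str, list[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        annotation[f"term{t:03d}"] = sorted(str(g) for g in members)
    if planted_term is not None:
        annotation["planted"] = sorted(set(planted_term))
    return annotation
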
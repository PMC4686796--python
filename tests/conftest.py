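import numpy as np
import pandas as pd
import pytest

import brainko as bk


@pytest.fixture
def toy_net():
    """T-O1, O1-X, O1-O2, O2-Y: the hand-enumerable target-centric example."""
    return bk.GeneNetwork.from_edges(
        [("T", "O1", 0.95), ("O1", "X", 0.95), ("O1", "O2", 0.95), ("O2", "Y", 0.95)]
    )


def _pick_planted_target(net, objectives):
    """Deterministic choice: the non-objective gene touching the most
    objectives (ties broken lexicographically), so the planted knockout acts
    through several objective models at once."""
    cand = sorted(
        g
        for g in net.nodes
        if g not in objectives and len(net.neighbours(g) & objectives) >= 2
    )
    if not cand:
        raise RuntimeError("fixture network has no suitable planted target")
    return max(cand, key=lambda g: (len(net.neighbours(g) & objectives), g))


def make_recovery_bundle(seed, noise_sd=0.02, n_areas=300, n_structures=3, multiplier=3.0):
    """Synthetic network + expression with one planted structure-specific target."""
    net, objectives = bk.make_network(
        120, mean_degree=4.0, objective_fraction=0.2, seed=seed
    )
    target = _pick_planted_target(net, objectives)
    multipliers = {(target, "s1"): multiplier}
    matrix, truth = bk.make_expression(
        net,
        objectives,
        n_areas=n_areas,
        n_structures=n_structures,
        noise_sd=noise_sd,
        structure_multipliers=multipliers,
        seed=seed,
    )
    return net, objectives, target, matrix, truth


@pytest.fixture(scope="session")
def recovery_bundle():
    return make_recovery_bundle(seed=3)


def small_matrix(data: dict[str, list[float]], structures: dict[str, str] | None = None):
    """Build an ExpressionMatrix from {gene: per-area values}."""
    df = pd.DataFrame(data).T
    df.index.name = "gene"
    areas = [f"p{i}" for i in range(df.shape[1])]
    df.columns = areas
    if structures is None:
        structures = {a: "all" for a in areas}
    return bk.ExpressionMatrix(values=df, area_structure=structures)


@pytest.fixture
def linear_matrix():
    """10 areas where E(O) = 3*E(x1) - 1*E(x2) + 1 exactly."""
    rng = np.random.default_rng(42)
    x1 = rng.uniform(4, 10, 10)
    x2 = rng.uniform(1, 4, 10)
    o = 3 * x1 - 1 * x2 + 1
    assert (o > 0).all()
    return small_matrix({"O": o.tolist(), "x1": x1.tolist(), "x2": x2.tolist()})
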
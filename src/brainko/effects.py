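"""Knockout simulation and effect / specificity indices.

Knocking out a target sets its expression to zero (activation: to any
chosen level) in every surviving objective model and re-evaluates the
predicted objective expression, holding all other predictors at their
observed values.  The per-area effect is the sum over objectives of the
absolute relative change of their expression; structure and whole-set
effects are plain averages of the per-area effect; a fold-change against
the remaining structures measures specificity; and a rank-based score
combines effect size and specificity on a common [0, 1] scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix, ExpressionError, structure_means, POSITIVITY_EPS
from .models import TargetCentricModel

logger = logging.getLogger(__name__)

BASELINE_MODES = ("observed", "predicted")


class EffectError(ValueError):
    pass


@dataclass
class EffectProfile:
    """All effect indices of one target's in-silico knockout."""

    target: str
    per_area: dict[str, float]  # R_p: per-area summed |relative change|
    per_structure: dict[str, float]  # R_s: mean of R_p within structure
    whole: float  # R_all: mean of R_p over every area
    fold_change: dict[str, float]  # FC_s: R_s / mean of other structures
    baseline_mode: str = "observed"
    fold_change_flags: dict[str, bool] | None = None  # True where FC was +inf


def simulate_perturbation(
    model: TargetCentricModel,
    matrix: ExpressionMatrix,
    target_level: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Predict objective expression with the target forced to ``target_level``.

    Returns a map (objective, area) -> predicted expression.  Predictions
    are plain linear extrapolations and may be negative; the absolute value
    in the effect index handles the sign, so no clamping is applied.
    Objective models whose predictor list lacks the target (possible after
    predictor pruning) simply reproduce their baseline prediction.
    """
    if target_level < 0:
        raise EffectError("target_level must be >= 0")
    if not model.usable:
        raise EffectError(f"target excluded: {model.target}")
    out: dict[tuple[str, str], float] = {}
    for om in model.objective_models:
        overrides = {model.target: target_level} if model.target in om.predictors else None
        pred = om.predict(matrix, overrides=overrides)
        for area, value in zip(matrix.areas, pred):
            out[(om.objective, area)] = float(value)
    return out


def effect_per_area(
    model: TargetCentricModel,
    matrix: ExpressionMatrix,
    baseline_mode: str = "observed",
    target_level: float = 0.0,
) -> dict[str, float]:
    """Per-area knockout effect: sum over objectives of |change| / observed.

    ``baseline_mode`` picks what the knockout prediction is compared to:

    - ``"observed"``: the measured objective expression (the verbatim
      definition; it entangles model misfit with the knockout effect);
    - ``"predicted"``: the model's own baseline prediction, which isolates
      the contribution of the target term from misfit.

    The denominator is always the *observed* expression, which is strictly
    positive by the matrix invariant.
    """
    if baseline_mode not in BASELINE_MODES:
        raise EffectError(f"baseline_mode must be one of {BASELINE_MODES}")
    if not model.usable:
        raise EffectError(f"target excluded: {model.target}")
    areas = matrix.areas
    total = np.zeros(len(areas))
    for om in model.objective_models:
        observed = matrix.expression(om.objective).to_numpy(dtype=float)
        if np.any(observed <= POSITIVITY_EPS):
            raise ExpressionError(f"non-positive expression for {om.objective}")
        overrides = {model.target: target_level} if model.target in om.predictors else None
        knocked = om.predict(matrix, overrides=overrides)
        baseline = observed if baseline_mode == "observed" else om.predict(matrix)
        total += np.abs(knocked - baseline) / observed
    return dict(zip(areas, total.tolist()))


def effect_summary(
    per_area: Mapping[str, float], matrix: ExpressionMatrix
) -> tuple[dict[str, float], float]:
    """Aggregate the per-area effect: per-structure means and the whole-set mean.

    The whole-set index is the unweighted mean over all areas (not a mean
    of structure means), so large structures weigh proportionally more.
    """
    per_structure = structure_means(matrix, per_area)
    whole = float(np.mean(list(per_area.values())))
    return per_structure, whole


def fold_change(per_structure: Mapping[str, float]) -> tuple[dict[str, float], dict[str, bool]]:
    """Specificity fold-change of each structure against the rest.

    FC_s = R_s / mean(R_d over d != s).  When the other-structure mean is
    zero the ratio is reported as ``+inf`` and flagged.  Returns
    ``(fold_changes, inf_flags)``.
    """
    structures = list(per_structure)
    if len(structures) < 2:
        raise EffectError("need at least two structures")
    values = np.array([per_structure[s] for s in structures], dtype=float)
    total = values.sum()
    n = len(values)
    fc: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for i, s in enumerate(structures):
        others_mean = (total - values[i]) / (n - 1)
        if others_mean == 0.0:
            fc[s] = float("inf") if values[i] > 0 else 0.0
            flags[s] = values[i] > 0
        else:
            fc[s] = float(values[i] / others_mean)
            flags[s] = False
    return fc, flags


def compute_effect_profile(
    model: TargetCentricModel,
    matrix: ExpressionMatrix,
    baseline_mode: str = "observed",
    target_level: float = 0.0,
) -> EffectProfile:
    """Run the full effect computation for one target."""
    per_area = effect_per_area(model, matrix, baseline_mode, target_level)
    per_structure, whole = effect_summary(per_area, matrix)
    fc, flags = fold_change(per_structure)
    return EffectProfile(
        target=model.target,
        per_area=per_area,
        per_structure=per_structure,
        whole=whole,
        fold_change=fc,
        baseline_mode=baseline_mode,
        fold_change_flags=flags,
    )


# -- rank-based specificity --------------------------------------------------


def rank_spec(rows: Sequence[tuple[str, float, float]]) -> pd.DataFrame:
    """Rank-combine effect size and specificity for one structure.

    ``rows`` are ``(gene, R_s, FC_s)`` for every candidate target.  Each
    axis is ranked ascending (1 = smallest; ties share the average rank)
    and normalised by the maximum rank, so the gene that tops both lists
    scores exactly 1.0.  The combined score is the mean of the two
    normalised ranks; being rank-based it is invariant to any strictly
    monotone rescaling of either axis.

    Returns a DataFrame with columns ``gene, rst, fcst, rst_rank,
    fcst_rank, rank_spec`` sorted by descending ``rank_spec``.
    """
    if not rows:
        raise EffectError("need at least one gene")
    genes = [g for g, _, _ in rows]
    rst = np.array([r for _, r, _ in rows], dtype=float)
    fcst = np.array([f for _, _, f in rows], dtype=float)
    rst_rank = rankdata(rst, method="average")
    fcst_rank = rankdata(fcst, method="average")
    norm = (rst_rank / rst_rank.max() + fcst_rank / fcst_rank.max()) / 2.0
    df = pd.DataFrame(
        {
            "gene": genes,
            "rst": rst,
            "fcst": fcst,
            "rst_rank": rst_rank,
            "fcst_rank": fcst_rank,
            "rank_spec": norm,
        }
    )
    return df.sort_values(
        ["rank_spec", "gene"], ascending=[False, True], ignore_index=True
    )


def top_n(ranking: Iterable[tuple[str, float]], n: int = 100) -> list[str]:
    """Genes with the ``n`` largest values, descending; ties break lexicographically."""
    if n < 1:
        raise EffectError("n must be >= 1")
    items = sorted(ranking, key=lambda gv: (-gv[1], gv[0]))
    if len(items) < n:
        logger.warning("top_n: only %d genes available (requested %d)", len(items), n)
    if len(items) > n and items[n - 1][1] == items[n][1]:
        logger.info("top_n: tie at the cut boundary resolved lexicographically")
    return [g for g, _ in items[:n]]


# -- tabular export ----------------------------------------------------------


def write_effect_table(
    profiles: Sequence[EffectProfile],
    rank_tables: Mapping[str, pd.DataFrame],
    path,
    normalize_by_max: bool = False,
) -> None:
    """Write ``target structure RsT FCsT RankSpec`` rows plus ``__all__`` rows.

    With ``normalize_by_max`` an extra column divides each effect by the
    table-wide maximum, giving a dimensionless 0-1 effect scale.
    """
    import pathlib

    spec_lookup: dict[tuple[str, str], float] = {}
    for structure, table in rank_tables.items():
        for _, row in table.iterrows():
            spec_lookup[(row["gene"], structure)] = float(row["rank_spec"])
    max_effect = max(
        (v for p in profiles for v in p.per_structure.values()), default=float("nan")
    )
    with pathlib.Path(path).open("w") as fh:
        header = "target\tstructure\tRsT\tFCsT\tRankSpec"
        if normalize_by_max:
            header += "\tRsT_norm"
        fh.write(header + "\n")
        for p in profiles:
            for s in sorted(p.per_structure):
                spec = spec_lookup.get((p.target, s), float("nan"))
                line = f"{p.target}\t{s}\t{p.per_structure[s]:.6g}\t{p.fold_change[s]:.6g}\t{spec:.6g}"
                if normalize_by_max:
                    line += f"\t{p.per_structure[s] / max_effect:.6g}"
                fh.write(line + "\n")
            line = f"{p.target}\t__all__\t{p.whole:.6g}\tNA\tNA"
            if normalize_by_max:
                line += f"\t{p.whole / max_effect:.6g}"
            fh.write(line + "\n")
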
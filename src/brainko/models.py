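"""Per-objective linear regression models and their cross-validated filtering.

For a target gene *T*, each objective gene gets one ordinary-least-squares
model predicting its expression across areas from the expression of its
direct network neighbours (the target among them):

    E_p(obj) = sum_i k_i * E_p(neighbour_i) + k0

Model quality is a repeated random-subsampling cross-validation error: the
areas are split 90/10, the model is fit on the training split, and the
root-mean-square of per-area *relative* prediction errors on the test split
is averaged over repetitions.  Models whose error exceeds a cutoff
(default 25%) are excluded; a target survives while at least one of its
objective models does.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix, ExpressionError
from .network import TargetCentricNetwork

logger = logging.getLogger(__name__)

DEFAULT_MAX_ERROR = 0.25
DEFAULT_TEST_FRACTION = 0.1
DEFAULT_CV_REPETITIONS = 1000


class ModelError(ValueError):
    pass


@dataclass
class ObjectiveModel:
    """OLS model of one objective gene on its neighbour predictors."""

    objective: str
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # one per predictor
    intercept: float
    cv_error: float = float("nan")  # relative error, fraction; NaN until CV'd

    def predict(
        self, matrix: ExpressionMatrix, overrides: dict[str, float] | None = None
    ) -> np.ndarray:
        """Predicted objective expression per area, optionally overriding
        the expression of some predictors (e.g. target set to zero)."""
        X = _design(matrix, self.predictors, overrides)
        return X @ self.coefficients + self.intercept


@dataclass
class TargetCentricModel:
    """All surviving objective models of one target, plus the excluded ones."""

    target: str
    objective_models: list[ObjectiveModel]
    excluded: list[tuple[str, float]] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return len(self.objective_models) > 0


def _design(
    matrix: ExpressionMatrix,
    predictors: Sequence[str],
    overrides: dict[str, float] | None = None,
) -> np.ndarray:
    cols = []
    n = len(matrix.areas)
    for gene in predictors:
        if overrides is not None and gene in overrides:
            cols.append(np.full(n, float(overrides[gene])))
        else:
            cols.append(matrix.expression(gene).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((n, 0))


def fit_objective_model(
    matrix: ExpressionMatrix, objective: str, predictors: Sequence[str]
) -> ObjectiveModel:
    """Fit one objective model by least squares over all areas.

    Singular designs (collinear predictors, or more predictors than areas)
    fall back to the minimum-norm solution of the pseudoinverse, with a
    logged warning, because large neighbour sets are routinely collinear.
    """
    if objective not in matrix.values.index:
        raise ExpressionError(f"missing gene: {objective}")
    predictors = tuple(predictors)
    y = matrix.expression(objective).to_numpy(dtype=float)
    X = _design(matrix, predictors)
    if X.shape[0] < 2:
        raise ModelError("need at least 2 areas to fit")
    A = np.column_stack([X, np.ones(len(y))])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        logger.warning(
            "singular design for objective %s (%d predictors, %d areas): "
            "minimum-norm solution used",
            objective,
            len(predictors),
            len(y),
        )
    return ObjectiveModel(
        objective=objective,
        predictors=predictors,
        coefficients=coef[:-1],
        intercept=float(coef[-1]),
    )


def cross_validate(
    matrix: ExpressionMatrix,
    objective: str,
    predictors: Sequence[str],
    test_fraction: float = DEFAULT_TEST_FRACTION,
    repetitions: int = DEFAULT_CV_REPETITIONS,
    seed: int = 0,
) -> float:
    """Repeated random-subsampling CV relative error of one objective model.

    Each repetition draws a test set of ``ceil(test_fraction * n)`` areas
    without replacement, fits on the rest, and scores
    ``sqrt(mean(((pred - obs) / obs) ** 2))`` over the test areas.  The
    returned error is the mean over repetitions.  Deterministic per seed
    and invariant to area or predictor order.
    """
    if repetitions < 1:
        raise ModelError("invalid repetitions: must be >= 1")
    if not 0.0 < test_fraction < 1.0:
        raise ModelError("test_fraction must be in (0, 1)")
    predictors = tuple(predictors)
    y = matrix.expression(objective).to_numpy(dtype=float)
    X = _design(matrix, predictors)
    n = len(y)
    n_test = math.ceil(test_fraction * n)
    if n_test >= n:
        raise ModelError("test set would consume all areas")

    # Canonicalise over area and predictor order so the split sequence and
    # the fitted subspace do not depend on input ordering.
    area_order = np.argsort(np.asarray(matrix.areas, dtype=object))
    pred_order = np.argsort(np.asarray(predictors, dtype=object))
    y = y[area_order]
    X = X[area_order][:, pred_order]

    rng = np.random.default_rng(seed)
    errors = np.empty(repetitions)
    ones = np.ones(n)
    for r in range(repetitions):
        test_idx = rng.choice(n, size=n_test, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        A_train = np.column_stack([X[~mask], ones[~mask]])
        coef, _, _, _ = np.linalg.lstsq(A_train, y[~mask], rcond=None)
        pred = np.column_stack([X[mask], ones[mask]]) @ coef
        rel = (pred - y[mask]) / y[mask]
        errors[r] = math.sqrt(float(np.mean(rel**2)))
    return float(np.mean(errors))


def fit_target_centric(
    matrix: ExpressionMatrix,
    tcn: TargetCentricNetwork,
    max_error: float = DEFAULT_MAX_ERROR,
    cv_repetitions: int = DEFAULT_CV_REPETITIONS,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> TargetCentricModel:
    """Fit, cross-validate, and filter all objective models of one target.

    Predictor genes absent from the expression matrix are dropped with a
    warning; objectives absent from the matrix are skipped the same way.
    Objective models with CV error above ``max_error`` are recorded in
    ``excluded``.  A model with nothing surviving is returned with
    ``usable == False`` rather than raising, so callers can count excluded
    targets.
    """
    surviving: list[ObjectiveModel] = []
    excluded: list[tuple[str, float]] = []
    present = set(matrix.values.index)
    for j, objective in enumerate(tcn.objectives):
        if objective not in present:
            logger.warning("objective %s missing from expression matrix; skipped", objective)
            continue
        predictors = tuple(
            sorted(g for g in tcn.neighbour_sets[objective] if g in present)
        )
        dropped = len(tcn.neighbour_sets[objective]) - len(predictors)
        if dropped:
            logger.warning(
                "objective %s: %d predictor(s) missing from expression matrix; dropped",
                objective,
                dropped,
            )
        if not predictors:
            logger.warning("objective %s has no usable predictors; skipped", objective)
            continue
        model = fit_objective_model(matrix, objective, predictors)
        model.cv_error = cross_validate(
            matrix,
            objective,
            predictors,
            test_fraction=test_fraction,
            repetitions=cv_repetitions,
            seed=_child_seed(seed, j),
        )
        if model.cv_error > max_error:
            excluded.append((objective, model.cv_error))
            logger.info(
                "target %s: objective model %s excluded (CV error %.3f > %.3f)",
                tcn.target,
                objective,
                model.cv_error,
                max_error,
            )
        else:
            surviving.append(model)
    tcm = TargetCentricModel(target=tcn.target, objective_models=surviving, excluded=excluded)
    if not tcm.usable:
        logger.info("target %s excluded: no surviving objective models", tcn.target)
    return tcm


def _child_seed(seed: int, index: int) -> int:
    """Stable per-objective child seed below 2**31."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


# -- model store ------------------------------------------------------------


def write_model(tcm: TargetCentricModel, path: str | Path, meta: dict | None = None) -> None:
    """Persist one target's models as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        for om in tcm.objective_models:
            fh.write(f"#cv_error={om.objective}\t{om.cv_error:.10g}\n")
        for obj, err in tcm.excluded:
            fh.write(f"#excluded={obj}\t{err:.10g}\n")
        fh.write("objective\tpredictor\tcoefficient\n")
        for om in tcm.objective_models:
            for pred, k in zip(om.predictors, om.coefficients):
                fh.write(f"{om.objective}\t{pred}\t{k:.12g}\n")
            fh.write(f"{om.objective}\t__intercept__\t{om.intercept:.12g}\n")
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"target": tcm.target, **meta}, indent=2))


def read_model(path: str | Path, target: str) -> TargetCentricModel:
    """Load a model previously written by :func:`write_model`."""
    path = Path(path)
    cv: dict[str, float] = {}
    excluded: list[tuple[str, float]] = []
    rows: dict[str, list[tuple[str, float]]] = {}
    intercepts: dict[str, float] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#cv_error="):
                obj, err = line[len("#cv_error=") :].split("\t")
                cv[obj] = float(err)
                continue
            if line.startswith("#excluded="):
                obj, err = line[len("#excluded=") :].split("\t")
                excluded.append((obj, float(err)))
                continue
            if not line or line.startswith("objective\t"):
                continue
            obj, pred, value = line.split("\t")
            if pred == "__intercept__":
                intercepts[obj] = float(value)
            else:
                rows.setdefault(obj, []).append((pred, float(value)))
    models = [
        ObjectiveModel(
            objective=obj,
            predictors=tuple(p for p, _ in pairs),
            coefficients=np.array([k for _, k in pairs]),
            intercept=intercepts[obj],
            cv_error=cv.get(obj, float("nan")),
        )
        for obj, pairs in rows.items()
    ]
    return TargetCentricModel(target=target, objective_models=models, excluded=excluded)
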
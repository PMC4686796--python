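"""Expression matrices over spatial areas, with area-to-structure metadata.

The pipeline consumes one gene x area matrix of strictly positive
normalised intensities (microarray-style), plus a metadata table assigning
every area to an anatomical structure and, optionally, 3-D coordinates.
Positivity is enforced at load time because the knockout-effect index
divides by observed expression; silently flooring small values would
distort relative changes, so violations are rejected instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Smallest admissible expression value.
POSITIVITY_EPS = 1e-6


class ExpressionError(ValueError):
    """Raised for invalid expression data (non-positive values, unknown areas...)."""


@dataclass
class ExpressionMatrix:
    """Strictly positive gene x area expression values with structure labels.

    Attributes
    ----------
    values:
        DataFrame indexed by gene id, columns are area ids.  All entries
        must exceed :data:`POSITIVITY_EPS`.
    area_structure:
        Maps every area id to its anatomical structure label.
    coords:
        Optional map area id -> (x, y, z), used only for map-style exports.
    """

    values: pd.DataFrame
    area_structure: dict[str, str]
    coords: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size == 0:
            raise ExpressionError("empty expression matrix")
        if not np.all(arr > POSITIVITY_EPS):
            bad = int((arr <= POSITIVITY_EPS).sum())
            raise ExpressionError(
                f"non-positive expression: {bad} values <= {POSITIVITY_EPS}"
            )
        missing = [a for a in self.values.columns if a not in self.area_structure]
        if missing:
            raise ExpressionError(f"areas without structure label: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def areas(self) -> list[str]:
        return list(self.values.columns)

    @property
    def structures(self) -> list[str]:
        """Distinct structure labels of the matrix's areas, sorted."""
        return sorted({self.area_structure[a] for a in self.values.columns})

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    def expression(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise ExpressionError(f"missing gene: {gene}")
        return self.values.loc[gene]

    def areas_of_structure(self, structure: str) -> list[str]:
        return [a for a in self.values.columns if self.area_structure[a] == structure]


def average_replicates(
    raw_rows: Iterable[tuple[str, str, float]],
    area_structure: Mapping[str, str] | None = None,
    coords: Mapping[str, tuple[float, float, float]] | None = None,
) -> ExpressionMatrix:
    """Collapse repeated (gene, area) measurements by arithmetic mean.

    Genes and areas are sorted lexicographically so output is deterministic
    regardless of input row order.  When no metadata is given every area is
    assigned a single placeholder structure.
    """
    df = pd.DataFrame(list(raw_rows), columns=["gene", "area", "value"])
    if df.empty:
        raise ExpressionError("no measurement rows")
    wide = (
        df.groupby(["gene", "area"], sort=True)["value"]
        .mean()
        .unstack("area")
    )
    if wide.isna().any().any():
        raise ExpressionError("missing (gene, area) combinations after averaging")
    if area_structure is None:
        area_structure = {a: "all" for a in wide.columns}
    return ExpressionMatrix(
        values=wide,
        area_structure=dict(area_structure),
        coords=dict(coords) if coords is not None else None,
    )


def profile_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation between two per-gene mean expression profiles.

    Intended for the donor-consistency check: whole-set average expression
    profiles of two donors should correlate strongly before one is chosen.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ExpressionError("profiles must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ExpressionError("degenerate profile: zero variance")
    return float(sps.pearsonr(x, y).statistic)


def structure_means(
    matrix: ExpressionMatrix, per_area_values: Mapping[str, float]
) -> dict[str, float]:
    """Average a per-area quantity within each anatomical structure."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for area, value in per_area_values.items():
        if area not in matrix.area_structure:
            raise ExpressionError(f"unknown area: {area}")
        s = matrix.area_structure[area]
        sums[s] = sums.get(s, 0.0) + float(value)
        counts[s] = counts.get(s, 0) + 1
    return {s: sums[s] / counts[s] for s in sums}


# -- I/O --------------------------------------------------------------------


def read_expression(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene x area matrix: first column gene id, header row of area ids."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_metadata(
    path: str | Path,
) -> tuple[dict[str, str], dict[str, tuple[float, float, float]] | None]:
    """Read the sample metadata TSV: ``area_id structure [x y z]``."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "area_id" not in df.columns or "structure" not in df.columns:
        raise ExpressionError("metadata must have area_id and structure columns")
    area_structure = dict(zip(df["area_id"].astype(str), df["structure"].astype(str)))
    coords = None
    if {"x", "y", "z"} <= set(df.columns):
        coords = {
            str(a): (float(x), float(y), float(z))
            for a, x, y, z in zip(df["area_id"], df["x"], df["y"], df["z"])
        }
    return area_structure, coords


def load_expression_matrix(
    expression_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Load and validate a matrix plus metadata into an :class:`ExpressionMatrix`."""
    values = read_expression(expression_path)
    area_structure, coords = read_metadata(metadata_path)
    missing = [a for a in values.columns if a not in area_structure]
    if missing:
        raise ExpressionError(f"metadata missing areas: {missing[:5]}")
    return ExpressionMatrix(values=values, area_structure=area_structure, coords=coords)


def write_area_values(
    matrix: ExpressionMatrix, per_area: Mapping[str, float], path: str | Path
) -> None:
    """Export ``area_id x y z value`` rows for external spatial rendering."""
    with Path(path).open("w") as fh:
        fh.write("area_id\tx\ty\tz\tvalue\n")
        for area in matrix.areas:
            if area not in per_area:
                continue
            x, y, z = (matrix.coords or {}).get(area, (float("nan"),) * 3)
            fh.write(f"{area}\t{x:.6g}\t{y:.6g}\t{z:.6g}\t{per_area[area]:.6g}\n")
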
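"""Incidence matrices for the field-trial mixed models.

A plot table is turned into:

* ``X`` — the fixed-effect incidence of the combined year-location-trial
  (YLT) factor, cell-means coded (one column per observed combination, one
  1 per row), which is full rank by construction;
* ``Z`` over lines — the incidence connecting each plot to its line's
  genetic effect (used with a genomic G or pedigree A covariance);
* spatial incidences — for single-plot (F5-style) layouts the plot's grid
  column and row as factor levels, for replicated (F6-style) layouts a
  moving-average incidence over the plot and its eight grid neighbours.

Spatial levels are nested within (year, location, trial): a neighbourhood
never crosses a trial boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "DesignMatrices",
    "build_fixed_YLT",
    "build_line_incidence",
    "build_spatial_F5",
    "build_spatial_F6",
]


@dataclass
class DesignMatrices:
    """Bundle of incidence matrices for one trait's model."""

    X: sp.csr_matrix
    ylt_levels: list[tuple]
    Z_g: sp.csr_matrix
    line_levels: list[str]
    Z_s: sp.csr_matrix | None = None
    spatial_levels: list[tuple] = field(default_factory=list)


def _factor_incidence(keys: pd.Series | list) -> tuple[sp.csr_matrix, list]:
    codes, levels = pd.factorize(keys, sort=True)
    n = len(codes)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return Z, list(levels)


def build_fixed_YLT(plots: pd.DataFrame) -> tuple[sp.csr_matrix, list[tuple]]:
    """Cell-means incidence of the year-location-trial combination.

    One column per observed (year, location, trial) cell and exactly one 1
    per row, so X has full column rank and no reference-level constraint is
    needed.
    """
    if plots.empty:
        raise ValueError("empty plot table")
    keys = list(zip(plots["year"], plots["location"], plots["trial"]))
    return _factor_incidence(pd.Series(keys))


def build_line_incidence(
    plots: pd.DataFrame, line_order: list[str]
) -> sp.csr_matrix:
    """Plots x lines incidence mapping each plot to its line's effect.

    ``line_order`` fixes the column order (it must match the relationship
    matrix the effect's covariance comes from); every plotted line must be
    present in it.
    """
    idx = pd.Index(line_order).get_indexer(plots["line_id"])
    if (idx < 0).any():
        missing = sorted(set(plots.loc[idx < 0, "line_id"]))
        raise KeyError(f"plotted lines absent from relationship matrix: {missing[:5]}")
    n = len(plots)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, len(line_order))
    )


def _require_coords(plots: pd.DataFrame) -> None:
    bad = plots[plots[["x", "y"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"plots without coordinates: {bad['plot_id'].tolist()[:5]}")


def build_spatial_F5(plots: pd.DataFrame) -> tuple[sp.csr_matrix, list[tuple]]:
    """Row/column factor incidence for single-replicate layouts (n = 2).

    Each plot carries a 1 for its grid column (x) level and a 1 for its grid
    row (y) level, both nested within (year, location, trial).  The two
    factors are stacked into one incidence so they share a single spatial
    variance; each row therefore sums to 2.
    """
    _require_coords(plots)
    trial_key = list(zip(plots["year"], plots["location"], plots["trial"]))
    Zx, x_levels = _factor_incidence(
        pd.Series([k + ("x", v) for k, v in zip(trial_key, plots["x"])])
    )
    Zy, y_levels = _factor_incidence(
        pd.Series([k + ("y", v) for k, v in zip(trial_key, plots["y"])])
    )
    Z = sp.hstack([Zx, Zy]).tocsr()
    return Z, x_levels + y_levels


def build_spatial_F6(plots: pd.DataFrame) -> tuple[sp.csr_matrix, list[tuple]]:
    """Moving-average incidence over the 3x3 plot neighbourhood (n = 9).

    Spatial levels are the occupied plot positions within each
    (year, location, trial) grid.  A plot's row carries a 1 for its own
    position and for each of its eight Moore neighbours that exists in the
    same trial; edge plots simply have fewer than nine 1s (no padding).
    """
    _require_coords(plots)
    trial_key = list(zip(plots["year"], plots["location"], plots["trial"]))
    positions = [k + (x, y) for k, x, y in zip(trial_key, plots["x"], plots["y"])]
    level_index = {pos: i for i, pos in enumerate(sorted(set(positions)))}
    levels = sorted(level_index, key=level_index.get)
    rows, cols = [], []
    for i, (k, x, y) in enumerate(zip(trial_key, plots["x"], plots["y"])):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                neighbour = k + (x + dx, y + dy)
                j = level_index.get(neighbour)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
    Z = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(plots), len(levels))
    )
    return Z, levels
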
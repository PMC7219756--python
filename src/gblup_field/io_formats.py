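"""Readers, writers and validation for the three tabular inputs.

The package consumes three delimited text files:

* a genotype table of minor-allele counts (lines x markers, 0/1/2, missing
  allowed),
* a pedigree table (line, parent1, parent2, selfing cycles),
* a plot table of field-trial records (design factors, grid coordinates,
  yield per plot).

The canonical dialect is tab-separated UTF-8 with a header row and ``NA``
for missing values; comma-separated input is accepted via ``dialect``.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "PLOT_COLUMNS",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_plots",
    "write_plots",
    "validate_plots",
    "summarize_phenotypes",
]

_SEPARATORS = {"tsv": "\t", "csv": ","}

#: Required columns of a plot table, in canonical order.
PLOT_COLUMNS = [
    "plot_id",
    "line_id",
    "generation",
    "set",
    "year",
    "location",
    "trial",
    "replicate",
    "x",
    "y",
    "yield",
    "is_check",
]


class ParseError(ValueError):
    """A malformed value in an input file, located by row and column."""


@dataclass
class GenotypeMatrix:
    """Lines x markers minor-allele counts with missing values as NaN.

    ``counts`` is float-valued so a single array can hold raw 0/1/2 calls,
    missing cells (NaN) and mean-imputed real values.
    """

    line_ids: list[str]
    marker_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids in genotype matrix")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids in genotype matrix")
        if len(self.line_ids) < 2 or len(self.marker_ids) < 1:
            raise ValueError("need at least 2 lines and 1 marker")
        finite = self.counts[~np.isnan(self.counts)]
        # raw calls must be allele counts; imputed matrices relax this
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("allele counts outside [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.line_ids, columns=self.marker_ids)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.counts, other.counts, equal_nan=True)
        )


@dataclass
class Pedigree:
    """Pedigree records with per-line selfing bookkeeping.

    Each record is (id, parent1, parent2, selfing_cycles).  Unknown parents
    are None.  ``selfing_cycles`` counts rounds of self-fertilisation applied
    after the cross that created the line (for founders: after their unknown
    origin); it drives the inbreeding recursion in the pedigree relationship
    matrix.
    """

    records: pd.DataFrame  # columns: id, parent1, parent2, selfing_cycles
    order: list[str] = field(default_factory=list)  # topological order

    def __post_init__(self) -> None:
        df = self.records
        required = ["id", "parent1", "parent2", "selfing_cycles"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"pedigree missing columns {missing}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate pedigree ids: {dups}")
        if (df["selfing_cycles"] < 0).any():
            raise ValueError("selfing_cycles must be non-negative")
        ids = set(df["id"])
        for col in ("parent1", "parent2"):
            named = df[col].dropna()
            unknown = set(named) - ids
            if unknown:
                raise ValueError(f"parents without a record: {sorted(unknown)}")
        if not self.order:
            self.order = self._toposort()

    def _toposort(self) -> list[str]:
        graph: dict[str, set[str]] = {}
        for row in self.records.itertuples(index=False):
            parents = {p for p in (row.parent1, row.parent2) if pd.notna(p)}
            graph[row.id] = parents
        try:
            return list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as err:
            cycle = err.args[1]
            raise ValueError(f"pedigree contains a cycle: {' -> '.join(cycle)}") from err

    def parents_of(self, line_id: str) -> tuple[str | None, str | None]:
        row = self.records.set_index("id").loc[line_id]
        p1 = row["parent1"] if pd.notna(row["parent1"]) else None
        p2 = row["parent2"] if pd.notna(row["parent2"]) else None
        return p1, p2

    @property
    def ids(self) -> list[str]:
        return self.records["id"].tolist()


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'") from None


def read_genotypes(
    path, dialect: str = "tsv", missing: str = "NA", line_id_column: str | None = None
) -> GenotypeMatrix:
    """Read a lines x markers table of minor-allele counts.

    The first column (or ``line_id_column``) holds line ids; the header row
    holds marker ids.  Cells must be 0, 1, 2 or the ``missing`` token.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    if line_id_column is None:
        line_id_column = df.columns[0]
    line_ids = df[line_id_column].tolist()
    markers = [c for c in df.columns if c != line_id_column]
    counts = np.empty((len(line_ids), len(markers)), dtype=float)
    for j, m in enumerate(markers):
        col = df[m].to_numpy()
        for i, tok in enumerate(col):
            if tok == missing or tok == "":
                counts[i, j] = np.nan
            elif tok in ("0", "1", "2"):
                counts[i, j] = float(tok)
            else:
                raise ParseError(
                    f"invalid allele count {tok!r} at line {line_ids[i]!r}, marker {m!r}"
                )
    return GenotypeMatrix(line_ids, markers, counts)


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "tsv", missing: str = "NA") -> None:
    df = g.to_frame()
    # integers written without decimal point so a round-trip is byte-stable
    out = df.map(lambda v: missing if np.isnan(v) else (str(int(v)) if v == int(v) else repr(v)))
    out.index.name = "line_id"
    out.to_csv(path, sep=_sep(dialect))


def read_pedigree(path, dialect: str = "tsv", missing: str = "NA") -> Pedigree:
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    required = ["id", "parent1", "parent2", "selfing_cycles"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"pedigree file missing columns {missing_cols}")
    df = df[required].copy()
    for col in ("parent1", "parent2"):
        df[col] = df[col].replace({missing: None, "": None})
    try:
        df["selfing_cycles"] = df["selfing_cycles"].astype(int)
    except ValueError as err:
        raise ParseError(f"non-integer selfing_cycles: {err}") from err
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path, dialect: str = "tsv", missing: str = "NA") -> None:
    df = ped.records.copy()
    for col in ("parent1", "parent2"):
        df[col] = df[col].fillna(missing)
    df.to_csv(path, sep=_sep(dialect), index=False)


def validate_plots(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a plot table against the schema and design invariants."""
    missing_cols = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"plot table missing columns {missing_cols}")
    df = df[PLOT_COLUMNS].copy()
    df["generation"] = df["generation"].astype(str)
    bad_gen = set(df["generation"]) - {"F5", "F6"}
    if bad_gen:
        raise ValueError(f"unknown generation labels {sorted(bad_gen)}")
    for col in ("set", "year", "replicate", "x", "y"):
        df[col] = df[col].astype(int)
    df["yield"] = df["yield"].astype(float)
    df["is_check"] = df["is_check"].astype(bool)
    observed = df["yield"].notna()
    if (df.loc[observed, "yield"] <= 0).any():
        bad = df.loc[observed & (df["yield"] <= 0), "plot_id"].tolist()
        raise ValueError(f"non-positive yields at plots {bad}")
    coord_cols = ["year", "location", "trial", "x", "y"]
    dup = df.duplicated(subset=coord_cols, keep=False)
    if dup.any():
        first = df.loc[dup, coord_cols].iloc[0].tolist()
        raise ValueError(f"duplicate plot coordinates, e.g. {first}")
    f5 = df[df["generation"] == "F5"]
    multi = f5.groupby("line_id").size()
    repeated = multi[multi > 1]
    noncheck = repeated.index.difference(f5.loc[f5["is_check"], "line_id"].unique())
    if len(noncheck):
        raise ValueError(
            f"non-check lines with more than one F5 plot: {sorted(noncheck)[:5]}"
        )
    return df


def read_plots(path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect))
    return validate_plots(df)


def write_plots(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    validate_plots(df).to_csv(path, sep=_sep(dialect), index=False)


def summarize_phenotypes(plots: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics of plot yield per generation.

    Returns one row per generation with plot count, mean, sample standard
    deviation (n-1 denominator; 0 with a warning-free convention for n=1
    groups), minimum and maximum.  Empty groups are omitted.
    """
    if plots.empty:
        raise ValueError("empty plot table")
    rows = []
    for gen, grp in plots.groupby("generation", sort=True):
        y = grp["yield"].dropna()
        if y.empty:
            continue
        sd = float(y.std(ddof=1)) if len(y) > 1 else 0.0
        rows.append(
            {
                "generation": gen,
                "n_plots": int(len(y)),
                "mean": float(y.mean()),
                "sd": sd,
                "min": float(y.min()),
                "max": float(y.max()),
            }
        )
    return pd.DataFrame(rows)
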
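"""Relationship matrices for inbred breeding lines.

Two covariance structures over lines are built here:

* the genomic relationship matrix ``G = ZZ' / (2 * sum_j p_j (1 - p_j))``
  with ``Z`` the column-centred minor-allele counts (VanRaden's first
  method), after marker/line quality control and marker-mean imputation;
* the pedigree numerator relationship matrix ``A`` by the tabular
  recursion, extended with explicit self-fertilisation bookkeeping so that
  fully inbred parents (nine selfing cycles) and partially inbred
  single-seed-descent lines get the correct diagonal ``1 + F``.

Also here: allele-frequency/QC summaries, principal coordinate analysis of
a relationship matrix, and eigenvalue conditioning so downstream REML can
invert the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .io_formats import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "MarkerStats",
    "qc_filter",
    "allele_frequencies",
    "mean_impute",
    "build_G",
    "build_A_selfed",
    "pcoa",
    "mean_diagonal",
    "condition_pd",
]


@dataclass
class RelationshipMatrix:
    """Symmetric covariance structure over a labelled set of lines."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "genomic" | "pedigree"
    bend_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, labels: list[str]) -> "RelationshipMatrix":
        idx = pd.Index(self.labels).get_indexer(labels)
        if (idx < 0).any():
            missing = [l for l, i in zip(labels, idx) if i < 0]
            raise KeyError(f"labels not in matrix: {missing[:5]}")
        return RelationshipMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.kind, self.bend_applied
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = self.kind
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        kind = df.index.name if df.index.name in ("genomic", "pedigree") else "genomic"
        values = df.to_numpy(dtype=float)
        return cls(list(df.index.astype(str)), 0.5 * (values + values.T), kind)


@dataclass
class MarkerStats:
    """Per-marker allele frequencies and per-line missingness."""

    marker_ids: list[str]
    p: np.ndarray  # frequency of the counted (minor at scoring time) allele
    maf: np.ndarray
    call_rate: np.ndarray
    line_ids: list[str]
    line_missing: np.ndarray


def allele_frequencies(g: GenotypeMatrix) -> MarkerStats:
    """Allele frequencies p_j = sum(counts) / (2 * n_called) per marker."""
    counts = g.counts
    called = ~np.isnan(counts)
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        dead = [m for m, n in zip(g.marker_ids, n_called) if n == 0]
        raise ValueError(f"markers with zero calls: {dead[:5]}")
    p = np.nansum(counts, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    return MarkerStats(
        marker_ids=list(g.marker_ids),
        p=p,
        maf=maf,
        call_rate=n_called / g.n_lines,
        line_ids=list(g.line_ids),
        line_missing=np.isnan(counts).mean(axis=1),
    )


def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.01, line_missing_max: float = 0.02
) -> GenotypeMatrix:
    """Drop high-missingness lines, then low-MAF markers.

    Lines are filtered first; marker allele frequencies are recomputed on the
    surviving lines before the MAF filter, so a marker rescued or doomed by
    the removed lines is judged on the data that will actually enter G.
    """
    line_missing = np.isnan(g.counts).mean(axis=1)
    keep_lines = line_missing <= line_missing_max
    if keep_lines.sum() < 2:
        raise ValueError("fewer than 2 lines survive the missingness filter")
    counts = g.counts[keep_lines]
    line_ids = [l for l, k in zip(g.line_ids, keep_lines) if k]

    called = ~np.isnan(counts)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, np.nansum(counts, axis=0) / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep_markers = (n_called > 0) & (maf >= maf_min)
    if not keep_markers.any():
        raise ValueError("no markers survive the MAF filter")
    marker_ids = [m for m, k in zip(g.marker_ids, keep_markers) if k]
    return GenotypeMatrix(line_ids, marker_ids, counts[:, keep_markers])


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its marker's mean count over called lines."""
    counts = g.counts.copy()
    missing = np.isnan(counts)
    if missing.any():
        col_means = np.nanmean(counts, axis=0)
        idx = np.where(missing)
        counts[idx] = col_means[idx[1]]
    return GenotypeMatrix(list(g.line_ids), list(g.marker_ids), counts)


def build_G(g_imputed: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``Z = M - 2p`` centres the 0/1/2 counts by twice the allele frequency;
    ``G = ZZ' / (2 sum_j p_j(1-p_j))``.  Frequencies are taken from the
    matrix passed in (post-QC, already imputed), so the columns of Z have
    exactly zero mean.
    """
    counts = g_imputed.counts
    if np.isnan(counts).any():
        raise ValueError("impute missing genotypes before building G")
    if g_imputed.n_lines < 2:
        raise ValueError("need at least 2 lines")
    p = counts.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    Z = counts - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(g_imputed.line_ids), G, kind="genomic")


def build_A_selfed(ped: Pedigree, founder_selfing: int = 9) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix under recorded selfing.

    Tabular recursion in topological order: for individuals i processed
    before j, a_ij = 0.5 (a_{i,p1(j)} + a_{i,p2(j)}); the diagonal is
    1 + F_j, with the inbreeding coefficient F_j = 0.5 a_{p1(j),p2(j)} at
    the cross and then F' = 0.5 (1 + F) per recorded selfing cycle.
    Founders (and lines with unknown parents) start non-inbred and receive
    ``founder_selfing`` cycles unless their record says otherwise; with the
    default nine cycles a founder diagonal is 1 + (1 - 2^-9).
    """
    order = ped.order
    pos = {line_id: k for k, line_id in enumerate(order)}
    rec = ped.records.set_index("id")
    n = len(order)
    A = np.zeros((n, n))
    for j, jid in enumerate(order):
        row = rec.loc[jid]
        p1 = row["parent1"] if pd.notna(row["parent1"]) else None
        p2 = row["parent2"] if pd.notna(row["parent2"]) else None
        cycles = int(row["selfing_cycles"])
        if p1 is None and p2 is None:
            F = 0.0
            cycles = cycles if cycles > 0 else founder_selfing
        else:
            # a single known parent is treated as a cross with an unrelated
            # non-inbred unknown founder
            i1 = pos[p1] if p1 is not None else None
            i2 = pos[p2] if p2 is not None else None
            for i in range(j):
                a1 = A[i, i1] if i1 is not None else 0.0
                a2 = A[i, i2] if i2 is not None else 0.0
                A[i, j] = A[j, i] = 0.5 * (a1 + a2)
            F = 0.5 * A[i1, i2] if (i1 is not None and i2 is not None) else 0.0
        for _ in range(cycles):
            F = 0.5 * (1.0 + F)
        A[j, j] = 1.0 + F
    # reorder to the pedigree's record order
    perm = [pos[i] for i in ped.ids]
    A = A[np.ix_(perm, perm)]
    return RelationshipMatrix(list(ped.ids), A, kind="pedigree")


def mean_diagonal(G: RelationshipMatrix | np.ndarray) -> float:
    """Mean diagonal element d(G), the genomic-variance multiplier in the
    phenotypic variance of line means."""
    values = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("square matrix required")
    return float(np.mean(np.diag(values)))


def pcoa(G: RelationshipMatrix, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinate analysis of a relationship matrix.

    The matrix is double-centred and eigendecomposed; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) and the variance-explained
    share of each axis is its eigenvalue over the sum of positive
    eigenvalues (negative eigenvalues are excluded from the denominator).
    """
    M = G.values
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ M @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(eigval.max(), 0) * 1e-12
    rank = int(positive.sum())
    k = min(n_axes, rank)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    shares = eigval[:k] / eigval[positive].sum()
    frame = pd.DataFrame(
        coords, index=G.labels, columns=[f"Axis{i + 1}" for i in range(k)]
    )
    return frame, shares


def condition_pd(G: RelationshipMatrix, epsilon: float = 1e-6) -> RelationshipMatrix:
    """Shift the spectrum up so the smallest eigenvalue is at least epsilon.

    REML needs invertible covariances; duplicate lines or more lines than
    markers make G rank-deficient.  When the smallest eigenvalue is below
    ``epsilon``, ``(epsilon - lambda_min) I`` is added and the bend is
    recorded on the result.
    """
    lam_min = float(scipy.linalg.eigvalsh(G.values, subset_by_index=(0, 0))[0])
    if lam_min >= epsilon:
        return RelationshipMatrix(list(G.labels), G.values.copy(), G.kind, G.bend_applied)
    bent = G.values + (epsilon - lam_min) * np.eye(G.n)
    return RelationshipMatrix(list(G.labels), bent, G.kind, bend_applied=True)
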
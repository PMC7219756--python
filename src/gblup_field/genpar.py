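"""Genetic-parameter summaries derived from fitted variance components.

The phenotypic variance of line means combines the genomic, spatial and
residual components with their effective replicate counts,

    sigma_p^2 = d(G) sigma_g^2 + n_s sigma_s^2 / r1 + sigma_e^2 / r2,

where d(G) is the mean diagonal of the genomic relationship matrix and
n_s the spatial neighbourhood size (2 for the row/column layout, 9 for the
moving average).  Heritability is h^2 = d(G) sigma_g^2 / sigma_p^2; plot
heritability uses r1 = r2 = 1 and line heritability the mean per-line
replicate counts, so line heritability is never below plot heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HeritabilityEstimate", "line_heritability", "genetic_correlation", "replicate_counts"]


@dataclass
class HeritabilityEstimate:
    sigma_p2: float  # phenotypic variance of line means
    h2_plot: float
    h2_line: float
    d_G: float
    n_s: int
    r1: float
    r2: float


def _sigma_p2(d_G, sigma_g2, sigma_s2, sigma_e2, n_s, r1, r2) -> float:
    return d_G * sigma_g2 + n_s * sigma_s2 / r1 + sigma_e2 / r2


def line_heritability(
    sigma_g2: float,
    sigma_e2: float,
    d_G: float = 1.0,
    sigma_s2: float = 0.0,
    n_s: int = 9,
    r1: float = 1.0,
    r2: float = 1.0,
) -> HeritabilityEstimate:
    """Plot and line heritability from converged variance components.

    ``r1`` and ``r2`` are the replicate counts of the spatial and residual
    effects per line (1.0 gives plot heritability; a single plot per line
    makes the two coincide).
    """
    if r1 < 1 or r2 < 1:
        raise ValueError("replicate counts must be >= 1")
    if min(sigma_g2, sigma_s2, sigma_e2) < 0:
        raise ValueError("variance components must be non-negative")
    sigma_p2_line = _sigma_p2(d_G, sigma_g2, sigma_s2, sigma_e2, n_s, r1, r2)
    sigma_p2_plot = _sigma_p2(d_G, sigma_g2, sigma_s2, sigma_e2, n_s, 1.0, 1.0)
    if sigma_p2_line <= 0 or sigma_p2_plot <= 0:
        raise ValueError("phenotypic variance is zero")
    return HeritabilityEstimate(
        sigma_p2=float(sigma_p2_line),
        h2_plot=float(d_G * sigma_g2 / sigma_p2_plot),
        h2_line=float(d_G * sigma_g2 / sigma_p2_line),
        d_G=float(d_G),
        n_s=int(n_s),
        r1=float(r1),
        r2=float(r2),
    )


def genetic_correlation(H: np.ndarray) -> float:
    """Genetic correlation H12 / sqrt(H11 H22) from a 2x2 trait covariance."""
    H = np.asarray(H, dtype=float)
    if H.shape != (2, 2):
        raise ValueError("H must be 2x2")
    if H[0, 0] <= 0 or H[1, 1] <= 0:
        raise ValueError("H diagonal must be positive")
    return float(H[0, 1] / np.sqrt(H[0, 0] * H[1, 1]))


def replicate_counts(plots: pd.DataFrame) -> float:
    """Mean number of plots per line — the effective replicate count used
    for line-mean heritability when no explicit value is supplied."""
    if plots.empty:
        raise ValueError("empty plot table")
    return float(plots.groupby("line_id").size().mean())
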
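"""Estimator classes for single- and multi-trait GBLUP.

:class:`GBLUP` fits the univariate field-trial model

    y = YLT + g (+ a) (+ s) + e

with g ~ N(0, G sigma_g^2) over a genomic relationship matrix, optionally a
pedigree term a ~ N(0, A sigma_a^2) and a spatial term s ~ N(0, I sigma_s^2)
(row/column factors for single-replicate layouts, a 3x3 moving average for
replicated layouts).  :class:`MultiTraitGBLUP` treats the F5 and F6 yield
expressions as two correlated traits sharing one genomic covariance,
[g1; g2] ~ N(0, H (x) G), with independent per-trait residuals.

Both follow the scikit-learn estimator contract: parameters are set in
``__init__``, ``fit`` takes a validated plot table and stores fitted
attributes with trailing underscores, and ``predict`` returns genomic
breeding values for requested lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from . import design, reml
from .relmat import RelationshipMatrix

__all__ = ["GBLUP", "MultiTraitGBLUP"]


def _spatial_term(plots: pd.DataFrame, layout: str, name: str):
    if layout == "f5":
        Z, levels = design.build_spatial_F5(plots)
    elif layout == "f6":
        Z, levels = design.build_spatial_F6(plots)
    else:
        raise ValueError("spatial layout must be 'f5' or 'f6'")
    return reml.RandomTerm(name, Z, None), levels


class GBLUP(BaseEstimator):
    """Univariate GBLUP with year-location-trial fixed effects.

    Parameters
    ----------
    gmat : RelationshipMatrix
        Genomic relationship matrix; its labels define the lines that
        receive breeding values (plotted or not).
    amat : RelationshipMatrix, optional
        Pedigree relationship matrix for an additional additive term.
    spatial : {None, "f5", "f6"}
        Spatial random-effect layout: row/column factors ("f5") or the
        nine-plot moving average ("f6").
    max_iter, tol : REML stopping rule (relative parameter change).
    """

    def __init__(
        self,
        gmat: RelationshipMatrix | None = None,
        amat: RelationshipMatrix | None = None,
        spatial: str | None = None,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.gmat = gmat
        self.amat = amat
        self.spatial = spatial
        self.max_iter = max_iter
        self.tol = tol

    def _build_model(self, plots: pd.DataFrame) -> reml.MixedModel:
        if self.gmat is None:
            raise ValueError("gmat is required")
        X, self.ylt_levels_ = design.build_fixed_YLT(plots)
        terms = [
            reml.RandomTerm(
                "genomic", design.build_line_incidence(plots, self.gmat.labels), self.gmat.values
            )
        ]
        if self.amat is not None:
            terms.append(
                reml.RandomTerm(
                    "pedigree",
                    design.build_line_incidence(plots, self.amat.labels),
                    self.amat.values,
                )
            )
        if self.spatial is not None:
            term, self.spatial_levels_ = _spatial_term(plots, self.spatial, "spatial")
            terms.append(term)
        return reml.MixedModel(plots["yield"].to_numpy(float), X, terms)

    def fit(self, plots: pd.DataFrame, y=None) -> "GBLUP":
        plots = plots[plots["yield"].notna()].reset_index(drop=True)
        model = self._build_model(plots)
        result = reml.reml_fit(model, max_iter=self.max_iter, tol=self.tol)
        self.result_ = result
        self.variance_components_ = result.vc
        self.sigma_g2_ = result.vc.variances["genomic"]
        self.sigma_a2_ = result.vc.variances.get("pedigree")
        self.sigma_s2_ = result.vc.variances.get("spatial")
        self.sigma_e2_ = float(result.vc.residual[0])
        self.loglik_ = result.loglik
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.fixed_effects_ = pd.Series(result.b_hat, index=self.ylt_levels_)
        self.ebv_ = pd.Series(result.effects["genomic"], index=self.gmat.labels, name="ebv")
        return self

    def predict(self, line_ids) -> np.ndarray:
        """Genomic estimated breeding values for the requested lines."""
        if not hasattr(self, "ebv_"):
            raise RuntimeError("fit the model first")
        return self.ebv_.reindex(line_ids).to_numpy(float)


class MultiTraitGBLUP(BaseEstimator):
    """Bivariate GBLUP over the F5 and F6 yield expressions.

    The two generations enter as trait 1 (F5) and trait 2 (F6) with genetic
    covariance H (x) G and a diagonal residual structure: because the two
    traits are recorded on different plots in different years their residual
    covariance is structurally zero.  Pedigree and spatial terms, when
    enabled, are fitted per trait with independent variances.

    ``predict`` returns the F6 (target-trait) breeding values, which is what
    forward validation correlates against next-year performance.
    """

    traits = ("F5", "F6")

    def __init__(
        self,
        gmat: RelationshipMatrix | None = None,
        amat: RelationshipMatrix | None = None,
        spatial: bool = False,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.gmat = gmat
        self.amat = amat
        self.spatial = spatial
        self.max_iter = max_iter
        self.tol = tol

    def _build_model(self, plots: pd.DataFrame) -> reml.MixedModel:
        if self.gmat is None:
            raise ValueError("gmat is required")
        parts = [plots[plots["generation"] == g].reset_index(drop=True) for g in self.traits]
        for g, part in zip(self.traits, parts):
            if part.empty:
                raise ValueError(f"no {g} records: bivariate model unidentifiable")
        y = np.concatenate([p["yield"].to_numpy(float) for p in parts])
        trait_index = np.concatenate(
            [np.full(len(p), t, dtype=int) for t, p in enumerate(parts)]
        )
        X_blocks, self.ylt_levels_ = [], []
        for part in parts:
            Xt, levels = design.build_fixed_YLT(part)
            X_blocks.append(Xt)
            self.ylt_levels_.append(levels)
        X = sp.block_diag(X_blocks).tocsr()
        Z_lines = [design.build_line_incidence(p, self.gmat.labels) for p in parts]
        terms = [
            reml.CorrelatedTerm("genomic", sp.block_diag(Z_lines).tocsr(), self.gmat.values)
        ]
        n_parts = [len(p) for p in parts]
        if self.amat is not None:
            for t, part in enumerate(parts):
                Za = design.build_line_incidence(part, self.amat.labels)
                terms.append(
                    reml.RandomTerm(
                        f"pedigree_{self.traits[t].lower()}",
                        _pad_rows(Za, n_parts, t),
                        self.amat.values,
                    )
                )
        if self.spatial:
            layouts = ("f5", "f6")
            self.spatial_levels_ = []
            for t, part in enumerate(parts):
                term, levels = _spatial_term(part, layouts[t], f"spatial_{self.traits[t].lower()}")
                term = reml.RandomTerm(term.name, _pad_rows(term.Z, n_parts, t), None)
                terms.append(term)
                self.spatial_levels_.append(levels)
        return reml.MixedModel(y, X, terms, trait_index=trait_index, n_traits=2)

    def fit(self, plots: pd.DataFrame, y=None) -> "MultiTraitGBLUP":
        plots = plots[plots["yield"].notna()].reset_index(drop=True)
        model = self._build_model(plots)
        result = reml.reml_fit_bivariate(model, max_iter=self.max_iter, tol=self.tol)
        self.result_ = result
        self.variance_components_ = result.vc
        self.H_ = result.vc.covariances["genomic"]
        self.residual_ = np.asarray(result.vc.residual, dtype=float)
        h11, h22, h12 = self.H_[0, 0], self.H_[1, 1], self.H_[0, 1]
        self.genetic_correlation_ = float(h12 / np.sqrt(h11 * h22))
        self.loglik_ = result.loglik
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.ebv_ = pd.DataFrame(
            result.effects["genomic"], index=self.gmat.labels, columns=list(self.traits)
        )
        return self

    def predict(self, line_ids, trait: str = "F6") -> np.ndarray:
        """Genomic breeding values for the requested lines and trait."""
        if not hasattr(self, "ebv_"):
            raise RuntimeError("fit the model first")
        return self.ebv_[trait].reindex(line_ids).to_numpy(float)


def _pad_rows(Z: sp.spmatrix, n_parts: list[int], t: int) -> sp.csr_matrix:
    """Embed a per-trait incidence into the stacked two-trait row space."""
    blocks = []
    for k, n_k in enumerate(n_parts):
        blocks.append(Z if k == t else sp.csr_matrix((n_k, Z.shape[1])))
    return sp.vstack(blocks).tocsr()
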
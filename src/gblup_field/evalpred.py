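"""Forward cross-validation of genomic prediction.

The validation protocol is strictly forward in time: the newest set of
lines (set 4 by default) is the validation population, its F6 yield records
are withheld, and models trained on the earlier sets predict them.  The
single-trait model (STGP) trains on F6 records of the earlier sets only;
the multi-trait model (MTGP) additionally uses F5 records of *all* sets —
including the validation lines' own F5 plots, which is the point of the
design: a cheap early-generation record on the candidates themselves.

Predictive ability is the Pearson correlation between fixed-effect-
corrected validation line means and the genomic breeding values from the
training fit; accuracy divides it by the square root of the line-mean
heritability estimated on the training data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from . import genpar
from .models import GBLUP, MultiTraitGBLUP
from .relmat import RelationshipMatrix, mean_diagonal

__all__ = [
    "forward_split",
    "corrected_line_means",
    "predictive_ability",
    "accuracy",
    "compare_models",
]


def forward_split(
    plots: pd.DataFrame, validation_set: int = 4, mode: str = "stgp"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a plot table into training and validation partitions.

    Training is all F6 plots outside the validation set; in ``mode="mtgp"``
    it also contains every F5 plot, validation lines included.  Validation
    is the F6 plots of ``validation_set``.
    """
    if validation_set not in set(plots["set"]):
        raise ValueError(f"validation set {validation_set} absent from plot table")
    is_f6 = plots["generation"] == "F6"
    in_val = plots["set"] == validation_set
    validation = plots[is_f6 & in_val].copy()
    if validation.empty:
        raise ValueError(f"no F6 plots in validation set {validation_set}")
    train = is_f6 & ~in_val
    if mode == "mtgp":
        train = train | (plots["generation"] == "F5")
    elif mode != "stgp":
        raise ValueError("mode must be 'stgp' or 'mtgp'")
    return plots[train].copy(), validation


def corrected_line_means(
    validation: pd.DataFrame,
    gmat: RelationshipMatrix | None = None,
    method: str = "blup",
) -> pd.Series:
    """Validation line means corrected for year-location-trial effects.

    ``method="blup"`` estimates the YLT effects from the validation records
    alone with a model treating line as a random genomic effect, then
    averages y - x'b per line; no training phenotype enters the correction.
    ``method="center"`` simply centres within YLT cells.
    """
    validation = validation.reset_index(drop=True)
    if method == "blup":
        if gmat is None:
            raise ValueError("gmat required for the BLUP correction")
        fit = GBLUP(gmat=gmat).fit(validation)
        keys = list(zip(validation["year"], validation["location"], validation["trial"]))
        b = fit.fixed_effects_.reindex(keys).to_numpy(float)
        corrected = validation["yield"].to_numpy(float) - b
    elif method == "center":
        corrected = (
            validation["yield"]
            - validation.groupby(["year", "location", "trial"])["yield"].transform("mean")
        ).to_numpy(float)
    else:
        raise ValueError("method must be 'blup' or 'center'")
    singletons = validation.groupby(["year", "location", "trial"])["line_id"].nunique()
    if (singletons == 1).any():
        import warnings

        warnings.warn(
            "YLT level(s) with a single line: fixed-effect correction is confounded",
            stacklevel=2,
        )
    return pd.Series(corrected, index=validation["line_id"]).groupby(level=0).mean()


def predictive_ability(y_bar_c: pd.Series, g_hat: pd.Series) -> float:
    """Pearson correlation rho(y_bar_c, g_hat) over the common lines."""
    joined = pd.concat([y_bar_c.rename("y"), g_hat.rename("g")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 lines with both values")
    if joined["y"].std() == 0 or joined["g"].std() == 0:
        raise ValueError("zero variance in corrected means or breeding values")
    return float(scipy.stats.pearsonr(joined["y"], joined["g"])[0])


def accuracy(rho: float, h2_line: float) -> float:
    """Prediction accuracy rho / sqrt(h2_line)."""
    if not 0 < h2_line <= 1:
        raise ValueError("h2_line must be in (0, 1]")
    return float(rho / np.sqrt(h2_line))


def _evaluate(
    plots: pd.DataFrame,
    gmat: RelationshipMatrix,
    amat: RelationshipMatrix | None,
    mode: str,
    spatial: bool,
    validation_set: int,
    include_checks: bool,
    correction: str,
    max_iter: int,
    tol: float,
) -> dict:
    train, validation = forward_split(plots, validation_set, mode)
    if mode == "stgp":
        est = GBLUP(
            gmat=gmat,
            amat=amat,
            spatial="f6" if spatial else None,
            max_iter=max_iter,
            tol=tol,
        ).fit(train)
        sigma_g2 = est.sigma_g2_
        sigma_s2 = est.sigma_s2_ or 0.0
        sigma_e2 = est.sigma_e2_
    else:
        est = MultiTraitGBLUP(
            gmat=gmat, amat=amat, spatial=spatial, max_iter=max_iter, tol=tol
        ).fit(train)
        sigma_g2 = float(est.H_[1, 1])  # F6 trait
        sigma_s2 = est.variance_components_.variances.get("spatial_f6", 0.0)
        sigma_e2 = float(est.residual_[1])
    g_hat = pd.Series(est.predict(gmat.labels), index=gmat.labels)

    y_bar_c = corrected_line_means(validation, gmat=gmat, method=correction)
    if not include_checks:
        checks = set(validation.loc[validation["is_check"], "line_id"])
        y_bar_c = y_bar_c[~y_bar_c.index.isin(checks)]
    rho = predictive_ability(y_bar_c, g_hat)

    train_f6 = train[train["generation"] == "F6"]
    r2 = genpar.replicate_counts(train_f6)
    herit = genpar.line_heritability(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        d_G=mean_diagonal(gmat),
        sigma_s2=sigma_s2,
        n_s=9,
        r1=r2,
        r2=r2,
    )
    return {
        "model": mode.upper(),
        "relmat": "G" if amat is None else "G+A+spatial",
        "n_lines": int(len(y_bar_c)),
        "rho": rho,
        "h2_line": herit.h2_line,
        "accuracy": accuracy(rho, herit.h2_line),
    }


def compare_models(
    plots: pd.DataFrame,
    gmat: RelationshipMatrix,
    amat: RelationshipMatrix | None = None,
    validation_set: int = 4,
    include_checks: bool = False,
    correction: str = "blup",
    spatial_with_amat: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """STGP-vs-MTGP comparison on a shared forward split.

    Runs the G-only configuration for both models and, when a pedigree
    matrix is supplied, the G+A+spatial configuration, and reports one row
    per (model, relationship) combination with predictive ability and
    accuracy over the validation lines.
    """
    configs: list[tuple[str, RelationshipMatrix | None, bool]] = [
        ("stgp", None, False),
        ("mtgp", None, False),
    ]
    if amat is not None:
        configs += [("stgp", amat, spatial_with_amat), ("mtgp", amat, spatial_with_amat)]
    rows = [
        _evaluate(
            plots, gmat, a, mode, spat, validation_set, include_checks, correction, max_iter, tol
        )
        for mode, a, spat in configs
    ]
    return pd.DataFrame(rows)
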
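"""REML variance components and BLUP for field-trial mixed models.

The engine fits Gaussian mixed models of the form

    y = X b + sum_i Z_i u_i + e

where each random term ``u_i`` has covariance ``sigma_i^2 K_i`` (``K_i`` a
genomic G, a pedigree A, or the identity), or, for a two-trait genetic
term, ``H (x) K0`` with ``H`` an unconstrained 2x2 trait (co)variance.
Residuals are independent with one variance per trait; the residual
covariance between traits is structurally zero (the two traits are never
observed on the same plot).

Estimation is average-information REML with an expectation-maximisation
fallback whenever a Newton step leaves the parameter space or fails to
improve the restricted likelihood.  All per-iteration quantities come from
the mixed-model equations (MME)

    C = W' R^-1 W + diag(0_p, G*^-1),   W = [X, Z_1, ..., Z_m]

using the standard identities

    P = R^-1 - R^-1 W C^-1 W' R^-1
    log|V| + log|X' V^-1 X| = log|R| + log|G*| + log|C|
    Z' P Z = G*^-1 - G*^-1 C^uu G*^-1

so no n x n matrix is ever formed.  A dense direct evaluation of the
restricted likelihood (:func:`restricted_loglik`, ``method="dense"``) is
kept as an independent cross-check.

Variances are floored at ``1e-8`` times the phenotypic variance rather
than allowed negative, matching the reporting convention of mixed-model
packages used in breeding-value estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "RandomTerm",
    "CorrelatedTerm",
    "MixedModel",
    "VarianceComponents",
    "FitResult",
    "restricted_loglik",
    "reml_fit",
    "reml_fit_bivariate",
    "blup_solve",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RandomTerm:
    """A single-variance random term u ~ N(0, sigma^2 K)."""

    name: str
    Z: sp.spmatrix  # n x q incidence
    K: np.ndarray | None = None  # q x q covariance; None means identity

    def __post_init__(self) -> None:
        self.Z = sp.csr_matrix(self.Z)
        self.q = self.Z.shape[1]
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.q, self.q):
                raise ValueError(f"term {self.name}: K shape does not match Z columns")
            cf = scipy.linalg.cho_factor(self.K)
            self.Kinv = scipy.linalg.cho_solve(cf, np.eye(self.q))
            self.logdetK = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        else:
            self.Kinv = None
            self.logdetK = 0.0

    @property
    def n_params(self) -> int:
        return 1


@dataclass
class CorrelatedTerm:
    """A two-trait genetic term [u1; u2] ~ N(0, H (x) K0).

    ``Z`` has 2q columns ordered trait-major (trait-1 levels then trait-2
    levels) so that the covariance is ``kron(H, K0)``.  The three free
    parameters are H11, H22 and H12.
    """

    name: str
    Z: sp.spmatrix  # n x 2q
    K0: np.ndarray  # q x q base covariance (e.g. genomic G)

    def __post_init__(self) -> None:
        self.Z = sp.csr_matrix(self.Z)
        self.K0 = np.asarray(self.K0, dtype=float)
        q2 = self.Z.shape[1]
        if q2 % 2 or self.K0.shape != (q2 // 2, q2 // 2):
            raise ValueError(f"term {self.name}: Z must have 2q columns matching K0")
        self.q = q2 // 2
        cf = scipy.linalg.cho_factor(self.K0)
        self.K0inv = scipy.linalg.cho_solve(cf, np.eye(self.q))
        self.logdetK0 = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

    @property
    def n_params(self) -> int:
        return 3


@dataclass
class MixedModel:
    """Observed data plus design structure, ready for REML.

    ``trait_index`` assigns each observation to a residual class (all zeros
    for a univariate model).
    """

    y: np.ndarray
    X: sp.spmatrix
    terms: list
    trait_index: np.ndarray | None = None
    n_traits: int = 1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = sp.csr_matrix(self.X)
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        if self.trait_index is None:
            self.trait_index = np.zeros(n, dtype=int)
        self.trait_index = np.asarray(self.trait_index, dtype=int)
        self.n_traits = int(self.trait_index.max()) + 1 if n else 1
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"term {t.name}: Z row count does not match y")
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite values")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


@dataclass
class VarianceComponents:
    """REML estimates: one variance per simple term, a 2x2 H per correlated
    term, and one residual variance per trait."""

    variances: dict[str, float] = field(default_factory=dict)
    covariances: dict[str, np.ndarray] = field(default_factory=dict)
    residual: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            dict(self.variances),
            {k: v.copy() for k, v in self.covariances.items()},
            np.array(self.residual, dtype=float),
        )


@dataclass
class FitResult:
    vc: VarianceComponents
    b_hat: np.ndarray
    effects: dict[str, np.ndarray]  # term name -> (q,) or (q, 2)
    loglik: float
    n_iter: int
    converged: bool
    final_update_norm: float
    message: str = ""


# ---------------------------------------------------------------------------
# parameter packing


def _pack(model: MixedModel, vc: VarianceComponents) -> np.ndarray:
    theta = []
    for t in model.terms:
        if isinstance(t, RandomTerm):
            theta.append(vc.variances[t.name])
        else:
            H = vc.covariances[t.name]
            theta.extend([H[0, 0], H[1, 1], H[0, 1]])
    theta.extend(np.atleast_1d(vc.residual))
    return np.asarray(theta, dtype=float)


def _unpack(model: MixedModel, theta: np.ndarray) -> VarianceComponents:
    vc = VarianceComponents(residual=np.empty(model.n_traits))
    k = 0
    for t in model.terms:
        if isinstance(t, RandomTerm):
            vc.variances[t.name] = float(theta[k])
            k += 1
        else:
            h11, h22, h12 = theta[k : k + 3]
            vc.covariances[t.name] = np.array([[h11, h12], [h12, h22]])
            k += 3
    vc.residual = np.array(theta[k : k + model.n_traits], dtype=float)
    return vc


# ---------------------------------------------------------------------------
# MME engine


class _Engine:
    """Per-model caches and one-iteration computations for AI-REML."""

    def __init__(self, model: MixedModel):
        self.model = model
        self.W = sp.hstack([model.X] + [t.Z for t in model.terms]).tocsr()
        self.dim = self.W.shape[1]
        self.p = model.n_fixed
        # slices of the MME solution vector per term
        self.slices = []
        start = self.p
        for t in model.terms:
            width = t.q if isinstance(t, RandomTerm) else 2 * t.q
            self.slices.append(slice(start, start + width))
            start += width
        # per-trait Gram matrices and projections (R depends only on the
        # trait residual variances, so these are fixed across iterations)
        self.grams, self.wty, self.yty, self.n_t, self.masks = [], [], [], [], []
        for t in range(model.n_traits):
            mask = model.trait_index == t
            Wt = self.W[mask]
            self.grams.append(np.asarray((Wt.T @ Wt).todense()))
            self.wty.append(Wt.T @ model.y[mask])
            self.yty.append(float(model.y[mask] @ model.y[mask]))
            self.n_t.append(int(mask.sum()))
            self.masks.append(mask)

    # -- assembly ----------------------------------------------------------

    def _gstar_inv_logdet(self, vc: VarianceComponents):
        blocks, logdet = [], 0.0
        for t in self.model.terms:
            if isinstance(t, RandomTerm):
                s2 = vc.variances[t.name]
                blocks.append((np.eye(t.q) if t.Kinv is None else t.Kinv) / s2)
                logdet += t.q * np.log(s2) + t.logdetK
            else:
                H = vc.covariances[t.name]
                Hi = np.linalg.inv(H)
                blocks.append(np.kron(Hi, t.K0inv))
                sign, ld_H = np.linalg.slogdet(H)
                if sign <= 0:
                    raise FloatingPointError(f"H for term {t.name} not PD")
                logdet += t.q * ld_H + 2.0 * t.logdetK0
        return blocks, logdet

    def factorize(self, vc: VarianceComponents):
        """Assemble and factorize C; return solution state for this vc."""
        re_inv = 1.0 / vc.residual
        C = np.zeros((self.dim, self.dim))
        rhs = np.zeros(self.dim)
        y_rinv_y = 0.0
        for t in range(self.model.n_traits):
            C += self.grams[t] * re_inv[t]
            rhs += self.wty[t] * re_inv[t]
            y_rinv_y += self.yty[t] * re_inv[t]
        gblocks, logdet_gstar = self._gstar_inv_logdet(vc)
        for sl, blk in zip(self.slices, gblocks):
            C[sl, sl] += blk
        cf = scipy.linalg.cho_factor(C, lower=True)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        theta_hat = scipy.linalg.cho_solve(cf, rhs)
        e_hat = self.model.y - self.W @ theta_hat
        y_p_y = y_rinv_y - float(theta_hat @ rhs)
        logdet_R = float(np.sum(np.asarray(self.n_t) * np.log(vc.residual)))
        n, p = self.model.n_obs, self.p
        loglik = -0.5 * (
            (n - p) * _LOG2PI + logdet_R + logdet_gstar + logdet_C + y_p_y
        )
        return {
            "vc": vc,
            "cf": cf,
            "theta_hat": theta_hat,
            "e_hat": e_hat,
            "loglik": loglik,
            "re_inv": re_inv,
        }

    # -- derivatives -------------------------------------------------------

    def derivatives(self, state):
        """Score vector, AI matrix, EM-updated parameters at the current fit."""
        model, vc = self.model, state["vc"]
        cf, theta_hat = state["cf"], state["theta_hat"]
        Cinv = _chol_inverse(cf)
        r_per_obs = vc.residual[model.trait_index]
        Py = state["e_hat"] / r_per_obs

        scores, em, f_cols = [], [], []
        for t, sl in zip(model.terms, self.slices):
            u = theta_hat[sl]
            Cuu = Cinv[sl, sl]
            if isinstance(t, RandomTerm):
                s2 = vc.variances[t.name]
                Kinv_u = u if t.Kinv is None else t.Kinv @ u
                tr_KiC = float(np.trace(Cuu)) if t.Kinv is None else float(
                    np.sum(t.Kinv * Cuu)
                )
                tr_PV = t.q / s2 - tr_KiC / s2**2
                f = t.Z @ (u / s2)
                scores.append(-0.5 * (tr_PV - float(Py @ f)))
                em.append((float(u @ Kinv_u) + tr_KiC) / t.q)
                f_cols.append(f)
            else:
                H = vc.covariances[t.name]
                Hi = np.linalg.inv(H)
                q = t.q
                U = u.reshape(2, q)
                S = [[Cuu[i * q : (i + 1) * q, j * q : (j + 1) * q] for j in (0, 1)] for i in (0, 1)]
                # tG[k, l] = tr(K0^-1 S[k, l]); symmetric in (k, l)
                tG = np.array(
                    [[float(np.sum(t.K0inv * S[k][l])) for l in (0, 1)] for k in (0, 1)]
                )
                TS = tG @ Hi
                GinvU = (t.K0inv @ U.T).T  # (2, q): K0^-1 u_k per trait
                for E in (_E11, _E22, _E12):
                    EHi = E @ Hi
                    tr_PV = float(np.trace(EHi) * q - np.trace(EHi @ TS))
                    V = EHi @ U
                    f = t.Z @ V.ravel()
                    scores.append(-0.5 * (tr_PV - float(Py @ f)))
                    f_cols.append(f)
                H_em = (U @ GinvU.T + tG) / q
                H_em = 0.5 * (H_em + H_em.T)
                em.extend([H_em[0, 0], H_em[1, 1], H_em[0, 1]])
        for t in range(model.n_traits):
            s2 = vc.residual[t]
            mask = self.masks[t]
            tr_CG = float(np.sum(Cinv * self.grams[t]))
            tr_PV = self.n_t[t] / s2 - tr_CG / s2**2
            f = np.where(mask, Py, 0.0)
            scores.append(-0.5 * (tr_PV - float(Py @ f)))
            e_t = state["e_hat"][mask]
            em.append((float(e_t @ e_t) + tr_CG) / self.n_t[t])
            f_cols.append(f)

        F = np.column_stack(f_cols)
        B = F / r_per_obs[:, None]
        M = self.W.T @ B
        PF = B - (self.W @ scipy.linalg.cho_solve(cf, M)) / r_per_obs[:, None]
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)
        return np.asarray(scores), AI, np.asarray(em)

    def solutions(self, state) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        theta_hat = state["theta_hat"]
        b_hat = theta_hat[: self.p]
        effects = {}
        for t, sl in zip(self.model.terms, self.slices):
            u = theta_hat[sl]
            effects[t.name] = u if isinstance(t, RandomTerm) else u.reshape(2, t.q).T
        return b_hat, effects


def _chol_inverse(cf) -> np.ndarray:
    """Full inverse from a cho_factor result via LAPACK potri."""
    L, lower = cf
    inv, info = scipy.linalg.lapack.dpotri(L, lower=lower)
    if info != 0:
        raise FloatingPointError(f"dpotri failed with info={info}")
    # potri fills one triangle only; the other still holds factorization junk
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


_E11 = np.array([[1.0, 0.0], [0.0, 0.0]])
_E22 = np.array([[0.0, 0.0], [0.0, 1.0]])
_E12 = np.array([[0.0, 1.0], [1.0, 0.0]])


# ---------------------------------------------------------------------------
# public operations


def restricted_loglik(
    model: MixedModel, vc: VarianceComponents, method: str = "mme"
) -> float:
    """Restricted log-likelihood at the given variance components.

    ``method="mme"`` evaluates through the mixed-model-equations
    factorization; ``method="dense"`` forms V = sum Z K Z' sigma^2 + R
    explicitly and evaluates -2 logL_R = (n-p) log 2pi + log|V| +
    log|X'V^-1X| + y'Py directly.  The two agree to numerical precision and
    the dense route serves as the independent check of the factorized one.
    """
    if method == "mme":
        return _Engine(model).factorize(vc)["loglik"]
    if method != "dense":
        raise ValueError("method must be 'mme' or 'dense'")
    n, p = model.n_obs, model.n_fixed
    V = np.diag(vc.residual[model.trait_index].astype(float))
    for t in model.terms:
        Zd = np.asarray(t.Z.todense())
        if isinstance(t, RandomTerm):
            K = np.eye(t.q) if t.K is None else t.K
            V += vc.variances[t.name] * (Zd @ K @ Zd.T)
        else:
            K = np.kron(vc.covariances[t.name], t.K0)
            V += Zd @ K @ Zd.T
    Xd = np.asarray(model.X.todense())
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        lam = np.linalg.eigvalsh(V)
        raise FloatingPointError(f"singular V (lambda_min = {lam[0]:.3e})")
    Vinv = np.linalg.inv(V)
    XtVX = Xd.T @ Vinv @ Xd
    sign_x, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign_x <= 0:
        raise FloatingPointError("X'V^-1X singular; X not full column rank")
    beta = np.linalg.solve(XtVX, Xd.T @ (Vinv @ model.y))
    resid = model.y - Xd @ beta
    y_p_y = float(resid @ (Vinv @ model.y))
    return -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_XtVX + y_p_y)


def _default_init(model: MixedModel) -> VarianceComponents:
    """Half the trait phenotypic variance split equally among the random
    terms touching that trait; the other half to the residual."""
    vp = np.array(
        [float(np.var(model.y[model.trait_index == t])) or 1.0 for t in range(model.n_traits)]
    )
    touch: dict[str, np.ndarray] = {}
    for t in model.terms:
        rows = np.unique(t.Z.nonzero()[0])
        touch[t.name] = np.unique(model.trait_index[rows])
    counts = np.zeros(model.n_traits)
    for traits in touch.values():
        counts[traits] += 1
    counts = np.maximum(counts, 1)
    vc = VarianceComponents(residual=0.5 * vp)
    for t in model.terms:
        share = float(np.mean([0.5 * vp[tr] / counts[tr] for tr in touch[t.name]]))
        if isinstance(t, RandomTerm):
            vc.variances[t.name] = share
        else:
            d = np.array([0.5 * vp[tr] / counts[tr] for tr in (0, min(1, model.n_traits - 1))])
            vc.covariances[t.name] = np.diag(d)
    return vc


def _floor_theta(model: MixedModel, theta: np.ndarray, floor: float) -> np.ndarray:
    """Floor variances; keep each H positive definite."""
    theta = theta.copy()
    k = 0
    for t in model.terms:
        if isinstance(t, RandomTerm):
            theta[k] = max(theta[k], floor)
            k += 1
        else:
            h11 = max(theta[k], floor)
            h22 = max(theta[k + 1], floor)
            h12 = theta[k + 2]
            lim = 0.999 * np.sqrt(h11 * h22)
            h12 = float(np.clip(h12, -lim, lim))
            theta[k : k + 3] = (h11, h22, h12)
            k += 3
    theta[k:] = np.maximum(theta[k:], floor)
    return theta


def reml_fit(
    model: MixedModel,
    init: VarianceComponents | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> FitResult:
    """AI-REML with EM fallback.

    Iterates average-information (Newton-type) updates of the variance
    parameters; a step that leaves the parameter space or lowers the
    restricted likelihood is halved and ultimately replaced by an EM step,
    which cannot decrease the likelihood.  Convergence is declared when the
    relative parameter change drops below ``tol``; non-convergence within
    ``max_iter`` is flagged on the result, not raised.
    """
    engine = _Engine(model)
    vp = float(np.var(model.y)) or 1.0
    floor = 1e-8 * vp
    vc = (init or _default_init(model)).copy()
    theta = _floor_theta(model, _pack(model, vc), floor)
    state = engine.factorize(_unpack(model, theta))
    delta_rel = np.inf
    message = "converged"
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        scores, AI, em = engine.derivatives(state)
        em = _floor_theta(model, em, floor)
        # Newton candidate via the AI matrix, halved until it does not lower
        # the likelihood; an overshoot that lands on the parameter-space
        # boundary (floored variance, clamped H) is kept only if it still
        # beats the EM candidate, which is evaluated every iteration --
        # otherwise boundary-clamped steps glue the iterate to the boundary
        # and force a long EM crawl back
        new_state = None
        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(len(scores)), scores)
        except np.linalg.LinAlgError:
            step = None
        if step is not None:
            frac = 1.0
            for _ in range(6):
                cand = _floor_theta(model, theta + frac * step, floor)
                try:
                    cand_state = engine.factorize(_unpack(model, cand))
                except (FloatingPointError, np.linalg.LinAlgError, scipy.linalg.LinAlgError):
                    frac *= 0.5
                    continue
                if cand_state["loglik"] >= state["loglik"] - 1e-10:
                    new_state, new_theta = cand_state, cand
                    break
                frac *= 0.5
        try:  # EM candidate: guaranteed non-decreasing likelihood
            em_state = engine.factorize(_unpack(model, em))
        except (FloatingPointError, np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            em_state = None
        if em_state is not None and (
            new_state is None or em_state["loglik"] > new_state["loglik"]
        ):
            new_state, new_theta = em_state, em
        if new_state is None:
            message = "no admissible update step"
            break
        # components pinned at the floor are judged on a 1e-6*vp scale so a
        # boundary solution does not stall the relative-change criterion
        scale = np.maximum(np.abs(new_theta), 1e-6 * vp)
        delta_rel = float(np.max(np.abs(new_theta - theta) / scale))
        theta, state = new_theta, new_state
        if verbose:
            print(f"iter {it:3d} logL {state['loglik']:.6f} delta {delta_rel:.2e}")
        if delta_rel < tol:
            converged = True
            break
    if not converged and message == "converged":
        message = f"not converged after {max_iter} iterations (delta {delta_rel:.1e})"
    b_hat, effects = engine.solutions(state)
    return FitResult(
        vc=_unpack(model, theta),
        b_hat=b_hat,
        effects=effects,
        loglik=state["loglik"],
        n_iter=it,
        converged=converged,
        final_update_norm=delta_rel,
        message=message,
    )


def reml_fit_bivariate(
    model: MixedModel,
    init: VarianceComponents | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> FitResult:
    """REML for a two-trait model (same engine; checks the trait layout).

    The model must carry two residual classes and at least one correlated
    genetic term; lines observed for a single trait contribute that trait's
    records only, and breeding values for both traits are returned for
    every level of the genetic term's base covariance.
    """
    if model.n_traits != 2:
        raise ValueError("bivariate fit requires observations on two traits")
    if not any(isinstance(t, CorrelatedTerm) for t in model.terms):
        raise ValueError("bivariate model needs a correlated genetic term")
    for t in range(2):
        if not (model.trait_index == t).any():
            raise ValueError(f"no observations for trait {t + 1}: model unidentifiable")
    return reml_fit(model, init=init, max_iter=max_iter, tol=tol, verbose=verbose)


def blup_solve(model: MixedModel, vc: VarianceComponents) -> FitResult:
    """Henderson mixed-model-equation solutions at fixed variance components."""
    engine = _Engine(model)
    state = engine.factorize(vc)
    b_hat, effects = engine.solutions(state)
    return FitResult(
        vc=vc.copy(),
        b_hat=b_hat,
        effects=effects,
        loglik=state["loglik"],
        n_iter=0,
        converged=True,
        final_update_norm=0.0,
        message="BLUP at fixed variance components",
    )
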
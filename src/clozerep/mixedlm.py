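"""Maximum-likelihood linear mixed models with crossed random effects.

Implements the profiled ML deviance of the penalized-least-squares
formulation of the linear mixed model (the formulation popularised by
lme4): for

    y = X beta + Z Lambda(theta) u + eps,   u ~ N(0, sigma^2 I),
    eps ~ N(0, sigma^2 I),

beta and sigma^2 are profiled out analytically and only the relative
covariance parameters theta (one lower-triangular factor per random term,
or its diagonal when the term is uncorrelated) are optimised numerically.
The profiled deviance is

    -2 l(theta) = log det(Lambda' Z'Z Lambda + I)
                  + n [ log(2 pi PWRSS/n) + 1 ],

with PWRSS the penalized residual sum of squares at the joint
(u, beta)-minimiser.  All linear algebra is dense: the random-effect
dimension q = sum over terms of (levels x variables) stays in the hundreds
for the designs this package targets, so dense Cholesky factorisations are
both simple and fast enough for thousand-replicate simulation studies.

ML (not REML) is used throughout so that likelihood-ratio tests between
models differing in fixed effects are valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

__all__ = ["RandomTerm", "MixedLMFit", "fit_mixed_lm"]


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: ``(variables | factor)`` or ``(... || factor)``.

    ``variables`` name columns of the model data; the literal ``"1"`` denotes
    the intercept.  With ``correlated=False`` the covariance of the term's
    effects is diagonal (the double-bar form).
    """

    factor: str
    variables: tuple[str, ...] = ("1",)
    correlated: bool = True

    def describe(self) -> str:
        bar = "|" if self.correlated else "||"
        return f"({' + '.join(self.variables)} {bar} {self.factor})"


@dataclass
class MixedLMFit:
    """Result of an ML mixed-model fit."""

    beta: pd.Series
    se: pd.Series
    vcov: np.ndarray
    loglik: float
    sigma2: float
    theta: np.ndarray
    terms: tuple[RandomTerm, ...]
    ranef_sd: dict
    n_obs: int
    n_fixed: int
    converged: bool
    n_deviance_evals: int = 0

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


def _term_matrices(data: pd.DataFrame, term: RandomTerm):
    """Sparse random-effects design block and level labels for one term."""
    codes, levels = pd.factorize(data[term.factor], sort=True)
    if len(levels) < 2:
        raise ValueError(f"grouping factor {term.factor!r} has fewer than 2 levels")
    n = len(data)
    k = len(term.variables)
    cols = []
    vals = []
    rows = np.arange(n)
    for j, v in enumerate(term.variables):
        x = np.ones(n) if v == "1" else data[v].to_numpy(dtype=float)
        cols.append(codes * k + j)
        vals.append(x)
    Z = sparse.coo_matrix(
        (np.concatenate(vals), (np.tile(rows, k), np.concatenate(cols))),
        shape=(n, len(levels) * k),
    ).tocsr()
    return Z, len(levels), k


def _theta_slices(terms, ks):
    """Start offsets and per-term theta layouts.

    Correlated terms use the column-major lower triangle of a k x k factor
    (diagonal entries bounded below by 0); uncorrelated terms use just the
    k diagonal entries.
    """
    offsets, sizes = [], []
    pos = 0
    for term, k in zip(terms, ks):
        size = k * (k + 1) // 2 if term.correlated else k
        offsets.append(pos)
        sizes.append(size)
        pos += size
    return offsets, sizes, pos


def _factor_block(theta_t: np.ndarray, k: int, correlated: bool) -> np.ndarray:
    T = np.zeros((k, k))
    if correlated:
        idx = np.tril_indices(k)
        # column-major lower triangle, diagonal first within each column
        pos = 0
        for col in range(k):
            for row in range(col, k):
                T[row, col] = theta_t[pos]
                pos += 1
    else:
        T[np.diag_indices(k)] = theta_t
    return T


DEFAULT_START_SD = 0.3  # starting relative sd: RE spread well below residual


def _initial_theta(terms, ks) -> tuple[np.ndarray, list]:
    """Modest relative-covariance factors; bounds keep diagonals >= 0."""
    x0, bounds = [], []
    for term, k in zip(terms, ks):
        if term.correlated:
            for col in range(k):
                for row in range(col, k):
                    if row == col:
                        x0.append(DEFAULT_START_SD)
                        bounds.append((0.0, None))
                    else:
                        x0.append(0.0)
                        bounds.append((None, None))
        else:
            x0.extend([DEFAULT_START_SD] * k)
            bounds.extend([(0.0, None)] * k)
    return np.asarray(x0), bounds


def fit_mixed_lm(
    y: np.ndarray,
    X: pd.DataFrame,
    data: pd.DataFrame,
    terms,
    xtol: float = 1e-8,
    theta0: np.ndarray | None = None,
) -> MixedLMFit:
    """Fit a crossed random-effects linear mixed model by ML.

    Parameters
    ----------
    y:
        Response vector (length n).
    X:
        Fixed-effects design matrix as a DataFrame (column names become
        coefficient names).  Must have full column rank.
    data:
        Frame holding the grouping factors and slope variables referenced
        by ``terms`` (same row order as ``y``/``X``).
    terms:
        Sequence of :class:`RandomTerm`; may be empty, in which case the
        fit reduces to ordinary least squares (still reported with its ML
        log-likelihood so LRTs remain comparable).
    theta0:
        Optional warm-start for the relative-covariance parameters (e.g.
        the optimum of a fixed-effects-nested model, whose random-effect
        structure is identical).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(X) != n or len(data) != n:
        raise ValueError("y, X and data must have equal length")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance; model is degenerate")
    Xm = X.to_numpy(dtype=float)
    p = Xm.shape[1]

    # collinearity guard: name the offending columns, as callers rely on it
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        _, R = np.linalg.qr(Xm)
        bad = [X.columns[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"singular fixed-effects design; collinear terms: {bad}")

    terms = tuple(terms)
    XtX = Xm.T @ Xm
    Xty = Xm.T @ y
    yty = float(y @ y)

    if not terms:
        beta = np.linalg.solve(XtX, Xty)
        resid = y - Xm @ beta
        rss = float(resid @ resid)
        sigma2 = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        vcov = sigma2 * np.linalg.inv(XtX)
        return MixedLMFit(
            beta=pd.Series(beta, index=X.columns),
            se=pd.Series(np.sqrt(np.diag(vcov)), index=X.columns),
            vcov=vcov,
            loglik=loglik,
            sigma2=sigma2,
            theta=np.empty(0),
            terms=terms,
            ranef_sd={},
            n_obs=n,
            n_fixed=p,
            converged=True,
        )

    blocks = [_term_matrices(data, t) for t in terms]
    Z = sparse.hstack([b[0] for b in blocks], format="csr")
    ms = [b[1] for b in blocks]
    ks = [b[2] for b in blocks]
    q = Z.shape[1]
    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ Xm
    Zty = Z.T @ y

    offsets, sizes, n_theta = _theta_slices(terms, ks)
    evals = {"n": 0}

    def build_lambda(theta: np.ndarray) -> np.ndarray:
        Lam = np.zeros((q, q))
        col = 0
        for (term, m, k, off, size) in zip(
            terms, ms, ks, offsets, sizes
        ):
            T = _factor_block(theta[off : off + size], k, term.correlated)
            Lam[col : col + m * k, col : col + m * k] = np.kron(np.eye(m), T)
            col += m * k
        return Lam

    def deviance_parts(theta: np.ndarray):
        Lam = build_lambda(theta)
        LZtZ = Lam.T @ ZtZ @ Lam
        C = LZtZ + np.eye(q)
        LZtX = Lam.T @ ZtX
        LZty = Lam.T @ Zty
        M = np.block([[C, LZtX], [LZtX.T, XtX]])
        rhs = np.concatenate([LZty, Xty])
        try:
            cM = linalg.cho_factor(M, lower=True, check_finite=False)
            cC = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        sol = linalg.cho_solve(cM, rhs, check_finite=False)
        pwrss = yty - float(rhs @ sol)
        if pwrss <= 0:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(cC[0])))
        dev = logdet + n * (np.log(2 * np.pi * pwrss / n) + 1.0)
        return dev, sol, pwrss, C, LZtX

    def objective(theta: np.ndarray) -> float:
        evals["n"] += 1
        parts = deviance_parts(theta)
        if parts is None:
            return 1e12
        return parts[0]

    x0, bounds = _initial_theta(terms, ks)
    if theta0 is not None and len(theta0) == len(x0):
        x0 = np.asarray(theta0, dtype=float)
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": xtol, "gtol": 1e-6},
    )
    # polish with a derivative-free pass; cheap and guards against rough
    # finite-difference gradients near the theta >= 0 boundary
    res2 = optimize.minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    theta = np.asarray(res2.x)
    # Nelder-Mead ignores bounds; reflect negative diagonals (the sign of a
    # factor column is unidentified, so this leaves the fit unchanged)
    for (term, k, off, size) in zip(terms, ks, offsets, sizes):
        th = theta[off : off + size]
        if term.correlated:
            pos = 0
            for col in range(k):
                width = k - col
                if th[pos] < 0:
                    th[pos : pos + width] *= -1.0  # flip the whole factor column
                pos += width
        else:
            th[:] = np.abs(th)
    parts = deviance_parts(theta)
    converged = bool((res.success or res2.success) and parts is not None)
    if parts is None:  # pragma: no cover - defensive
        raise RuntimeError("mixed-model deviance not evaluable at the optimum")
    dev, sol, pwrss, C, LZtX = parts

    beta = sol[q:]
    sigma2 = pwrss / n
    # cov(beta) = sigma^2 (X'V^-1 X)^-1 via the Schur complement of C
    cC = linalg.cho_factor(C, lower=True, check_finite=False)
    S = XtX - LZtX.T @ linalg.cho_solve(cC, LZtX, check_finite=False)
    vcov = sigma2 * np.linalg.inv(S)
    loglik = -0.5 * dev

    ranef_sd = {}
    sigma = np.sqrt(sigma2)
    for (term, k, off, size) in zip(terms, ks, offsets, sizes):
        T = _factor_block(theta[off : off + size], k, term.correlated)
        cov = sigma2 * (T @ T.T)
        sds = np.sqrt(np.diag(cov))
        entry = {v: float(s) for v, s in zip(term.variables, sds)}
        if term.correlated and k > 1:
            denom = np.outer(sds, sds)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(denom > 0, cov / denom, 0.0)
            entry["corr"] = corr[np.tril_indices(k, -1)].tolist()
        ranef_sd[term.describe()] = entry

    return MixedLMFit(
        beta=pd.Series(beta, index=X.columns),
        se=pd.Series(np.sqrt(np.diag(vcov)), index=X.columns),
        vcov=vcov,
        loglik=float(loglik),
        sigma2=float(sigma2),
        theta=theta,
        terms=terms,
        ranef_sd=ranef_sd,
        n_obs=n,
        n_fixed=p,
        converged=converged,
        n_deviance_evals=evals["n"],
    )
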
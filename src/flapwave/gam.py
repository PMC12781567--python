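"""Penalized additive count models (GAMs) for hourly flap rates.

A small, self-contained GAM engine for overdispersed hourly counts with
a log link: penalized B-spline smooths (P-splines with second-order
difference penalties), full tensor-product interactions built as
row-wise Kronecker products of marginal bases, and ridge-penalized
per-individual random intercepts. Fitting is penalized IRLS; smoothing
parameters are chosen by minimizing the model's AICc (with effective
degrees of freedom from the trace of the influence matrix), so every
candidate model in a selection set is tuned and compared under one
criterion on one likelihood.

Families: Poisson and negative binomial (NB2 with fixed dispersion
``alpha``; Var = mu + alpha*mu^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = ["SmoothTerm", "GAM", "aicc", "estimate_nb_alpha"]

_ETA_CLIP = 30.0
_RIDGE = 1e-8


def aicc(loglik: float, edf: float, n: int) -> float:
    """Small-sample-corrected Akaike criterion.

    ``AICc = -2*loglik + 2*edf + 2*edf*(edf + 1)/(n - edf - 1)``; the
    correction requires ``n > edf + 1``.
    """
    if n <= edf + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed edf+1={edf + 1}")
    return -2.0 * loglik + 2.0 * edf + 2.0 * edf * (edf + 1.0) / (n - edf - 1.0)


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _bspline_design(x: np.ndarray, lo: float, hi: float, k: int, degree: int = 3):
    """Design matrix of a k-function B-spline basis on [lo, hi]; x is clipped."""
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis dimension k={k} too small for degree {degree}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()


@dataclass
class SmoothTerm:
    """One model term: a marginal smooth, a tensor product, or a random intercept.

    ``kind`` is ``"spline"`` (one variable, ``k`` basis functions),
    ``"tensor"`` (two variables, ``k x k`` basis) or ``"random"``
    (ridge-penalized intercept per level of a categorical variable).
    """

    kind: str
    variables: tuple
    k: int = 5
    # fitted state
    ranges_: list = field(default_factory=list)
    levels_: np.ndarray | None = None
    colmeans_: np.ndarray | None = None

    def label(self) -> str:
        if self.kind == "spline":
            return f"s({self.variables[0]})"
        if self.kind == "tensor":
            return f"te({self.variables[0]},{self.variables[1]})"
        return f"re({self.variables[0]})"

    def build(self, df: pd.DataFrame, fit: bool) -> np.ndarray:
        if self.kind == "random":
            if fit:
                self.levels_ = np.unique(df[self.variables[0]].to_numpy())
            levels = pd.Categorical(
                df[self.variables[0]], categories=self.levels_
            ).codes
            X = np.zeros((len(df), self.levels_.size))
            ok = levels >= 0
            X[np.flatnonzero(ok), levels[ok]] = 1.0
            return X
        if fit:
            self.ranges_ = [
                (float(df[v].min()), float(df[v].max())) for v in self.variables
            ]
            for lo, hi in self.ranges_:
                if hi <= lo:
                    raise ValueError(
                        f"degenerate (zero-range) covariate in {self.label()}"
                    )
        bases = [
            _bspline_design(df[v].to_numpy(), lo, hi, self.k)
            for v, (lo, hi) in zip(self.variables, self.ranges_)
        ]
        if self.kind == "spline":
            X = bases[0]
        elif self.kind == "tensor":
            X = (bases[0][:, :, None] * bases[1][:, None, :]).reshape(
                len(df), self.k * self.k
            )
        else:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if fit:
            self.colmeans_ = X.mean(axis=0)
        return X - self.colmeans_

    def penalties(self) -> list[np.ndarray]:
        """One penalty matrix per smoothing parameter of this term."""
        if self.kind == "random":
            return [np.eye(self.levels_.size)]
        if self.kind == "spline":
            return [_diff_penalty(self.k)]
        s = _diff_penalty(self.k)
        eye = np.eye(self.k)
        return [np.kron(s, eye), np.kron(eye, s)]

    def n_cols(self) -> int:
        if self.kind == "random":
            return self.levels_.size
        return self.k if self.kind == "spline" else self.k * self.k

    def random_zero(self) -> bool:
        return self.kind == "random"


class GAM:
    """Penalized additive count model with log link.

    Parameters
    ----------
    terms : list of SmoothTerm
        Model structure beyond the intercept.
    family : {"poisson", "nb"}
        Count family; ``"nb"`` is NB2 with fixed dispersion ``alpha``.
    alpha : float
        NB2 dispersion (ignored for Poisson).
    """

    def __init__(self, terms: list[SmoothTerm], family: str = "poisson", alpha: float = 0.0):
        if family not in ("poisson", "nb"):
            raise ValueError("family must be 'poisson' or 'nb'")
        self.terms = terms
        self.family = family
        self.alpha = float(alpha) if family == "nb" else 0.0

    # -- family helpers ------------------------------------------------------

    def _loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        if self.family == "poisson":
            return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
        a = self.alpha
        r = 1.0 / a
        return float(
            np.sum(
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1.0)
                + y * np.log(a * mu / (1.0 + a * mu))
                - r * np.log1p(a * mu)
            )
        )

    def _deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        if self.family == "poisson":
            return float(2.0 * np.sum(ylogy - (y - mu)))
        a = self.alpha
        return float(
            2.0 * np.sum(ylogy - (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu)))
        )

    def _weights(self, mu: np.ndarray) -> np.ndarray:
        if self.family == "poisson":
            return mu
        return mu / (1.0 + self.alpha * mu)

    # -- design assembly -----------------------------------------------------

    def _design(self, df: pd.DataFrame, fit: bool, population: bool = False) -> np.ndarray:
        blocks = [np.ones((len(df), 1))]
        for term in self.terms:
            X = term.build(df, fit=fit)
            if population and term.random_zero():
                X = np.zeros_like(X)
            blocks.append(X)
        return np.hstack(blocks)

    def _penalty_blocks(self) -> list[tuple[slice, np.ndarray]]:
        out = []
        col = 1  # skip the intercept
        for term in self.terms:
            nc = term.n_cols()
            for s in term.penalties():
                out.append((slice(col, col + nc), s))
            col += nc
        return out

    # -- fitting -------------------------------------------------------------

    def _pirls(self, X, y, lam, max_iter=60, tol=1e-7):
        n, p = X.shape
        S = np.zeros((p, p))
        for lam_j, (sl, pen) in zip(lam, self._penalty_blocks()):
            S[sl, sl] += lam_j * pen
        S[np.diag_indices(p)] += _RIDGE
        mu = y + 0.5
        eta = np.log(mu)
        dev = np.inf
        beta = np.zeros(p)
        for _ in range(max_iter):
            w = self._weights(mu)
            z = eta + (y - mu) / mu
            Xw = X * w[:, None]
            A = X.T @ Xw + S
            beta = np.linalg.solve(A, Xw.T @ z)
            eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            new_dev = self._deviance(y, mu)
            if abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
                dev = new_dev
                break
            dev = new_dev
        w = self._weights(mu)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + S
        Ainv = np.linalg.inv(A)
        edf = float(np.trace(Ainv @ XtWX))
        return beta, mu, edf, Ainv, dev

    def fit(self, df: pd.DataFrame, y_col: str = "flaps", optimize_lambda: bool = True,
            lam0: float = 1.0, maxiter: int = 60):
        """Fit by penalized IRLS; smoothing parameters minimize AICc."""
        y = df[y_col].to_numpy(dtype=float)
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        X = self._design(df, fit=True)
        n_pen = len(self._penalty_blocks())
        n = len(df)

        def objective(log_lam: np.ndarray) -> float:
            lam = np.exp(np.clip(log_lam, -12.0, 12.0))
            try:
                _, mu, edf, _, _ = self._pirls(X, y, lam)
                if n <= edf + 1:
                    return 1e12
                return aicc(self._loglik(y, mu), edf, n)
            except np.linalg.LinAlgError:
                return 1e12

        log_lam = np.full(n_pen, np.log(lam0))
        if optimize_lambda and n_pen:
            res = minimize(
                objective,
                log_lam,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 0.15, "fatol": 0.02},
            )
            log_lam = res.x
        lam = np.exp(np.clip(log_lam, -12.0, 12.0))
        beta, mu, edf, Ainv, dev = self._pirls(X, y, lam)
        if not np.all(np.isfinite(beta)):
            raise RuntimeError("IRLS failed to converge to finite coefficients")
        self.lambda_ = lam
        self.beta_ = beta
        self.cov_ = Ainv
        self.edf_ = edf
        self.mu_ = mu
        self.y_ = y
        self.n_ = n
        self.deviance_ = dev
        self.loglik_ = self._loglik(y, mu)
        self.aicc_ = aicc(self.loglik_, edf, n)
        mu0 = np.full_like(y, y.mean())
        self.null_deviance_ = self._deviance(y, mu0)
        self.dev_explained_ = 1.0 - dev / self.null_deviance_ if self.null_deviance_ > 0 else 0.0
        sd_y = np.std(y)
        self.r2_ = (
            float(np.corrcoef(mu, y)[0, 1] ** 2) if sd_y > 0 and np.std(mu) > 0 else 0.0
        )
        return self

    # -- prediction ----------------------------------------------------------

    def predict(self, df: pd.DataFrame, population: bool = True, se: bool = False):
        """Predicted mean response; ``population=True`` zeroes random effects.

        With ``se=True`` also returns the pointwise standard error of
        the linear predictor, from the penalized coefficient covariance.
        """
        X = self._design(df, fit=False, population=population)
        eta = np.clip(X @ self.beta_, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        if not se:
            return mu
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov_, X), 0.0))
        return mu, se_eta


def estimate_nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion from a fitted Poisson mean.

    Solves ``sum((y - mu)^2 - mu) = alpha * sum(mu^2)``; clipped at a
    small positive floor (a non-overdispersed sample degrades to
    near-Poisson NB).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return float(max(num / den, 1e-6)) if den > 0 else 1e-6
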
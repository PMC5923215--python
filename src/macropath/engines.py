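"""Phylogenetic regression engines.

Continuous dependents are fitted by generalized least squares whose residual
covariance is the shared-path-length matrix V, optionally rescaled by Pagel's
λ estimated by maximum likelihood.  Binary dependents are fitted by a
correlated-residual ("GEE"-style) logistic regression whose working
correlation interpolates between independence and the phylogenetic
correlation matrix through a single signal parameter in [0, 1].

All continuous variables are standardized (zero mean, unit variance) once,
before any fitting, so path coefficients are comparable across paths; binary
variables enter as 0/1 indicators and coefficients toward binary dependents
are on the logit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import PhyloCovariance

__all__ = [
    "RegressionFit",
    "detect_variable_kinds",
    "standardize_continuous",
    "encode_binary",
    "fit_pgls",
    "fit_phylo_logistic",
]

LAMBDA_LOWER = 1e-7
#: bounded-search windows for the λ profile likelihood (3 restarts)
_LAMBDA_WINDOWS = ((LAMBDA_LOWER, 0.4), (0.3, 0.7), (0.6, 1.0))


class FitError(RuntimeError):
    """Raised when a single regression cannot be fitted."""


class VariableKindError(ValueError):
    """Raised for unusable trait columns (e.g. >2 categorical levels)."""


@dataclass
class RegressionFit:
    """Result of one fitted independence-claim regression."""

    dependent: str
    terms: tuple[str, ...]
    coefficients: pd.Series  # includes "(Intercept)"
    std_errors: pd.Series
    focal: str
    focal_p: float
    focal_log_p: float  # natural log of focal_p, underflow-safe
    phylo_par: float  # fitted lambda (continuous) / signal (binary)
    loglik: float
    n: int
    dependent_kind: str  # "continuous" | "binary"


def detect_variable_kinds(data: pd.DataFrame) -> dict[str, str]:
    """Classify each trait column as continuous or binary.

    Numeric columns are continuous (a 0/1-coded numeric column stays
    continuous: recode it explicitly to mark it as binary).  Categorical or
    string columns must have exactly two observed levels.
    """
    kinds: dict[str, str] = {}
    for col in data.columns:
        series = data[col]
        if pd.api.types.is_bool_dtype(series):
            kinds[col] = "binary"
        elif pd.api.types.is_numeric_dtype(series):
            kinds[col] = "continuous"
        else:
            levels = series.astype(str).nunique()
            if levels == 2:
                kinds[col] = "binary"
            elif levels < 2:
                raise VariableKindError(
                    f"column {col!r} has a single level; binary traits need two"
                )
            else:
                raise VariableKindError(
                    f"column {col!r} has {levels} levels; categorical variables "
                    "with more than two levels are not supported"
                )
    return kinds


def standardize_continuous(
    data: pd.DataFrame, kinds: dict[str, str] | None = None
) -> pd.DataFrame:
    """Zero-mean, unit-variance (sd with n-1 denominator) continuous columns."""
    if kinds is None:
        kinds = detect_variable_kinds(data)
    out = data.copy()
    for col, kind in kinds.items():
        if kind != "continuous":
            continue
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise VariableKindError(f"column {col!r} has zero variance")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def encode_binary(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Code a two-level column as 0/1; levels sorted, second level -> 1."""
    if pd.api.types.is_bool_dtype(series):
        return series.to_numpy().astype(float), ["False", "True"]
    levels = sorted(series.astype(str).unique())
    if len(levels) != 2:
        raise VariableKindError(
            f"binary column must have exactly 2 levels, got {levels}"
        )
    return (series.astype(str) == levels[1]).to_numpy().astype(float), levels


def _design_matrix(
    terms: tuple[str, ...], data: pd.DataFrame, kinds: dict[str, str]
) -> np.ndarray:
    cols = [np.ones(len(data))]
    for term in terms:
        if kinds.get(term, "continuous") == "binary":
            col, _ = encode_binary(data[term])
        else:
            col = data[term].to_numpy(dtype=float)
        cols.append(col)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending terms: those whose removal restores full rank
        collinear = []
        for j, term in enumerate(terms, start=1):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(term)
        raise FitError(f"singular design matrix; collinear terms: {collinear}")
    return X


def _lambda_matrix(V: np.ndarray, lam: float) -> np.ndarray:
    m = V * lam
    np.fill_diagonal(m, np.diag(V))
    return m


def _gls_profile(y: np.ndarray, X: np.ndarray, Vlam: np.ndarray):
    """GLS estimate and ML profile log-likelihood for fixed covariance."""
    n = len(y)
    try:
        L = linalg.cholesky(Vlam, lower=True)
    except linalg.LinAlgError as exc:
        raise FitError(f"phylogenetic covariance not positive definite: {exc}")
    yt = linalg.solve_triangular(L, y, lower=True)
    Xt = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdet + n)
    return beta, rss, Xt, loglik


def fit_pgls(
    dependent: str,
    terms: tuple[str, ...] | list[str],
    data: pd.DataFrame,
    V: PhyloCovariance,
    evo_model: str = "lambda",
    kinds: dict[str, str] | None = None,
    focal: str | None = None,
) -> RegressionFit:
    """Phylogenetic GLS of ``dependent`` on ``terms``.

    ``evo_model="BM"`` uses the untransformed V; ``"lambda"`` maximizes the
    profile ML over λ ∈ [~0, 1] (bounded scalar search restarted from three
    windows).  The focal term's two-sided p-value uses a t reference with
    n - (number of mean parameters) degrees of freedom.
    """
    terms = tuple(terms)
    if kinds is None:
        kinds = detect_variable_kinds(data)
    if kinds.get(dependent) != "continuous":
        raise FitError(f"PGLS dependent {dependent!r} must be continuous")
    if focal is None:
        focal = terms[-1]
    y = data[dependent].to_numpy(dtype=float)
    X = _design_matrix(terms, data, kinds)
    n, p = X.shape
    if n <= p:
        raise FitError(f"n={n} too small for {p} mean parameters")
    Vm = V.matrix

    if evo_model == "BM":
        lam_hat = 1.0
    elif evo_model == "lambda":
        def nll(lam: float) -> float:
            return -_gls_profile(y, X, _lambda_matrix(Vm, lam))[3]

        best_lam, best_val = None, np.inf
        for lo, hi in _LAMBDA_WINDOWS:
            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if res.fun < best_val:
                best_lam, best_val = float(res.x), float(res.fun)
        for lam in (LAMBDA_LOWER, 1.0):
            val = nll(lam)
            if val < best_val:
                best_lam, best_val = lam, val
        lam_hat = best_lam
    else:
        raise ValueError(f"unknown evolution model {evo_model!r}")

    Vlam = _lambda_matrix(Vm, lam_hat)
    beta, rss, Xt, loglik = _gls_profile(y, X, Vlam)
    df = n - p
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(Xt.T @ Xt)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    names = ["(Intercept)"] + list(terms)
    focal_idx = names.index(focal)
    tval = beta[focal_idx] / se[focal_idx]
    log_p = math.log(2.0) + stats.t.logsf(abs(tval), df)
    return RegressionFit(
        dependent=dependent,
        terms=terms,
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        focal=focal,
        focal_p=float(np.exp(log_p)),
        focal_log_p=float(log_p),
        phylo_par=float(lam_hat),
        loglik=float(loglik),
        n=n,
        dependent_kind="continuous",
    )


def _corr_from_cov(V: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(V))
    return V / np.outer(d, d)


def _gee_beta_step(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, Rinv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Fisher-scoring step of the GEE estimating equations."""
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    a = np.sqrt(mu * (1.0 - mu))
    # working covariance A^1/2 R A^1/2; score X' A^1/2 R^-1 A^-1/2 (y - mu)
    Xa = X * a[:, None]
    J = Xa.T @ Rinv @ Xa
    U = Xa.T @ (Rinv @ ((y - mu) / a))
    try:
        step = np.linalg.solve(J, U)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular GEE information matrix: {exc}")
    return beta + step, J, mu


def _signal_nll(e: np.ndarray, R: np.ndarray, s: float) -> float:
    n = len(e)
    Rs = s * R + (1.0 - s) * np.eye(n)
    try:
        L = linalg.cholesky(Rs, lower=True)
    except linalg.LinAlgError:
        return np.inf
    z = linalg.solve_triangular(L, e, lower=True)
    quad = float(z @ z)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return n * math.log(max(quad, 1e-300) / n) + logdet


def fit_phylo_logistic(
    dependent: str,
    terms: tuple[str, ...] | list[str],
    data: pd.DataFrame,
    V: PhyloCovariance,
    kinds: dict[str, str] | None = None,
    focal: str | None = None,
    max_outer: int = 25,
    tol: float = 1e-8,
) -> RegressionFit:
    """Phylogenetic logistic regression for a two-level dependent.

    Correlated-residual GEE: the working correlation is
    ``s·C + (1-s)·I`` with C the phylogenetic correlation matrix and
    s ∈ [0, 1] the signal parameter, estimated by a Gaussian profile
    likelihood on the Pearson residuals; β is estimated by Fisher scoring of
    the GEE score at the current s.  On a star phylogeny (C = I) the fit
    reduces exactly to ordinary logistic regression.  Coefficients are on the
    logit scale; the focal p-value is a two-sided Wald test.
    """
    terms = tuple(terms)
    if kinds is None:
        kinds = detect_variable_kinds(data)
    if kinds.get(dependent) != "binary":
        raise FitError(f"logistic dependent {dependent!r} must be binary")
    if focal is None:
        focal = terms[-1]
    y, _levels = encode_binary(data[dependent])
    if y.min() == y.max():
        raise FitError(f"dependent {dependent!r} has a single observed level")
    X = _design_matrix(terms, data, kinds)
    n, p = X.shape
    if n <= p:
        raise FitError(f"n={n} too small for {p} mean parameters")
    C = _corr_from_cov(V.matrix)
    star = np.allclose(C, np.eye(n))

    beta = np.zeros(p)
    s_hat = 0.0
    Rinv = np.eye(n)
    J = None
    for _ in range(max_outer):
        # inner Fisher scoring for beta at current working correlation
        for _inner in range(200):
            new_beta, J, mu = _gee_beta_step(y, X, beta, Rinv)
            if not np.all(np.isfinite(new_beta)) or np.max(np.abs(new_beta)) > 30:
                raise FitError(
                    f"{dependent!r} regression diverged: quasi-complete "
                    "separation suspected (a predictor perfectly splits the "
                    "two levels)"
                )
            delta = np.max(np.abs(new_beta - beta))
            beta = new_beta
            if delta < tol:
                break
        else:
            raise FitError(f"{dependent!r} logistic fit did not converge")
        if star:
            break
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        e = (y - mu) / np.sqrt(mu * (1.0 - mu))
        res = optimize.minimize_scalar(
            lambda s: _signal_nll(e, C, s), bounds=(0.0, 1.0 - 1e-6),
            method="bounded", options={"xatol": 1e-5},
        )
        new_s = float(res.x) if res.fun < _signal_nll(e, C, 0.0) else 0.0
        Rs = new_s * C + (1.0 - new_s) * np.eye(n)
        Rinv = np.linalg.inv(Rs)
        if abs(new_s - s_hat) < 1e-5:
            s_hat = new_s
            break
        s_hat = new_s
    # refit beta at final correlation
    for _inner in range(200):
        new_beta, J, mu = _gee_beta_step(y, X, beta, Rinv)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta

    cov = np.linalg.inv(J)
    se = np.sqrt(np.diag(cov))
    names = ["(Intercept)"] + list(terms)
    focal_idx = names.index(focal)
    z = beta[focal_idx] / se[focal_idx]
    log_p = math.log(2.0) + stats.norm.logsf(abs(z))
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return RegressionFit(
        dependent=dependent,
        terms=terms,
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        focal=focal,
        focal_p=float(np.exp(log_p)),
        focal_log_p=float(log_p),
        phylo_par=float(s_hat),
        loglik=loglik,
        n=n,
        dependent_kind="binary",
    )
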
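"""Firth-penalized logistic regression and phenome-wide association testing.

Firth's penalty adds half the log-determinant of the Fisher information
to the logistic log-likelihood (a Jeffreys prior), which keeps estimates
finite under complete separation and reduces small-sample bias — the
regime of rare-variant association in cohorts with skewed case-control
ratios.  The fit maximizes

    l*(beta) = l(beta) + 0.5 * log |I(beta)|

by Newton iteration on the Firth-adjusted score
U*_j = sum_i (y_i - p_i + h_i (0.5 - p_i)) x_ij, with h_i the hat values
of the weighted design.  Per-coefficient p-values are Wald by default,
with a penalized likelihood-ratio option.

The phenome-wide scan fits one model per (variant, phenotype) with
covariates, skipping phenotypes under a minimum case count, flagging
results under a minimum minor-allele count or without convergence, and
reporting the Bonferroni threshold alpha / n_tested_phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "FirthResult",
    "firth_fit",
    "run_phewas",
]


@dataclass
class FirthResult:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    n_iter: int
    penalized_loglik: float


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood written to stay finite for extreme eta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    W = p * (1 - p)
    sign, logdet = np.linalg.slogdet(X.T * W @ X)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(
    X,
    y,
    max_iter: int = 100,
    tol: float = 1e-8,
    method: str = "wald",
) -> FirthResult:
    """Fit Firth-penalized logistic regression.

    ``X`` is the design matrix including the intercept column; ``y`` is
    binary.  ``method`` selects per-coefficient p-values: "wald" (default)
    or "lrt" (penalized likelihood ratio, each coefficient refitted at 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X and y are misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must not be constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    n, k = X.shape
    beta = np.zeros(k)
    ll_old = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1 - p)
        XtWX = X.T * W @ X
        XtWX_inv = np.linalg.inv(XtWX)
        # Hat values of the weighted least-squares problem.
        h = np.einsum("ij,jk,ik->i", X * W[:, None], XtWX_inv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        delta = XtWX_inv @ U
        # Step-halving keeps the penalized log-likelihood non-decreasing.
        step = 1.0
        for _ in range(25):
            ll_new = _penalized_loglik(X, y, beta + step * delta)
            if ll_new >= ll_old - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        ll_old = ll_new
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break

    p_fit = expit(X @ beta)
    W = p_fit * (1 - p_fit)
    cov = np.linalg.inv(X.T * W @ X)
    se = np.sqrt(np.diag(cov))

    if method == "wald":
        z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    elif method == "lrt":
        pvals = np.empty(k)
        for j in range(k):
            keep = [c for c in range(k) if c != j]
            reduced = firth_fit(X[:, keep], y, max_iter, tol, method="wald")
            lr = 2.0 * (ll_old - reduced.penalized_loglik)
            pvals[j] = stats.chi2.sf(max(lr, 0.0), 1)
    else:
        raise ValueError("method must be 'wald' or 'lrt'")

    return FirthResult(beta, se, pvals, converged, it, ll_old)


def run_phewas(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
    min_cases: int = 50,
    min_mac: int = 20,
    alpha: float = 0.05,
    method: str = "wald",
) -> tuple[pd.DataFrame, float]:
    """Firth association of every variant against every phenotype.

    Genotypes are 0/1/2 dosages (NA allowed; samples with missing dosage
    are dropped per test).  Phenotypes with fewer than ``min_cases`` cases
    are skipped and do not count toward the Bonferroni denominator.
    Results with minor allele count below ``min_mac`` or without
    convergence keep their row but are flagged ``passed_filters=False``.
    Returns the result table and the Bonferroni threshold
    ``alpha / n_tested_phenotypes``.
    """
    if isinstance(phenotypes, pd.Series):
        phenotypes = phenotypes.to_frame()
    if not (genotypes.index.equals(phenotypes.index) and genotypes.index.equals(covariates.index)):
        raise ValueError("sample ids of genotypes, phenotypes and covariates are misaligned")

    tested = [
        ph for ph in phenotypes.columns
        if int(phenotypes[ph].sum()) >= min_cases
    ]
    if not tested:
        raise ValueError(f"no phenotype reaches {min_cases} cases")
    threshold = alpha / len(tested)

    rows = []
    for ph in tested:
        y_all = phenotypes[ph]
        for var in genotypes.columns:
            g = genotypes[var]
            mask = g.notna() & y_all.notna()
            gv = g[mask].to_numpy(dtype=float)
            yv = y_all[mask].to_numpy(dtype=float)
            cv = covariates.loc[mask].to_numpy(dtype=float)
            ac = gv.sum()
            mac = int(min(ac, 2 * len(gv) - ac))
            n_cases = int(yv.sum())
            n_controls = int(len(yv) - n_cases)
            X = np.column_stack([np.ones(len(gv)), gv, cv])
            beta = se = p = np.nan
            conv = False
            try:
                fit = firth_fit(X, yv, method=method)
                beta, se, p = float(fit.beta[1]), float(fit.se[1]), float(fit.p[1])
                conv = fit.converged
            except (ValueError, np.linalg.LinAlgError) as err:
                warnings.warn(f"{var} x {ph}: {err}")
            rows.append(
                {
                    "variant": var,
                    "phenotype": ph,
                    "n_cases": n_cases,
                    "n_controls": n_controls,
                    "mac": mac,
                    "beta": beta,
                    "se": se,
                    "odds_ratio": float(np.exp(beta)) if np.isfinite(beta) else np.nan,
                    "p": p,
                    "converged": conv,
                    "passed_filters": bool(conv and mac >= min_mac),
                }
            )
    return pd.DataFrame(rows), threshold
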
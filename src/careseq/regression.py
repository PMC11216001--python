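"""Shared weighted-regression machinery.

Survey-style estimation throughout the package: observation weights enter
the estimating equations, and variances come from the weighted sandwich
(Horvitz-Thompson-type) estimator with weights in both bread and meat,
treating the weights as known.  A weighted multinomial (baseline-category)
logit is implemented here directly because no installed library fits one
with observation weights; its equal-weight binary reduction is checked
against the standard logistic MLE in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_matrix(
    df: pd.DataFrame,
    categorical: dict[str, str] | None = None,
    continuous: list[str] | None = None,
    interactions: list[tuple[str, str]] | None = None,
    intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build a dummy-coded design matrix.

    ``categorical`` maps column -> reference level (validated to exist);
    ``interactions`` crosses the non-reference dummies of two categorical
    columns already listed in ``categorical``.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(df)
    if intercept:
        cols.append(np.ones(n))
        names.append("Intercept")
    level_dummies: dict[str, list[tuple[str, np.ndarray]]] = {}
    for col, ref in (categorical or {}).items():
        vals = df[col].astype(str).to_numpy()
        levels = [lv for lv in pd.unique(vals) if lv != ref]
        if ref not in set(vals) and len(levels) == len(pd.unique(vals)):
            raise ValueError(f"reference level {ref!r} absent from column {col!r}")
        dummies = []
        for lv in sorted(levels):
            d = (vals == lv).astype(float)
            dummies.append((lv, d))
            cols.append(d)
            names.append(f"{col}[{lv}]")
        level_dummies[col] = dummies
    for col in continuous or []:
        cols.append(df[col].to_numpy(dtype=float))
        names.append(col)
    for ca, cb in interactions or []:
        for la, da in level_dummies[ca]:
            for lb, db in level_dummies[cb]:
                cols.append(da * db)
                names.append(f"{ca}[{la}]:{cb}[{lb}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# effect-estimate container
# ---------------------------------------------------------------------------

def effect_table(terms, coefs, cov, conf_level: float = 0.95) -> pd.DataFrame:
    """Exponentiated coefficients with Wald CIs and p-values on the log scale."""
    coefs = np.asarray(coefs, dtype=float)
    se = np.sqrt(np.diag(np.atleast_2d(cov)))
    z = norm.ppf(0.5 + conf_level / 2.0)
    pvals = 2.0 * norm.sf(np.abs(coefs / np.where(se > 0, se, np.inf)))
    with np.errstate(over="ignore"):  # diverged nuisance terms -> inf, kept as such
        return pd.DataFrame(
            {
                "term": list(terms),
                "estimate": np.exp(coefs),
                "se_log": se,
                "ci_low": np.exp(coefs - z * se),
                "ci_high": np.exp(coefs + z * se),
                "p_value": pvals,
            }
        )


# ---------------------------------------------------------------------------
# weighted GLMs with sandwich covariance
# ---------------------------------------------------------------------------

@dataclass
class WeightedGLMFit:
    params: np.ndarray
    cov: np.ndarray            # weighted HC0 sandwich
    names: list[str]
    mu: np.ndarray
    converged: bool
    iteration_trace: list[float]

    def table(self) -> pd.DataFrame:
        return effect_table(self.names, self.params, self.cov)


def _irls(X, y, w, family: str, maxiter: int = 100, tol: float = 1e-10):
    """IRLS for canonical-link binomial (logit) or Poisson (log) models."""
    n, p = X.shape
    beta = np.zeros(p)
    mean_y = np.clip(np.average(y, weights=w), 1e-8, None)
    beta[0] = np.log(mean_y / (1 - mean_y)) if family == "binomial" else np.log(mean_y)
    trace = []
    for _ in range(maxiter):
        eta = X @ beta
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            v = np.clip(mu * (1 - mu), 1e-12, None)
        else:
            mu = np.exp(np.clip(eta, -35, 35))
            v = np.clip(mu, 1e-12, None)
        z = eta + (y - mu) / v
        ww = w * v
        XtW = X.T * ww
        H = XtW @ X
        try:
            new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError:
            # near-empty cells can zero out a column; the pseudoinverse pins
            # the unidentified coefficient without touching the others
            new = np.linalg.pinv(H) @ (XtW @ z)
        delta = float(np.max(np.abs(new - beta)))
        trace.append(delta)
        beta = new
        if delta < tol:
            return beta, mu, v, True, trace
    return beta, mu, v, False, trace


def fit_weighted_glm(X, y, weights, family: str, names=None,
                     require_convergence: bool = True) -> WeightedGLMFit:
    """Weighted logistic or modified-Poisson fit with sandwich covariance.

    family = "binomial" (logit link) or "poisson" (log link; used on binary
    outcomes to estimate risk ratios, where the sandwich variance is the
    standard remedy for the misspecified Poisson variance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    beta, mu, v, ok, trace = _irls(X, y, w, family)
    if not ok and require_convergence:
        raise RuntimeError(
            f"weighted {family} IRLS did not converge; |step| trace tail "
            f"{[f'{t:.2e}' for t in trace[-5:]]}"
        )
    bread = np.linalg.pinv((X.T * (w * v)) @ X)
    score = X * (w * (y - mu))[:, None]
    meat = score.T @ score
    cov = bread @ meat @ bread
    return WeightedGLMFit(
        params=beta, cov=cov, names=list(names) if names else [f"x{i}" for i in range(X.shape[1])],
        mu=mu, converged=ok, iteration_trace=trace,
    )


# ---------------------------------------------------------------------------
# weighted multinomial (baseline-category) logit
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    """Weighted baseline-category logit fit.

    ``params`` has one row per non-reference outcome category, one column per
    design column; ``cov`` is the sandwich covariance of the row-major
    flattened parameters.
    """

    params: np.ndarray          # (K-1, p)
    cov: np.ndarray             # ((K-1)p, (K-1)p)
    categories: list[str]       # K labels, reference first
    names: list[str]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = X @ self.params.T
        full = np.concatenate([np.zeros((len(X), 1)), eta], axis=1)
        full -= full.max(axis=1, keepdims=True)
        p = np.exp(full)
        return p / p.sum(axis=1, keepdims=True)

    def table(self) -> pd.DataFrame:
        rows = []
        p = len(self.names)
        for k, cat in enumerate(self.categories[1:]):
            cov_k = self.cov[k * p:(k + 1) * p, k * p:(k + 1) * p]
            tab = effect_table(self.names, self.params[k], cov_k)
            tab.insert(0, "category", cat)
            rows.append(tab)
        return pd.concat(rows, ignore_index=True)


def fit_weighted_multinomial_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    categories: list[str],
    names: list[str] | None = None,
) -> MultinomialFit:
    """Weighted multinomial logit by maximum likelihood with sandwich SEs.

    ``y`` holds integer category indices with 0 the reference; ``categories``
    lists the K labels in index order.
    """
    X_orig = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    w = np.asarray(weights, dtype=float)
    n, p = X_orig.shape
    K = len(categories)
    if K < 2:
        raise ValueError("need at least two outcome categories")

    # standardise non-constant columns for optimiser conditioning; the
    # coefficients and covariance are mapped back to the original scale below
    is_const = X_orig.std(axis=0) == 0
    if not is_const.any():
        raise ValueError("design must contain an intercept column")
    center = np.where(is_const, 0.0, X_orig.mean(axis=0))
    scale = np.where(is_const, 1.0, np.where(X_orig.std(axis=0) > 0, X_orig.std(axis=0), 1.0))
    X = (X_orig - center) / scale

    ind = np.zeros((n, K - 1))
    for k in range(1, K):
        ind[:, k - 1] = y == k

    def negll_grad(theta):
        B = theta.reshape(K - 1, p)
        eta = X @ B.T                               # (n, K-1)
        full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        lse = logsumexp(full, axis=1)
        ll = np.sum(w * (np.where(y > 0, np.take_along_axis(
            eta, np.clip(y - 1, 0, K - 2)[:, None], axis=1).ravel(), 0.0) - lse))
        prob = np.exp(full - lse[:, None])          # (n, K)
        resid = ind - prob[:, 1:]                   # (n, K-1)
        grad = (resid * w[:, None]).T @ X           # (K-1, p)
        return -ll, -grad.ravel()

    theta0 = np.zeros((K - 1) * p)
    res = optimize.minimize(negll_grad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 5000, "maxfun": 20000,
                                     "ftol": 1e-13, "gtol": 1e-8})
    if not res.success:
        raise RuntimeError(f"weighted multinomial fit failed: {res.message}")
    B = res.x.reshape(K - 1, p).copy()
    # map back to the original covariate scale
    const_idx = int(np.flatnonzero(is_const)[0])
    B /= scale[None, :]
    B[:, const_idx] -= (B[:, ~is_const] * center[~is_const]).sum(axis=1)
    X = X_orig

    eta = X @ B.T
    full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    prob = np.exp(full - logsumexp(full, axis=1)[:, None])
    pk = prob[:, 1:]                                # (n, K-1)
    # bread: weighted Fisher information, blocks (k,l) = X' W diag(p_k δ_kl − p_k p_l) X
    info = np.zeros(((K - 1) * p, (K - 1) * p))
    for k in range(K - 1):
        for l in range(K - 1):
            v = pk[:, k] * ((k == l) - pk[:, l])
            info[k * p:(k + 1) * p, l * p:(l + 1) * p] = (X.T * (w * v)) @ X
    bread = np.linalg.pinv(info)
    # meat: per-observation weighted score outer products
    resid = (ind - pk) * w[:, None]                 # (n, K-1)
    score = np.einsum("nk,np->nkp", resid, X).reshape(n, (K - 1) * p)
    meat = score.T @ score
    cov = bread @ meat @ bread
    return MultinomialFit(params=B, cov=cov, categories=list(categories),
                          names=list(names) if names else [f"x{i}" for i in range(p)])
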
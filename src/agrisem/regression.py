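"""Local regressions that parameterise the path diagram.

Every link coefficient in the analysis comes from one of two model families
fitted per response node: ordinary least squares for Gaussian land-cover
variables, and a Poisson log-link GLM (iteratively reweighted least squares)
for richness counts.  All predictors are standardised before fitting;
richness responses are left as raw counts.  Candidate models per response
are ranked by small-sample AICc, and predictors receive "strong" support
when they sit in the top model, "weak" support when they appear only in a
model within the ΔAICc window.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "FitResult",
    "ModelSelectionResult",
    "DegenerateInputError",
    "standardize",
    "design_matrix",
    "fit_linear",
    "fit_poisson",
    "fit_glm",
    "aicc",
    "all_subsets_selection",
]


class DegenerateInputError(ValueError):
    """Raised for inputs a regression cannot digest (zero variance, rank
    deficiency, all-zero counts, non-convergence)."""


@dataclass(frozen=True)
class FitResult:
    """One fitted local model.

    Coefficients are on the standardised-predictor scale and include the
    intercept as the first entry (term ``"(intercept)"``).  ``n_params``
    counts the intercept and slopes plus, for Gaussian fits, the error
    variance — so AICc is comparable across families.
    """

    response: str
    family: str
    terms: tuple[str, ...]          # excludes the intercept
    coefficients: tuple[float, ...]  # intercept first
    standard_errors: tuple[float, ...]
    loglik: float
    n: int
    n_params: int
    df_resid: int

    def coef(self, term: str) -> float:
        return self.coefficients[self.terms.index(term) + 1]

    def se(self, term: str) -> float:
        return self.standard_errors[self.terms.index(term) + 1]

    def wald_p(self, term: str) -> float:
        """Two-sided p-value for a single slope.

        Gaussian fits use the exact t reference on the residual degrees of
        freedom; Poisson fits use the large-sample normal reference.
        """
        z = self.coef(term) / self.se(term)
        if self.family == "gaussian":
            return float(2.0 * stats.t.sf(abs(z), self.df_resid))
        return float(2.0 * stats.norm.sf(abs(z)))


def standardize(column) -> np.ndarray:
    """Centre and scale to sample standard deviation 1 (n−1 denominator)."""
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("standardize needs a 1-d vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero or non-finite variance")
    return (x - x.mean()) / sd


def design_matrix(table: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Build [1 | columns] from term names; ``name^2`` squares the column."""
    n = len(table)
    cols = [np.ones(n)]
    for t in terms:
        if t.endswith("^2"):
            cols.append(np.asarray(table[t[:-2]], dtype=float) ** 2)
        else:
            cols.append(np.asarray(table[t], dtype=float))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, terms: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateInputError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); terms: {terms}"
        )


def fit_linear(response, X: np.ndarray, terms: tuple[str, ...] = (),
               response_name: str = "y") -> FitResult:
    """Ordinary least squares with a Gaussian log-likelihood at the MLE
    error variance (RSS/n); standard errors use the unbiased RSS/(n−p)."""
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length does not match design rows")
    _check_rank(X, terms)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2_mle = rss / n
    if sigma2_mle <= 0:
        sigma2_mle = np.finfo(float).tiny
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2_mle) + 1.0)
    df_resid = n - p
    sigma2_hat = rss / df_resid if df_resid > 0 else float("nan")
    cov = np.linalg.inv(xtx) * sigma2_hat
    ses = np.sqrt(np.diag(cov))
    return FitResult(
        response=response_name,
        family="gaussian",
        terms=tuple(terms),
        coefficients=tuple(float(b) for b in beta),
        standard_errors=tuple(float(s) for s in ses),
        loglik=float(loglik),
        n=n,
        n_params=p + 1,  # + error variance
        df_resid=df_resid,
    )


def fit_poisson(response, X: np.ndarray, terms: tuple[str, ...] = (),
                response_name: str = "y", tol: float = 1e-10,
                max_iter: int = 100) -> FitResult:
    """Poisson log-link GLM by iteratively reweighted least squares.

    Starts from the intercept ln(mean+0.5) with zero slopes and stops when
    the relative deviance change falls below ``tol``.
    """
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length does not match design rows")
    if np.any(y < 0):
        raise DegenerateInputError("negative counts")
    if np.all(y == 0):
        raise DegenerateInputError("all-zero response: intercept diverges to -inf")
    _check_rank(X, terms)

    beta = np.zeros(p)
    beta[0] = math.log(y.mean() + 0.5)
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        W = mu  # Poisson working weights
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / np.exp(np.clip(X @ beta, -30, 30))), 0.0)
        dev = 2.0 * float(np.sum(dev_terms - (y - np.exp(np.clip(X @ beta, -30, 30)))))
        if abs(dev - dev_old) <= tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    if not converged:
        raise DegenerateInputError(f"IRLS did not converge in {max_iter} iterations")
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    loglik = float(np.sum(y * eta - mu - special.gammaln(y + 1.0)))
    cov = np.linalg.inv((X.T * mu) @ X)
    ses = np.sqrt(np.diag(cov))
    return FitResult(
        response=response_name,
        family="poisson",
        terms=tuple(terms),
        coefficients=tuple(float(b) for b in beta),
        standard_errors=tuple(float(s) for s in ses),
        loglik=loglik,
        n=n,
        n_params=p,
        df_resid=n - p,
    )


def fit_glm(response, X: np.ndarray, family: str, terms: tuple[str, ...] = (),
            response_name: str = "y") -> FitResult:
    if family == "gaussian":
        return fit_linear(response, X, terms, response_name)
    if family == "poisson":
        return fit_poisson(response, X, terms, response_name)
    raise ValueError(f"unknown family {family!r}")


def aicc(loglik: float, n_params: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2K(K+1)/(n−K−1)."""
    if n <= n_params + 1:
        raise ValueError(f"AICc undefined: n={n} <= n_params+1={n_params + 1}")
    aic = -2.0 * loglik + 2.0 * n_params
    return aic + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)


@dataclass(frozen=True)
class ModelSelectionResult:
    """All-subsets AICc ranking for one response node.

    ``candidates`` holds (fit, AICc, ΔAICc) ascending; ``support`` labels
    each predictor group strong/weak/none; ``effect_coefficients`` gives the
    coefficient used on the corresponding diagram link (top-model estimate
    for strong predictors, best ΔAICc≤window model estimate for weak ones,
    0 otherwise).  Quadratic groups report the pair (linear, quadratic)
    under the terms ``x`` and ``x^2``.
    """

    response: str
    family: str
    candidates: tuple[tuple[FitResult, float, float], ...]
    support: dict[str, str] = field(default_factory=dict)
    effect_coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def top(self) -> FitResult:
        return self.candidates[0][0]


def _expand_group(group: str) -> tuple[str, ...]:
    """A predictor group is either ``x`` or ``x+x^2`` (quadratic pair)."""
    return tuple(group.split("+"))


def all_subsets_selection(
    response: str,
    predictors: list[str],
    table: pd.DataFrame,
    family: str,
    delta_window: float = 2.0,
) -> ModelSelectionResult:
    """Fit the null model, the global model and every sub-model, rank by
    AICc, and label predictor support.

    ``predictors`` lists groups: plain node names, or ``"x+x^2"`` for a
    quadratic pair whose terms enter and leave candidate models together.
    Ties in AICc prefer fewer parameters, then lexicographic term order.
    """
    groups = sorted(set(predictors))
    if len(groups) > 12:
        raise ValueError("more than 12 predictor groups: candidate set too large")
    y = np.asarray(table[response], dtype=float)
    fits: list[tuple[FitResult, float]] = []
    for r in range(len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            terms = tuple(t for g in subset for t in _expand_group(g))
            X = design_matrix(table, terms)
            try:
                fit = fit_glm(y, X, family, terms, response)
            except DegenerateInputError as err:
                raise DegenerateInputError(
                    f"subset {subset} for response {response!r}: {err}"
                ) from err
            fits.append((fit, aicc(fit.loglik, fit.n_params, fit.n)))

    fits.sort(key=lambda fa: (fa[1], fa[0].n_params, fa[0].terms))
    best = fits[0][1]
    candidates = tuple((f, a, a - best) for f, a in fits)

    top_terms = set(candidates[0][0].terms)
    support: dict[str, str] = {}
    effect: dict[str, float] = {}
    for g in groups:
        terms = _expand_group(g)
        if set(terms) <= top_terms:
            support[g] = "strong"
            for t in terms:
                effect[t] = candidates[0][0].coef(t)
            continue
        # best-ranked model inside the window containing the group
        holder = next(
            (f for f, _, d in candidates if d <= delta_window and set(terms) <= set(f.terms)),
            None,
        )
        if holder is not None:
            support[g] = "weak"
            for t in terms:
                effect[t] = holder.coef(t)
        else:
            support[g] = "none"
            for t in terms:
                effect[t] = 0.0
    return ModelSelectionResult(
        response=response,
        family=family,
        candidates=candidates,
        support=support,
        effect_coefficients=effect,
    )
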
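"""Intelligibility statistics: logistic GLMM and beta-binomial regression.

Two model classes in the statsmodels mould — construct from data, call
``fit()``, get a results object with estimates, standard errors, Wald
tests, AICc and AUC, and a ``summary()`` table.

:class:`LogisticGLMM` fits a logistic mixed model with a single random
intercept (participant) by maximum likelihood, integrating the random
effect with adaptive Gauss-Hermite quadrature (the quadrature grid is
re-centred at each group's posterior mode and rescaled by the local
curvature).  :class:`BetaBinomial` fits a beta-binomial regression with a
logit mean model mu = logistic(X b) and a single intra-trial correlation
rho, via alpha = mu (1-rho)/rho, beta = (1-mu)(1-rho)/rho.  Both reduce to
ordinary logistic regression in their no-heterogeneity limits
(sigma_u -> 0, rho -> 0), which the test suite exploits as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats as sps

__all__ = [
    "ConvergenceError",
    "LogisticGLMM",
    "BetaBinomial",
    "GLMMResults",
    "BetaBinomialResults",
    "aicc",
    "auc",
    "build_design_matrix",
]

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


class ConvergenceError(RuntimeError):
    """Optimiser failed to reach the required gradient tolerance."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def auc(outcomes: np.ndarray, fitted: np.ndarray) -> float:
    """Area under the ROC curve, rank formulation with ties counted half.

    The probability that a randomly chosen positive outcome receives a
    higher fitted value than a randomly chosen negative one.  Invariant
    under strictly monotone transforms of ``fitted``.
    """
    y = np.asarray(outcomes).astype(bool)
    p = np.asarray(fitted, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both outcome classes must be present")
    ranks = sps.rankdata(p)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def build_design_matrix(
    data: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix with intercept from term names.

    Categorical (object/category) columns are dummy-coded dropping the first
    level; ``"a:b"`` denotes an interaction (elementwise product of the
    coded columns).
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}

    def coded(name: str) -> dict[str, np.ndarray]:
        s = data[name]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(pd.unique(s).tolist())
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} has a single level")
            return {f"{name}[{lv}]": (s == lv).to_numpy(float) for lv in levels[1:]}
        return {name: s.to_numpy(float)}

    for term in terms:
        parts = term.split(":")
        sub = [coded(p) for p in parts]
        combo = sub[0]
        for nxt in sub[1:]:
            combo = {
                f"{k1}:{k2}": v1 * v2 for k1, v1 in combo.items() for k2, v2 in nxt.items()
            }
        cols.update(combo)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (degenerate factor coding)")
    return X, names


def _wald_table(params: np.ndarray, bse: np.ndarray, names: list[str]) -> pd.DataFrame:
    chi2 = (params / bse) ** 2
    return pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "wald_chi2": chi2,
            "p": sps.chi2.sf(chi2, df=1),
        },
        index=names,
    )


def _numeric_hessian(fun, x, step=1e-4):
    x = np.asarray(x, dtype=float)
    k = x.size
    h = step * (1.0 + np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * h[i] * h[j])
    return hess


# ---------------------------------------------------------------------------
# logistic GLMM


class LogisticGLMM:
    """Logistic mixed model with one random intercept, fitted by ML.

    Parameters
    ----------
    endog : array of 0/1 outcomes (one row per scoring unit)
    exog : fixed-effects design matrix (with intercept column)
    groups : group labels for the random intercept (participants)
    exog_names : optional column names for reporting
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be 2-D with one row per outcome")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        codes, uniques = pd.factorize(np.asarray(groups))
        if uniques.size < 2:
            raise ValueError("need >= 2 groups for a random intercept")
        self.group_labels = uniques
        self.group_codes = codes  # per original row
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        # collapse duplicate (group, x-row, y) rows into weights: the
        # likelihood only depends on these sufficient statistics
        df = pd.DataFrame(self.exog)
        df["__g"] = codes
        df["__y"] = self.endog
        grouped = df.groupby(list(df.columns), sort=True).size().reset_index(name="__w")
        grouped = grouped.sort_values("__g", kind="stable")
        self._g = grouped["__g"].to_numpy(np.int64)
        self._y = grouped["__y"].to_numpy(float)
        self._w = grouped["__w"].to_numpy(float)
        self._X = grouped[list(range(self.exog.shape[1]))].to_numpy(float)
        self.n_groups = uniques.size
        self._starts = np.searchsorted(self._g, np.arange(self.n_groups))
        self.nobs = self.endog.size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, terms: list[str], group: str):
        X, names = build_design_matrix(data, terms)
        return cls(data[response].to_numpy(float), X, data[group].to_numpy(), names)

    # -- likelihood machinery -----------------------------------------------

    def _group_modes(self, eta: np.ndarray, sigma2: float, n_iter: int = 30):
        """Posterior modes and curvatures of the random intercepts, all
        groups at once (Newton iterations on scalars)."""
        u = np.zeros(self.n_groups)
        w, y = self._w, self._y
        for _ in range(n_iter):
            p = special.expit(eta + u[self._g])
            grad = np.bincount(self._g, w * (y - p), minlength=self.n_groups) - u / sigma2
            curv = -np.bincount(self._g, w * p * (1 - p), minlength=self.n_groups) - 1.0 / sigma2
            step = grad / curv
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = special.expit(eta + u[self._g])
        curv = -np.bincount(self._g, w * p * (1 - p), minlength=self.n_groups) - 1.0 / sigma2
        return u, curv

    def _loglike_parts(self, params: np.ndarray, n_quad: int):
        beta, log_sigma = params[:-1], params[-1]
        sigma2 = np.exp(2.0 * log_sigma)
        eta = self._X @ beta
        u_hat, curv = self._group_modes(eta, sigma2)
        tau = 1.0 / np.sqrt(-curv)
        if n_quad not in _GH_CACHE:
            _GH_CACHE[n_quad] = np.polynomial.hermite.hermgauss(n_quad)
        nodes, weights = _GH_CACHE[n_quad]
        # adaptive grid: u = u_hat + sqrt(2) tau z
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (G, K)
        eta_nodes = eta[:, None] + u_nodes[self._g]  # (R, K)
        ll_rows = self._w[:, None] * (
            self._y[:, None] * eta_nodes - np.logaddexp(0.0, eta_nodes)
        )
        ll_groups = np.add.reduceat(ll_rows, self._starts, axis=0)  # (G, K)
        log_prior = -0.5 * u_nodes**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        log_terms = np.log(weights)[None, :] + nodes[None, :] ** 2 + ll_groups + log_prior
        per_group = special.logsumexp(log_terms, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
        return per_group, log_terms, eta_nodes, u_nodes, sigma2

    def loglike(self, params: np.ndarray, n_quad: int = 15) -> float:
        """Marginal log-likelihood at (beta, log sigma_u)."""
        per_group, *_ = self._loglike_parts(params, n_quad)
        return float(per_group.sum())

    def score(self, params: np.ndarray, n_quad: int = 15) -> np.ndarray:
        """Analytic gradient of the marginal log-likelihood.

        Posterior expectation of the complete-data score under the quadrature
        weights (the quadrature grid's own parameter dependence contributes
        only at the quadrature-error order).
        """
        per_group, log_terms, eta_nodes, u_nodes, sigma2 = self._loglike_parts(
            params, n_quad
        )
        post = np.exp(log_terms - special.logsumexp(log_terms, axis=1, keepdims=True))
        resid = self._w[:, None] * (self._y[:, None] - special.expit(eta_nodes))  # (R, K)
        d = (resid * post[self._g]).sum(axis=1)  # (R,)
        grad_beta = self._X.T @ d
        grad_log_sigma = float((post * (u_nodes**2 / sigma2 - 1.0)).sum())
        return np.append(grad_beta, grad_log_sigma)

    def loglike_bruteforce(self, params: np.ndarray, limit: float = 12.0) -> float:
        """Brute-force numerical integration of the random-effect integral
        (scipy.integrate.quad per group); the independent oracle for the
        quadrature implementation on tiny datasets."""
        from scipy.integrate import quad

        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = self._X @ beta
        total = 0.0
        for gi in range(self.n_groups):
            sel = self._g == gi
            e, y, w = eta[sel], self._y[sel], self._w[sel]

            def integrand(u):
                ll = np.sum(w * (y * (e + u) - np.logaddexp(0.0, e + u)))
                return np.exp(ll) * sps.norm.pdf(u, scale=sigma)

            val, _ = quad(integrand, -limit * sigma, limit * sigma, limit=200)
            total += np.log(val)
        return float(total)

    def fit(self, n_quad: int = 15, gtol: float = 1e-6, maxiter: int = 500) -> "GLMMResults":
        if n_quad < 9:
            raise ValueError("adaptive Gauss-Hermite quadrature requires >= 9 nodes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                self._y, self._X, family=sm.families.Binomial(), freq_weights=self._w
            ).fit()
        x0 = np.append(glm.params, np.log(0.3))
        # optimise in a column-scaled space: wildly different covariate
        # magnitudes (ms-scale durations vs unit dummies) otherwise leave
        # BFGS ill-conditioned
        col_scale = np.append(np.maximum(np.abs(self._X).max(axis=0), 1e-12), 1.0)

        def nll(xs):
            return -self.loglike(xs / col_scale, n_quad=n_quad)

        def njac(xs):
            return -self.score(xs / col_scale, n_quad=n_quad) / col_scale

        res = optimize.minimize(
            nll, x0 * col_scale, jac=njac, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        # convergence: gradient norm below gtol relative to the likelihood
        # magnitude (the absolute criterion is meaningless across data sizes)
        scale = max(1.0, abs(res.fun))
        grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > gtol * scale:
            # polish: restart once from the current point
            res = optimize.minimize(
                nll, res.x, jac=njac, method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > max(gtol * scale, 1e-4):
            raise ConvergenceError(
                f"GLMM optimisation failed: {res.message} (|grad|={grad_norm:.2e})"
            )
        params = res.x / col_scale
        hess_s = _numeric_hessian(nll, res.x)
        try:
            cov_s = np.linalg.inv(hess_s)
        except np.linalg.LinAlgError:
            cov_s = np.linalg.pinv(hess_s)
        # vanished curvature on the linear-predictor scale marks separation
        # (or an otherwise unidentified coefficient)
        if np.any(np.sqrt(np.clip(np.diag(cov_s)[:-1], 0, None)) > 50):
            warnings.warn(
                "coefficient unidentified at the linear-predictor scale: "
                "possible complete separation",
                RuntimeWarning,
            )
        cov = cov_s / np.outer(col_scale, col_scale)
        llf = -res.fun
        # empirical-Bayes intercept modes for conditional fitted values
        sigma2 = max(np.exp(2 * params[-1]), 1e-12)
        u_hat, _ = self._group_modes(self._X @ params[:-1], sigma2)
        return GLMMResults(self, params, cov, llf, res, u_hat)


@dataclass
class GLMMResults:
    """ML estimates for a logistic random-intercept model."""

    model: LogisticGLMM
    _params: np.ndarray
    cov: np.ndarray
    llf: float
    optim_result: object
    random_effects: np.ndarray

    def __post_init__(self) -> None:
        self.params = self._params[:-1]
        self.bse = np.sqrt(np.clip(np.diag(self.cov)[:-1], 0.0, None))
        self.sigma_u = float(np.exp(self._params[-1]))
        self.sigma_u2 = self.sigma_u**2
        self.k_params = self._params.size
        self.nobs = self.model.nobs
        self.aicc = aicc(self.llf, self.k_params, self.nobs)
        self.exog_names = self.model.exog_names

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional fitted probabilities (empirical-Bayes intercepts)."""
        return special.expit(
            self.model.exog @ self.params + self.random_effects[self.model.group_codes]
        )

    @property
    def auc(self) -> float:
        return auc(self.model.endog, self.fittedvalues)

    def wald_table(self) -> pd.DataFrame:
        return _wald_table(self.params, self.bse, self.exog_names)

    def summary(self) -> str:
        tbl = self.wald_table()
        lines = [
            "Logistic GLMM (random intercept, adaptive Gauss-Hermite ML)",
            f"  groups: {self.model.n_groups}   units: {self.nobs}",
            f"  log-likelihood: {self.llf:.2f}   AICc: {self.aicc:.1f}   AUC: {self.auc:.3f}",
            f"  sigma_u: {self.sigma_u:.4f}  (variance {self.sigma_u2:.4f})",
            "",
            tbl.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        tbl = self.wald_table()
        return {
            "family": "logistic_glmm",
            "coefficients": dict(zip(self.exog_names, self.params.tolist())),
            "se": dict(zip(self.exog_names, self.bse.tolist())),
            "wald_chi2": tbl["wald_chi2"].to_dict(),
            "p": tbl["p"].to_dict(),
            "sigma_u2": self.sigma_u2,
            "loglik": self.llf,
            "aicc": self.aicc,
            "auc": self.auc,
            "n_obs": int(self.nobs),
            "n_groups": int(self.model.n_groups),
        }


# ---------------------------------------------------------------------------
# beta-binomial regression


class BetaBinomial:
    """Beta-binomial regression on (n_correct, n_units) trial counts.

    Mean model mu = logistic(X b); overdispersion rho in [0, 1) with
    alpha = mu (1-rho)/rho and beta = (1-mu)(1-rho)/rho.
    """

    def __init__(self, successes, totals, exog, exog_names=None):
        self.successes = np.asarray(successes, dtype=float)
        self.totals = np.asarray(totals, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if np.any(self.totals < 1):
            raise ValueError("each trial needs n_units >= 1")
        if np.any(self.successes < 0) or np.any(self.successes > self.totals):
            raise ValueError("successes must lie in [0, totals]")
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        self.nobs = self.successes.size

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, successes: str, totals: str, terms: list[str]
    ):
        X, names = build_design_matrix(data, terms)
        return cls(data[successes].to_numpy(float), data[totals].to_numpy(float), X, names)

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at (beta, logit rho)."""
        beta, rho_t = params[:-1], params[-1]
        rho = special.expit(rho_t)
        mu = special.expit(self.exog @ beta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        k, n = self.successes, self.totals
        if rho < 1e-8:
            # binomial limit, numerically stable for tiny rho
            ll = (
                special.gammaln(n + 1)
                - special.gammaln(k + 1)
                - special.gammaln(n - k + 1)
                + k * np.log(mu)
                + (n - k) * np.log1p(-mu)
            )
            return float(ll.sum())
        s = (1.0 - rho) / rho
        a, b = mu * s, (1.0 - mu) * s
        ll = (
            special.gammaln(n + 1)
            - special.gammaln(k + 1)
            - special.gammaln(n - k + 1)
            + special.betaln(k + a, n - k + b)
            - special.betaln(a, b)
        )
        return float(ll.sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood at (beta, logit rho)."""
        beta, rho_t = params[:-1], params[-1]
        rho = float(np.clip(special.expit(rho_t), 1e-10, 1 - 1e-10))
        mu = np.clip(special.expit(self.exog @ beta), 1e-12, 1 - 1e-12)
        k, n = self.successes, self.totals
        s = (1.0 - rho) / rho
        a, b = mu * s, (1.0 - mu) * s
        psi = special.digamma
        dll_da = psi(k + a) - psi(n + s) - psi(a) + psi(s)
        dll_db = psi(n - k + b) - psi(n + s) - psi(b) + psi(s)
        grad_beta = self.exog.T @ (mu * (1.0 - mu) * s * (dll_da - dll_db))
        # d s / d logit(rho) = -s
        grad_t = float(np.sum(-s * (mu * dll_da + (1.0 - mu) * dll_db)))
        return np.append(grad_beta, grad_t)

    def fit(self, gtol: float = 1e-6, maxiter: int = 500) -> "BetaBinomialResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                np.column_stack([self.successes, self.totals - self.successes]),
                self.exog,
                family=sm.families.Binomial(),
            ).fit()
        x0 = np.append(glm.params, special.logit(0.05))
        col_scale = np.append(np.maximum(np.abs(self.exog).max(axis=0), 1e-12), 1.0)

        def nll(xs):
            return -self.loglike(xs / col_scale)

        def njac(xs):
            return -self.score(xs / col_scale) / col_scale

        res = optimize.minimize(
            nll, x0 * col_scale, jac=njac, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        scale = max(1.0, abs(res.fun))
        grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > gtol * scale:
            res = optimize.minimize(
                nll, res.x, jac=njac, method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > max(gtol * scale, 1e-4):
            raise ConvergenceError(
                f"beta-binomial optimisation failed: {res.message} (|grad|={grad_norm:.2e})"
            )
        params = res.x / col_scale
        rho = float(special.expit(params[-1]))
        if rho < 1e-6 or rho > 1 - 1e-6:
            warnings.warn("rho at boundary: overdispersion poorly identified", RuntimeWarning)
        if np.all(self.successes == self.totals) or np.all(self.successes == 0):
            warnings.warn("degenerate outcomes: all trials fully correct/incorrect", RuntimeWarning)
        hess_s = _numeric_hessian(nll, res.x)
        try:
            cov_s = np.linalg.inv(hess_s)
        except np.linalg.LinAlgError:
            cov_s = np.linalg.pinv(hess_s)
        cov = cov_s / np.outer(col_scale, col_scale)
        return BetaBinomialResults(self, params, cov, -res.fun, res)


@dataclass
class BetaBinomialResults:
    """ML estimates for a beta-binomial regression."""

    model: BetaBinomial
    _params: np.ndarray
    cov: np.ndarray
    llf: float
    optim_result: object

    def __post_init__(self) -> None:
        self.params = self._params[:-1]
        self.bse = np.sqrt(np.clip(np.diag(self.cov)[:-1], 0.0, None))
        self.rho = float(special.expit(self._params[-1]))
        self.k_params = self._params.size
        self.nobs = self.model.nobs  # trials: the model's observation level
        self.aicc = aicc(self.llf, self.k_params, self.nobs)
        self.exog_names = self.model.exog_names

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted mean proportion per trial."""
        return special.expit(self.model.exog @ self.params)

    @property
    def auc(self) -> float:
        """AUC on unit-level outcomes expanded from the trial counts."""
        k = self.model.successes.astype(int)
        n = self.model.totals.astype(int)
        mu = self.fittedvalues
        y = np.concatenate([np.repeat([1, 0], [ki, ni - ki]) for ki, ni in zip(k, n)])
        p = np.concatenate([np.full(ni, mi) for ni, mi in zip(n, mu)])
        return auc(y, p)

    def wald_table(self) -> pd.DataFrame:
        return _wald_table(self.params, self.bse, self.exog_names)

    def summary(self) -> str:
        tbl = self.wald_table()
        lines = [
            "Beta-binomial regression (logit mean, ML)",
            f"  trials: {self.nobs}",
            f"  log-likelihood: {self.llf:.2f}   AICc: {self.aicc:.1f}   AUC: {self.auc:.3f}",
            f"  rho: {self.rho:.4f}",
            "",
            tbl.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        tbl = self.wald_table()
        return {
            "family": "beta_binomial",
            "coefficients": dict(zip(self.exog_names, self.params.tolist())),
            "se": dict(zip(self.exog_names, self.bse.tolist())),
            "wald_chi2": tbl["wald_chi2"].to_dict(),
            "p": tbl["p"].to_dict(),
            "rho": self.rho,
            "loglik": self.llf,
            "aicc": self.aicc,
            "auc": self.auc,
            "n_obs": int(self.nobs),
        }
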
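"""Random-intercept linear mixed model with Satterthwaite degrees of freedom.

Model: y = X b + Z u + e with one random intercept per group,
u ~ N(0, tau2), e ~ N(0, sigma2). Variance components are estimated by
REML; the covariance V is block diagonal with blocks
``sigma2 * I + tau2 * J``, so every quantity reduces to closed-form
per-group sums (no n x n algebra).

The Satterthwaite approximation for a fixed-effect contrast l is

    df = 2 * (l' C(th) l)^2 / Var(l' C(th) l)

with C(th) = (X' V(th)^-1 X)^-1 evaluated at the REML estimate, the
variance in the denominator obtained by the delta method: gradient of
l'C l with respect to th = (sigma2, tau2) against the inverse observed
REML information. This mirrors the standard mixed-model t-test with
Satterthwaite df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .model import FusionValidationError


@dataclass
class RandomInterceptResult:
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    tau2: float
    df: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    loglik: float
    n_obs: int
    n_groups: int


class _REMLProblem:
    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0] or len(groups) != len(y):
            raise FusionValidationError("y, X and groups must align")
        self.n, self.p = X.shape
        codes, _ = pd_factorize(groups)
        self.G = codes.max() + 1
        # per-group sufficient statistics
        self.ng = np.zeros(self.G)
        self.XtX = np.zeros((self.G, self.p, self.p))
        self.Xty = np.zeros((self.G, self.p))
        self.yty = np.zeros(self.G)
        self.X1 = np.zeros((self.G, self.p))
        self.y1 = np.zeros(self.G)
        for g in range(self.G):
            m = codes == g
            Xg, yg = X[m], y[m]
            self.ng[g] = m.sum()
            self.XtX[g] = Xg.T @ Xg
            self.Xty[g] = Xg.T @ yg
            self.yty[g] = yg @ yg
            self.X1[g] = Xg.sum(axis=0)
            self.y1[g] = yg.sum()

    def _assemble(self, sigma2: float, tau2: float):
        c = tau2 / (sigma2 + self.ng * tau2)  # per group
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        logdetV = 0.0
        for g in range(self.G):
            XtViX += (self.XtX[g] - c[g] * np.outer(self.X1[g], self.X1[g])) / sigma2
            XtViy += (self.Xty[g] - c[g] * self.X1[g] * self.y1[g]) / sigma2
            ytViy += (self.yty[g] - c[g] * self.y1[g] ** 2) / sigma2
            logdetV += (self.ng[g] - 1) * np.log(sigma2) + np.log(
                sigma2 + self.ng[g] * tau2
            )
        return XtViX, XtViy, ytViy, logdetV

    def reml_loglik(self, sigma2: float, tau2: float) -> float:
        if sigma2 <= 0 or tau2 < 0:
            return -np.inf
        XtViX, XtViy, ytViy, logdetV = self._assemble(sigma2, tau2)
        sign, logdet_info = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - beta @ XtViy
        return -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi) + logdetV + logdet_info + quad
        )

    def beta_cov(self, sigma2: float, tau2: float):
        XtViX, XtViy, _, _ = self._assemble(sigma2, tau2)
        C = np.linalg.inv(XtViX)
        return C @ XtViy, C


def pd_factorize(values) -> tuple[np.ndarray, np.ndarray]:
    """Stable integer codes for group labels (order of first appearance)."""
    seen: dict = {}
    codes = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        codes[i] = seen.setdefault(v, len(seen))
    return codes, np.array(list(seen))


def fit_random_intercept(y, X, groups) -> RandomInterceptResult:
    """REML fit of a random-intercept model with Satterthwaite df per
    coefficient.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (include the intercept column yourself)
    groups : (n,) group labels for the random intercept
    """
    prob = _REMLProblem(y, np.atleast_2d(X), np.asarray(groups))
    if prob.G < 2:
        raise FusionValidationError(
            "random-intercept model needs >= 2 groups; use a per-group test instead"
        )

    # moment-based starting values
    yv = np.asarray(y, dtype=float)
    s2_0 = max(np.var(yv), 1e-8)
    start = np.log([0.7 * s2_0, 0.3 * s2_0 + 1e-8])

    def nll(phi):
        return -prob.reml_loglik(np.exp(phi[0]), np.exp(phi[1]))

    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
    sigma2, tau2 = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    beta, C = prob.beta_cov(sigma2, tau2)
    se = np.sqrt(np.diag(C))

    # observed information of (sigma2, tau2) by central differences
    theta = np.array([sigma2, tau2])
    h = np.maximum(1e-6, 1e-4 * np.abs(theta))

    def ll(t):
        return prob.reml_loglik(max(t[0], 1e-12), max(t[1], 0.0))

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            H[i, j] = H[j, i] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    info = -H
    try:
        A = np.linalg.inv(info)
        if not np.all(np.isfinite(A)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(info)

    # Satterthwaite df per coefficient via gradient of C_jj in theta
    p = len(beta)
    df = np.empty(p)
    for j in range(p):
        grad = np.zeros(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = h[i]
            _, C_plus = prob.beta_cov(*(theta + e))
            _, C_minus = prob.beta_cov(*np.maximum(theta - e, [1e-12, 0.0]))
            grad[i] = (C_plus[j, j] - C_minus[j, j]) / (2 * h[i])
        denom = float(grad @ A @ grad)
        if denom <= 0 or not np.isfinite(denom):
            df[j] = prob.n - p  # fallback when the information is degenerate
        else:
            df[j] = max(1.0, 2.0 * C[j, j] ** 2 / denom)

    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return RandomInterceptResult(
        beta=beta,
        se=se,
        sigma2=sigma2,
        tau2=tau2,
        df=df,
        tvalues=tvals,
        pvalues=pvals,
        loglik=-res.fun,
        n_obs=prob.n,
        n_groups=prob.G,
    )
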
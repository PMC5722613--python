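"""Random-intercept linear mixed model for intensity effects on phase firing.

The model is ``y_ij = b0 + beta * x_ij + u_i + e_ij`` with animal-level
random intercepts ``u_i ~ N(0, var_animal)`` and residuals
``e_ij ~ N(0, var_resid)``; ``x`` is stimulation intensity in %MT (entered
raw, not centered) and ``y`` is per-trial mean normalized firing rate of a
response phase.

Estimation is restricted maximum likelihood, profiled in the single
variance ratio ``theta = var_animal / var_resid``: for fixed theta the GLS
fixed effects and the residual variance have closed forms via per-group
sums (the covariance is block-compound-symmetric), and theta is found by a
bounded derivative-free search.  This makes the fit deterministic and
reproducible to the optimizer tolerance.

The fixed effect is tested with an F statistic (squared Wald t) whose
denominator degrees of freedom use the Satterthwaite approximation --
computed from the REML observed information, as in lmerTest -- with a
parametric-bootstrap alternative.  A Wilcoxon rank-sum test (exact by full
enumeration for small samples) is provided for simple two-sample
comparisons such as motor thresholds between coil orientations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LmmFit", "fit_lmm", "test_fixed_effect", "rank_sum_test"]

_THETA_BOUNDS = (0.0, 1.0e6)
_THETA_XATOL = 1.0e-10


@dataclass
class LmmFit:
    """REML estimates and fixed-effect inference for the random-intercept model."""

    beta: float
    intercept: float
    var_animal: float
    var_resid: float
    se_beta: float
    F: float = np.nan
    p: float = np.nan
    ddf: float = np.nan
    n_obs: int = 0
    n_groups: int = 0
    method: str = "satterthwaite"

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "intercept": self.intercept,
            "var_animal": self.var_animal, "var_resid": self.var_resid,
            "se_beta": self.se_beta, "F": self.F, "p": self.p, "ddf": self.ddf,
            "n_obs": self.n_obs, "n_groups": self.n_groups, "method": self.method,
        }


class _RemlProblem:
    """Per-group sufficient statistics for the compound-symmetric REML fit."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        codes, self.levels = pd.factorize(np.asarray(groups))
        self.n, self.p = self.X.shape
        self.G = len(self.levels)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.ni = np.bincount(codes, minlength=self.G).astype(float)
        self.sx = np.zeros((self.G, self.p))
        for j in range(self.p):
            self.sx[:, j] = np.bincount(codes, weights=self.X[:, j], minlength=self.G)
        self.sy = np.bincount(codes, weights=self.y, minlength=self.G)

    def pieces(self, theta: float):
        """A = X'V^-1 X, b = X'V^-1 y, q = y'V^-1 y for V = I + theta Z Z'."""
        c = theta / (1.0 + theta * self.ni)
        A = self.XtX - (self.sx * c[:, None]).T @ self.sx
        b = self.Xty - self.sx.T @ (c * self.sy)
        q = self.yty - float(c @ (self.sy ** 2))
        return A, b, q

    def profile_neg2reml(self, theta: float):
        """Profiled -2 REML log-likelihood (up to a constant) and GLS by-products."""
        A, b, q = self.pieces(theta)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        dof = self.n - self.p
        sigma_e2 = max(rss / dof, 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        neg2 = (dof * math.log(sigma_e2) + float(np.sum(np.log1p(theta * self.ni)))
                + logdetA)
        return neg2, beta, A, sigma_e2

    def neg2reml(self, var_animal: float, var_resid: float) -> float:
        """-2 REML log-likelihood (up to a constant) at given variance components."""
        theta = var_animal / var_resid
        A, b, q = self.pieces(theta)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        _, logdetA = np.linalg.slogdet(A)
        return ((self.n - self.p) * math.log(var_resid)
                + float(np.sum(np.log1p(theta * self.ni)))
                + logdetA + rss / var_resid)

    def fit(self):
        """Optimize theta; returns (theta, beta, A, sigma_e2)."""
        res = optimize.minimize_scalar(
            lambda t: self.profile_neg2reml(t)[0],
            bounds=_THETA_BOUNDS, method="bounded",
            options={"xatol": _THETA_XATOL},
        )
        theta = float(res.x)
        # check the boundary explicitly; a boundary fit is reported, not an error
        if self.profile_neg2reml(0.0)[0] <= res.fun:
            theta = 0.0
        _, beta, A, sigma_e2 = self.profile_neg2reml(theta)
        return theta, beta, A, sigma_e2


def _problem_from_table(table: pd.DataFrame, response: str, fixed: Optional[str],
                        group: str) -> _RemlProblem:
    y = table[response].to_numpy(dtype=float)
    if fixed is not None:
        x = table[fixed].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"singular design: {fixed!r} is constant")
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = np.ones((len(y), 1))
    return _RemlProblem(X, y, table[group].to_numpy())


def fit_lmm(table: pd.DataFrame, response: str = "mean_fr", fixed: str = "intensity",
            group: str = "animal", inference: bool = True,
            method: str = "satterthwaite", n_boot: int = 500,
            seed: Optional[int] = None) -> LmmFit:
    """REML fit of the one-random-intercept model to a per-trial phase table.

    Requires at least two groups and at least two distinct values of the
    fixed covariate.  A boundary fit (``var_animal = 0``) is reported, not
    an error.  With ``inference=True`` the fixed effect is tested against
    the null model (see :func:`test_fixed_effect`) and F/p/ddf are filled.
    """
    prob = _problem_from_table(table, response, fixed, group)
    if prob.G < 2:
        raise ValueError(f"need >= 2 groups, got {prob.G}")
    theta, beta, A, sigma_e2 = prob.fit()
    cov_beta = sigma_e2 * np.linalg.inv(A)
    fit = LmmFit(
        beta=float(beta[1]), intercept=float(beta[0]),
        var_animal=float(theta * sigma_e2), var_resid=float(sigma_e2),
        se_beta=float(np.sqrt(cov_beta[1, 1])),
        n_obs=prob.n, n_groups=prob.G, method=method,
    )
    if inference:
        F, p, ddf = test_fixed_effect(table, response=response, fixed=fixed, group=group,
                                      method=method, n_boot=n_boot, seed=seed,
                                      _fitted=(prob, theta, beta, A, sigma_e2),
                                      return_ddf=True)
        fit.F, fit.p, fit.ddf = F, p, ddf
    return fit


def _satterthwaite_ddf(prob: _RemlProblem, var_animal: float, var_resid: float) -> float:
    """Satterthwaite denominator df for the slope, from the REML observed information."""
    k = prob.p - 1  # slope index

    def c_of(phi):
        A, _, _ = prob.pieces(phi[0] / phi[1])
        return phi[1] * np.linalg.inv(A)[k, k]

    fallback = max(prob.n - prob.G - prob.p + 1, 1.0)
    phi = np.array([var_animal, var_resid], dtype=float)
    if phi[0] <= 1e-12 * phi[1]:
        return fallback
    h = 1e-4 * np.maximum(phi, 1e-10 * phi[1])
    # gradient of Var(beta_hat) wrt the variance components
    g = np.zeros(2)
    for j in range(2):
        e = np.zeros(2); e[j] = h[j]
        g[j] = (c_of(phi + e) - c_of(phi - e)) / (2 * h[j])
    # observed information from the -2 log REML likelihood Hessian
    f = prob.neg2reml
    H = np.zeros((2, 2))
    f0 = f(*phi)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(*(phi + ei)) - 2 * f0 + f(*(phi - ei))) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(*(phi + ei + ej)) - f(*(phi + ei - ej))
                    - f(*(phi - ei + ej)) + f(*(phi - ei - ej))
                ) / (4 * h[i] * h[j])
    try:
        cov_phi = 2.0 * np.linalg.inv(H)  # Var(phi_hat) ~ [0.5 * Hessian]^-1
    except np.linalg.LinAlgError:
        return fallback
    denom = float(g @ cov_phi @ g)
    if denom <= 0:
        return fallback
    ddf = 2.0 * c_of(phi) ** 2 / denom
    if not np.isfinite(ddf) or ddf < 1.0:
        return fallback
    return float(ddf)


def test_fixed_effect(table: pd.DataFrame, response: str = "mean_fr",
                      fixed: str = "intensity", group: str = "animal",
                      method: str = "satterthwaite", n_boot: int = 500,
                      seed: Optional[int] = None, _fitted=None,
                      return_ddf: bool = False):
    """F-test for dropping the intensity fixed effect.

    ``method='satterthwaite'`` (default): F = squared Wald t with
    Satterthwaite denominator df.  ``method='bootstrap'``: parametric
    bootstrap of the F statistic under the fitted null (intercept +
    random intercept) model; p = (1 + #{F* >= F}) / (n_boot + 1).
    Returns ``(F, p)`` (plus ddf if ``return_ddf``).
    """
    if _fitted is None:
        prob = _problem_from_table(table, response, fixed, group)
        theta, beta, A, sigma_e2 = prob.fit()
    else:
        prob, theta, beta, A, sigma_e2 = _fitted
    k = prob.p - 1
    se = math.sqrt(sigma_e2 * np.linalg.inv(A)[k, k])
    F = (beta[k] / se) ** 2

    if method == "satterthwaite":
        ddf = _satterthwaite_ddf(prob, theta * sigma_e2, sigma_e2)
        p = float(stats.f.sf(F, 1, ddf))
    elif method == "bootstrap":
        null = _problem_from_table(table, response, None, group)
        theta0, beta0, _, s2_0 = null.fit()
        va0, ve0 = theta0 * s2_0, s2_0
        rng = np.random.default_rng(seed)
        codes, _ = pd.factorize(table[group].to_numpy())
        x = table[fixed].to_numpy(dtype=float)
        Xfull = np.column_stack([np.ones_like(x), x])
        exceed = 0
        for _ in range(n_boot):
            u = rng.normal(0.0, math.sqrt(va0), size=null.G)
            ystar = beta0[0] + u[codes] + rng.normal(0.0, math.sqrt(ve0), size=null.n)
            pb = _RemlProblem(Xfull, ystar, codes)
            _, bb, Ab, s2b = pb.fit()
            seb = math.sqrt(s2b * np.linalg.inv(Ab)[1, 1])
            if (bb[1] / seb) ** 2 >= F:
                exceed += 1
        p = (1.0 + exceed) / (n_boot + 1.0)
        ddf = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    if return_ddf:
        return float(F), float(p), float(ddf)
    return float(F), float(p)


def rank_sum_test(a, b) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by full enumeration of rank assignments for combined n <= 20
    (midranks handle ties naturally); normal approximation with tie
    correction otherwise.  Returns ``(W, p)`` where W is the rank sum of
    the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(a), len(b)
    N = n + m
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n].sum())

    if N <= 20:
        lo = hi = total = 0
        for comb in itertools.combinations(range(N), n):
            s = sum(ranks[i] for i in comb)
            total += 1
            if s <= w + 1e-12:
                lo += 1
            if s >= w - 1e-12:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return w, p

    mu = n * (N + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float(np.sum(counts ** 3 - counts)) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_corr)
    if var <= 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))
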
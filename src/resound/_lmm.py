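"""Profiled maximum-likelihood fitting of Gaussian linear mixed models
with crossed random intercepts.

The model is ``y = X b + sum_g Z_g u_g + e`` with ``u_g ~ N(0, s2_g I)``
and ``e ~ N(0, s2_e I)``; each ``Z_g`` is an indicator matrix of one
grouping factor (site, year, stratum, route), so the random structure is
fully crossed. Writing ``theta_g = s2_g / s2_e``, both ``b`` and
``s2_e`` profile out of the Gaussian likelihood analytically, leaving an
optimization over the handful of log variance ratios only. All
likelihood pieces reduce to fixed-size cross-products (X'X, Z'Z, Z'X,
Z'y, ...), so one likelihood evaluation costs O(q^3) in the total number
of random levels q, independent of the number of observations, and the
Woodbury/determinant identities are applied in the symmetric
``I + L^{1/2} Z'Z L^{1/2}`` form, which stays well-conditioned as any
``theta_g`` approaches the zero boundary.

Likelihood-ratio tests between nested fixed-effect structures therefore
compare genuine ML (not REML) maxima. Fits are deterministic: the
Nelder-Mead search starts from a fixed grid of starting points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .errors import FitError

_LOG_THETA_MIN = -30.0  # theta below e^-30 is treated as a zero variance
_LOG_THETA_MAX = 30.0
_STARTS = (-1.0, -4.0, 1.0)


def indicator_matrix(codes) -> np.ndarray:
    """Dense 0/1 design for one grouping factor (levels in sorted order)."""
    codes = np.asarray(codes)
    levels, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((codes.size, levels.size))
    Z[np.arange(codes.size), inv] = 1.0
    return Z


@dataclass
class LMMFit:
    """A fitted crossed random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    fixed_names: list[str]
    vc: dict[str, float]  # variance per random grouping
    sigma2: float  # residual variance
    m2ll: float  # -2 * max log-likelihood (ML)
    n: int
    converged: bool
    cov_beta: np.ndarray

    @property
    def loglik(self) -> float:
        return -0.5 * self.m2ll

    def coef(self, name: str) -> float:
        return float(self.beta[self.fixed_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.fixed_names.index(name)])


def _suffstats(y, X, Zs):
    Z = np.hstack(Zs) if Zs else np.zeros((len(y), 0))
    return {
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
        "ZtX": Z.T @ X,
        "Zty": Z.T @ y,
        "ZtZ": Z.T @ Z,
        "n": len(y),
        "qs": [z.shape[1] for z in Zs],
    }


def _core(logth, ss):
    th = np.exp(np.clip(logth, _LOG_THETA_MIN, _LOG_THETA_MAX))
    lam = np.concatenate([np.full(q, t) for q, t in zip(ss["qs"], th)]) if len(th) else np.zeros(0)
    if lam.size:
        rt = np.sqrt(lam)
        A = np.eye(lam.size) + rt[:, None] * ss["ZtZ"] * rt[None, :]
        cA = linalg.cho_factor(A, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cA[0])))
        sZtX = rt[:, None] * ss["ZtX"]
        sZty = rt * ss["Zty"]
        XtVX = ss["XtX"] - sZtX.T @ linalg.cho_solve(cA, sZtX, check_finite=False)
        XtVy = ss["Xty"] - sZtX.T @ linalg.cho_solve(cA, sZty, check_finite=False)
        ytVy = ss["yty"] - sZty @ linalg.cho_solve(cA, sZty, check_finite=False)
    else:
        logdetV, XtVX, XtVy, ytVy = 0.0, ss["XtX"], ss["Xty"], ss["yty"]
    beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    rss = max(float(ytVy - XtVy @ beta), 1e-300)
    return logdetV, XtVX, beta, rss


def _nll(logth, ss):
    try:
        logdetV, _, _, rss = _core(logth, ss)
    except (linalg.LinAlgError, ValueError):
        return 1e12
    n = ss["n"]
    return n * np.log(2.0 * np.pi * rss / n) + logdetV + n


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    fixed_names: list[str] | None = None,
    vc_names: list[str] | None = None,
) -> LMMFit:
    """Fit the crossed random-intercept LMM by profiled ML.

    ``Zs`` are indicator matrices, one per random grouping. An empty
    ``Zs`` degenerates to ordinary least squares with the same API.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise FitError("X must be (n, p) aligned with y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("fixed-effect design is rank deficient")
    fixed_names = fixed_names or [f"x{j}" for j in range(X.shape[1])]
    vc_names = vc_names or [f"g{j}" for j in range(len(Zs))]
    ss = _suffstats(y, X, Zs)
    k = len(Zs)
    if k == 0:
        logth = np.zeros(0)
        converged = True
        best_fun = _nll(logth, ss)
    else:
        best = None
        # one variance ratio gives a unimodal profiled likelihood; the
        # multi-start grid only matters for crossed structures
        starts = _STARTS if k > 1 else (_STARTS[0],)
        for s0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    _nll,
                    np.full(k, s0),
                    args=(ss,),
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000, "maxfev": 8000},
                )
            if best is None or res.fun < best.fun:
                best = res
        logth = np.asarray(best.x, dtype=float)
        converged = bool(best.success)
        best_fun = float(best.fun)
    try:
        logdetV, XtVX, beta, rss = _core(logth, ss)
    except (linalg.LinAlgError, ValueError) as exc:
        raise FitError(f"mixed-model likelihood evaluation failed: {exc}") from exc
    sigma2 = rss / ss["n"]
    cov_beta = linalg.inv(XtVX) * sigma2
    th = np.exp(np.clip(logth, _LOG_THETA_MIN, _LOG_THETA_MAX))
    vc = {}
    for name, t in zip(vc_names, th):
        var = float(t * sigma2)
        if np.log(t) <= _LOG_THETA_MIN + 1e-9:
            warnings.warn(f"random-effect variance for {name!r} pinned at 0 (boundary)")
            var = 0.0
        vc[name] = var
    return LMMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        fixed_names=list(fixed_names),
        vc=vc,
        sigma2=float(sigma2),
        m2ll=float(best_fun),
        n=ss["n"],
        converged=converged,
        cov_beta=cov_beta,
    )


def lrt(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested ML fits: (chi2, df, p)."""
    from scipy import stats

    chi2 = max(0.0, reduced.m2ll - full.m2ll)
    df = len(full.fixed_names) - len(reduced.fixed_names)
    if df < 1:
        raise FitError("models are not nested with positive df")
    return chi2, df, float(stats.chi2.sf(chi2, df))
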
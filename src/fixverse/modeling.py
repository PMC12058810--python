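"""Mixed models for the frequency effect on single fixation durations.

Three model families, all with crossed random intercepts for subject and
item (no slopes) and word frequency as a categorical fixed effect with
treatment coding (high-frequency reference, so the coefficient estimates
low minus high — positive is the canonical frequency effect):

``lmm_identity``
    Gaussian linear mixed model on raw durations (ms).
``lmm_log``
    Gaussian linear mixed model on natural-log durations.
``glmm_gamma``
    Gamma generalized linear mixed model with an identity link, fitted by
    iteratively reweighted penalized quasi-likelihood (working weights
    ``1/mu^2``, the Gamma variance function).

The Gaussian fits use a profiled REML criterion over the two
variance-component ratios; with only crossed intercepts the likelihood can
be evaluated from low-dimensional sufficient statistics (Woodbury identity
on the ``q = n_subjects + n_items`` random-effect columns), making a fit a
few milliseconds rather than seconds. Significance is the two-sided Wald
test on a normal reference; degrees-of-freedom corrections are out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

FAMILIES = ("lmm_identity", "lmm_log", "glmm_gamma")


@dataclass(frozen=True)
class ModelSpec:
    family: str = "lmm_identity"
    significance_alpha: float = 0.05

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class ModelResult:
    family: str
    beta_freq: float
    se_beta: float
    stat: float
    p_value: float
    significant: bool
    converged: bool
    n_obs: int
    intercept: float
    effect_ms: float | None
    var_subject: float = float("nan")
    var_item: float = float("nan")
    var_residual: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "beta_freq": self.beta_freq,
            "se_beta": self.se_beta,
            "stat": self.stat,
            "p_value": self.p_value,
            "significant": self.significant,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "intercept": self.intercept,
            "effect_ms": self.effect_ms,
            "var_subject": self.var_subject,
            "var_item": self.var_item,
            "var_residual": self.var_residual,
        }


class _CrossedStats:
    """Sufficient statistics for the profiled crossed-intercepts likelihood."""

    def __init__(self, y, X, subj, item, weights=None):
        n = len(y)
        ns = int(subj.max()) + 1
        ni = int(item.max()) + 1
        w = np.ones(n) if weights is None else weights
        self.n, self.ns, self.ni, self.p = n, ns, ni, X.shape[1]
        self.sumlogw = float(np.log(w).sum())
        # Z'WZ in blocks
        s_diag = np.bincount(subj, weights=w, minlength=ns)
        i_diag = np.bincount(item, weights=w, minlength=ni)
        cross = np.zeros((ns, ni))
        np.add.at(cross, (subj, item), w)
        ztwz = np.zeros((ns + ni, ns + ni))
        ztwz[:ns, :ns] = np.diag(s_diag)
        ztwz[ns:, ns:] = np.diag(i_diag)
        ztwz[:ns, ns:] = cross
        ztwz[ns:, :ns] = cross.T
        self.ztwz = ztwz
        wX = X * w[:, None]
        self.ztwX = np.vstack(
            [
                np.stack([np.bincount(subj, weights=wX[:, j], minlength=ns)
                          for j in range(X.shape[1])], axis=1),
                np.stack([np.bincount(item, weights=wX[:, j], minlength=ni)
                          for j in range(X.shape[1])], axis=1),
            ]
        )
        wy = y * w
        self.ztwy = np.concatenate(
            [
                np.bincount(subj, weights=wy, minlength=ns),
                np.bincount(item, weights=wy, minlength=ni),
            ]
        )
        self.xtwx = X.T @ wX
        self.xtwy = X.T @ wy
        self.ytwy = float(y @ wy)

    def profile(self, lam_s: float, lam_i: float, reml: bool = True):
        """Profiled deviance and GLS quantities at variance ratios (lam_s, lam_i)."""
        q = self.ns + self.ni
        d = np.concatenate(
            [np.full(self.ns, math.sqrt(max(lam_s, 0.0))),
             np.full(self.ni, math.sqrt(max(lam_i, 0.0)))]
        )
        M = np.eye(q) + d[:, None] * self.ztwz * d[None, :]
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet_v0 = 2.0 * float(np.log(np.diag(cf[0])).sum()) - self.sumlogw

        zx = d[:, None] * self.ztwX
        zy = d * self.ztwy
        Mi_zx = linalg.cho_solve(cf, zx, check_finite=False)
        Mi_zy = linalg.cho_solve(cf, zy, check_finite=False)
        A = self.xtwx - zx.T @ Mi_zx
        b = self.xtwy - zx.T @ Mi_zy
        c = self.ytwy - zy @ Mi_zy
        beta = linalg.solve(A, b, assume_a="pos")
        rss = max(c - b @ beta, 1e-12)
        if reml:
            dof = self.n - self.p
            sigma2 = rss / dof
            sign, logdet_a = np.linalg.slogdet(A)
            dev = dof * math.log(2 * math.pi * sigma2) + dof + logdet_v0 + logdet_a
        else:
            sigma2 = rss / self.n
            dev = self.n * math.log(2 * math.pi * sigma2) + self.n + logdet_v0
        cov_beta = sigma2 * linalg.inv(A)
        return dev, beta, cov_beta, sigma2


def fit_crossed_lmm(
    y: np.ndarray,
    X: np.ndarray,
    subj: np.ndarray,
    item: np.ndarray,
    weights: np.ndarray | None = None,
    reml: bool = True,
) -> dict:
    """REML (or ML) fit of ``y = X beta + u_subj + u_item + eps``.

    ``subj``/``item`` are 0-based integer codes. Returns a dict with
    ``beta``, ``cov_beta``, variance components and a convergence flag.
    """
    ss = _CrossedStats(np.asarray(y, float), np.asarray(X, float),
                       np.asarray(subj), np.asarray(item), weights)

    def objective(gamma):
        try:
            dev, *_ = ss.profile(gamma[0] ** 2, gamma[1] ** 2, reml)
        except linalg.LinAlgError:
            return np.inf
        return dev

    res = optimize.minimize(
        objective,
        x0=np.array([0.3, 0.3]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
    )
    lam_s, lam_i = res.x[0] ** 2, res.x[1] ** 2
    dev, beta, cov_beta, sigma2 = ss.profile(lam_s, lam_i, reml)
    converged = bool(res.success) and np.all(np.isfinite(beta)) and np.all(
        np.isfinite(cov_beta)
    )
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "sigma2": sigma2,
        "var_subject": lam_s * sigma2,
        "var_item": lam_i * sigma2,
        "deviance": dev,
        "converged": converged,
        "n_iter": res.nit,
    }


def _design(obs: pd.DataFrame, response: str):
    subj, _ = pd.factorize(obs["subject_id"], sort=True)
    item, _ = pd.factorize(obs["item_id"], sort=True)
    conds = set(obs["condition"].unique())
    if conds != {"high", "low"}:
        raise ValueError(f"need both conditions present, got {sorted(conds)}")
    if subj.max() < 1:
        raise ValueError("need at least 2 subjects")
    if item.max() < 1:
        raise ValueError("need at least 2 items")
    low = (obs["condition"] == "low").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(obs)), low])
    y = obs["sfd_ms"].to_numpy(dtype=float)
    if response == "log":
        y = np.log(y)
    return y, X, subj, item


def _wald(beta, cov_beta, alpha, converged, n_obs, family):
    b, se = float(beta[1]), float(math.sqrt(max(cov_beta[1, 1], 0.0)))
    z = b / se if se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else float("nan")
    return ModelResult(
        family=family,
        beta_freq=b,
        se_beta=se,
        stat=z,
        p_value=float(p),
        significant=bool(converged and math.isfinite(p) and p < alpha),
        converged=bool(converged),
        n_obs=n_obs,
        intercept=float(beta[0]),
        effect_ms=None,
    )


def fit_model(obs: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one model family on the observation table.

    Raises on structurally unusable input (a single condition, or fewer
    than two levels of either random factor); numerical convergence
    failures are recorded in ``converged``, never raised.
    """
    if spec.family == "lmm_log":
        y, X, subj, item = _design(obs, "log")
        fit = fit_crossed_lmm(y, X, subj, item, reml=True)
    elif spec.family == "lmm_identity":
        y, X, subj, item = _design(obs, "identity")
        fit = fit_crossed_lmm(y, X, subj, item, reml=True)
    else:  # glmm_gamma, identity link, PQL
        y, X, subj, item = _design(obs, "identity")
        fit = _fit_gamma_pql(y, X, subj, item)
    result = _wald(
        fit["beta"], fit["cov_beta"], spec.significance_alpha, fit["converged"],
        len(obs), spec.family,
    )
    result.var_subject = fit["var_subject"]
    result.var_item = fit["var_item"]
    result.var_residual = fit["sigma2"]
    return back_transform(result)


def _fit_gamma_pql(y, X, subj, item, max_iter=30, tol=1e-6):
    """Gamma/identity quasi-likelihood fit: iteratively reweighted LMM with
    working weights 1/mu^2 (mu from the fixed-effect predictor)."""
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    fit = None
    converged_loop = False
    for _ in range(max_iter):
        mu = X @ beta
        if np.any(mu <= 0):
            mu = np.maximum(mu, 1.0)
        w = 1.0 / mu**2
        fit = fit_crossed_lmm(y, X, subj, item, weights=w, reml=True)
        new_beta = fit["beta"]
        if np.max(np.abs(new_beta - beta)) < tol * max(1.0, np.max(np.abs(beta))):
            beta = new_beta
            converged_loop = True
            break
        beta = new_beta
    fit["converged"] = bool(fit["converged"] and converged_loop)
    return fit


def back_transform(result: ModelResult) -> ModelResult:
    """Fill ``effect_ms``, the frequency effect on the millisecond scale.

    Identity-link families report the raw coefficient; the log model
    back-transforms at the fixed-effect scale:
    ``exp(intercept + beta) - exp(intercept)``.
    """
    if not result.converged:
        result.effect_ms = None
        return result
    if result.family == "lmm_log":
        result.effect_ms = float(
            math.exp(result.intercept + result.beta_freq) - math.exp(result.intercept)
        )
    else:
        result.effect_ms = float(result.beta_freq)
    return result


def make_spec(family: str, alpha: float = 0.05) -> ModelSpec:
    return ModelSpec(family=family, significance_alpha=alpha)
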
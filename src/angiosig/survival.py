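"""Survival analysis: Kaplan-Meier curves, log-rank tests and Cox
proportional-hazards regression.

The product-limit estimator and the log-rank test are delegated to
lifelines. The Cox model maximizes the partial likelihood by Newton-Raphson
with Efron (default) or Breslow handling of tied event times; standard
errors come from the observed information, p-values are Wald. Times and
events are taken as given (months, event=1 death / 0 censored); an optional
administrative truncation horizon can be applied before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the Cox Newton-Raphson iteration fails to converge."""


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray      # number at risk just before each event time
    events: np.ndarray       # number of events at each event time
    survival: np.ndarray     # S(t) at each event time (nonincreasing, from 1)

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod(1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if set(np.unique(events)) - {0, 1, 0.0, 1.0, True, False}:
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter().fit(times, event_observed=events.astype(int))
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    ev_times = ev_rows.index.to_numpy(dtype=float)
    surv = np.array([kmf.predict(t) for t in ev_times], dtype=float)
    return KMCurve(
        event_times=ev_times,
        at_risk=ev_rows["at_risk"].to_numpy(dtype=int),
        events=ev_rows["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Log-rank test across 2+ groups: returns (chi2, df, p)."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events).astype(int)
    )
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


@dataclass
class CoxFit:
    names: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    ties_method: str
    converged: bool
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "se": self.se,
                "p": self.wald_p,
            },
            index=self.names,
        )


def _partial_loglik_parts(beta, x, times, events, ties):
    """Log partial likelihood, gradient and Hessian (Efron or Breslow)."""
    order = np.argsort(times, kind="stable")
    x = x[order]
    times = times[order]
    events = events[order]
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = np.einsum("i,ij,ik->ijk", w, x, x)
    # suffix sums over the risk set {j: t_j >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d_idx = np.arange(i, j)[events[i:j] == 1]
        d = len(d_idx)
        if d:
            s0_r, s1_r, s2_r = s0[i], s1[i], s2[i]
            s0_d = w[d_idx].sum()
            s1_d = wx[d_idx].sum(axis=0)
            s2_d = wxx[d_idx].sum(axis=0)
            ll += eta[d_idx].sum()
            grad += x[d_idx].sum(axis=0)
            for l in range(d):
                f = l / d if ties == "efron" else 0.0
                phi = s0_r - f * s0_d
                m1 = (s1_r - f * s1_d) / phi
                m2 = (s2_r - f * s2_d) / phi
                ll -= np.log(phi)
                grad -= m1
                hess -= m2 - np.outer(m1, m1)
        i = j
    return ll, grad, hess


def cox_fit(
    times,
    events,
    covariates,
    names=None,
    ties: str = "efron",
    horizon: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Parameters
    ----------
    covariates : samples x p array or DataFrame (constant columns rejected).
    ties : "efron" (default) or "breslow".
    horizon : optional administrative truncation time; events after it are
        censored at the horizon before fitting.

    Raises ``ConvergenceError`` after ``max_iter`` Newton steps without
    convergence (no silent output).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = names or [f"x{j + 1}" for j in range(x.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if horizon is not None:
        over = times > horizon
        events = np.where(over, 0, events)
        times = np.minimum(times, horizon)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    const = np.where(np.ptp(x, axis=0) == 0)[0]
    if const.size:
        raise ValueError(f"constant covariate(s): {[names[i] for i in const]}")

    center = x.mean(axis=0)
    xc = x - center  # centering leaves coefficients unchanged, aids stability
    beta = np.zeros(x.shape[1])
    ll, grad, hess = _partial_loglik_parts(beta, xc, times, events, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(hess, grad)
        new_beta = beta - step
        new_ll, new_grad, new_hess = _partial_loglik_parts(new_beta, xc, times, events, ties)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _partial_loglik_parts(
                new_beta, xc, times, events, ties
            )
            halvings += 1
            if halvings > 50:
                raise ConvergenceError("step-halving failed to improve the partial likelihood")
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(grad)) < tol or abs(delta) < 1e-12:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"Cox Newton-Raphson did not converge in {max_iter} iterations")
    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    return CoxFit(
        names=list(names),
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        se=se,
        wald_p=2.0 * norm.sf(np.abs(z)),
        loglik=float(ll),
        ties_method=ties,
        converged=converged,
        n_iter=it,
    )


def median_dichotomize(scores) -> np.ndarray:
    """Above-median indicator: 1 if score > median, else 0.

    All-equal input yields all zeros with a warning. The median and group
    sizes are logged.
    """
    import warnings

    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")
    med = float(np.median(scores))
    out = (scores > med).astype(int)
    if out.sum() == 0 and np.all(scores == scores[0]):
        warnings.warn("all scores equal; dichotomized factor is all zeros")
    logger.info("median_dichotomize: median=%.4g, above=%d, at-or-below=%d",
                med, int(out.sum()), int(len(out) - out.sum()))
    return out


def survival_table(times, events, factors: pd.DataFrame, ties: str = "efron") -> pd.DataFrame:
    """Univariate and multivariate hazard-ratio table.

    ``factors`` holds one numeric (0/1 or continuous) column per factor.
    The univariate columns come from one-covariate Cox fits plus a log-rank
    p for binary factors; the multivariate columns from a joint Cox fit of
    all factors.
    """
    rows = []
    multi = cox_fit(times, events, factors, ties=ties)
    for j, name in enumerate(factors.columns):
        uni = cox_fit(times, events, factors[[name]], ties=ties)
        col = factors[name].to_numpy()
        logrank_p = np.nan
        if set(np.unique(col)).issubset({0, 1, 0.0, 1.0}):
            _, _, logrank_p = logrank_test(times, events, col.astype(int))
        rows.append(
            {
                "factor": name,
                "HR_univariate": uni.hazard_ratios[0],
                "p_univariate": uni.wald_p[0],
                "p_logrank": logrank_p,
                "HR_multivariate": multi.hazard_ratios[j],
                "p_multivariate": multi.wald_p[j],
            }
        )
    return pd.DataFrame(rows).set_index("factor")
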